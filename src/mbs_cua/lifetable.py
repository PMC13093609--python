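"""Annual all-cause mortality (life table) support.

The published inputs give only two anchor death probabilities from the
Australian life tables (weighted average of males and females): 0.00053
at age 30 and 0.15277 at age 90.  Adult all-cause mortality is close to
log-linear in age (Gompertz), so the packaged table interpolates
q(x) = a·exp(b·x) through the anchors; users can substitute a full
empirical table from a two-column CSV (age, qx).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Printed anchor death probabilities (age, annual probability of death).
DEFAULT_ANCHORS = ((30, 0.00053), (90, 0.15277))


@dataclass(frozen=True)
class LifeTable:
    """Annual death probability by integer age.

    Lookups at fractional ages interpolate log-linearly between integer
    ages; lookups outside the table clamp to the first/last age, so
    modelling past the final tabulated age (90 in the packaged table)
    holds the hazard at that age's value.
    """

    ages: np.ndarray
    qx: np.ndarray
    _logq: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        qx = np.asarray(self.qx, dtype=float)
        if ages.ndim != 1 or ages.shape != qx.shape or ages.size < 2:
            raise ValueError("life table needs matching 1-d ages and qx with >= 2 rows")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("life table ages must be strictly increasing")
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("life table qx must lie in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        with np.errstate(divide="ignore"):
            object.__setattr__(self, "_logq", np.log(np.maximum(qx, 1e-300)))

    def lookup(self, age) -> np.ndarray | float:
        """Annual death probability at ``age`` (scalar or array)."""
        age = np.clip(np.asarray(age, dtype=float), self.ages[0], self.ages[-1])
        out = np.exp(np.interp(age, self.ages, self._logq))
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages.astype(int), "qx": self.qx})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        missing = {"age", "qx"} - set(df.columns)
        if missing:
            raise ValueError(f"life table CSV missing column(s): {sorted(missing)}")
        return cls(df["age"].to_numpy(), df["qx"].to_numpy())


def build_lifetable(anchors, max_age: int = 100, min_age: int = 18) -> LifeTable:
    """Gompertz life table through anchor points.

    Fits log q(x) = log a + b·x by least squares through the anchors
    (exact when two anchors are given) and tabulates integer ages
    ``min_age``..``max_age``.  Anchors must be strictly increasing in
    both age and qx unless all qx are equal (degenerate constant table).
    """
    anchors = sorted((float(a), float(q)) for a, q in anchors)
    if len(anchors) < 2:
        raise ValueError("need at least two anchor points")
    ages = np.array([a for a, _ in anchors])
    qs = np.array([q for _, q in anchors])
    if np.any((qs <= 0) | (qs >= 1)):
        raise ValueError("anchor qx must lie in (0, 1)")
    if len(set(ages)) != len(ages):
        raise ValueError("anchor ages must be distinct")
    if np.all(qs == qs[0]):
        b, loga = 0.0, np.log(qs[0])
    else:
        if np.any(np.diff(qs) <= 0):
            raise ValueError("anchor qx must be strictly increasing with age")
        b, loga = np.polyfit(ages, np.log(qs), 1)
    grid = np.arange(int(min_age), int(max_age) + 1, dtype=float)
    qx = np.minimum(1.0, np.exp(loga + b * grid))
    return LifeTable(grid, qx)
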
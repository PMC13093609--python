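"""Parameter uncertainty distributions.

Each uncertain model input carries a :class:`DistributionSpec` describing
how it is drawn in probabilistic sensitivity analysis.  The source table
reports only a mean and standard deviation for Beta and Gamma parameters,
so both are parameterized by the method of moments — the standard
health-economics convention for PSA (Briggs/Claxton/Sculpher style).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


class InfeasibleMomentsError(ValueError):
    """Raised when (mean, sd) cannot be matched by the requested family."""


def moments_to_beta(mean: float, sd: float) -> tuple[float, float]:
    """Beta shape parameters (alpha, beta) matching a given mean and sd.

    Uses the method of moments:

        alpha = mean * (mean*(1-mean)/sd^2 - 1)
        beta  = alpha * (1-mean)/mean

    Feasibility requires 0 < mean < 1 and sd^2 < mean*(1-mean).
    """
    if not 0.0 < mean < 1.0:
        raise InfeasibleMomentsError(f"beta mean must be in (0,1), got {mean}")
    if sd <= 0.0:
        raise InfeasibleMomentsError(f"beta sd must be positive, got {sd}")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"beta infeasible: sd^2={var:g} >= mean*(1-mean)={mean * (1 - mean):g}"
        )
    alpha = mean * (mean * (1.0 - mean) / var - 1.0)
    beta = alpha * (1.0 - mean) / mean
    return alpha, beta


def moments_to_gamma(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, scale) matching a given mean and sd.

    shape = (mean/sd)^2, scale = sd^2/mean; the first two moments are
    reproduced exactly.
    """
    if mean <= 0.0:
        raise ValueError(f"gamma mean must be positive, got {mean}")
    if sd <= 0.0:
        raise ValueError(f"gamma sd must be positive, got {sd}")
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


@dataclass(frozen=True)
class DistributionSpec:
    """How one parameter is drawn in PSA.

    kind: "fixed", "beta", "gamma" or "triangular".
    Beta/Gamma are moment-matched from (mean, sd).  Triangular uses
    (min, mode, max); the mean field is informational for that kind.
    """

    kind: str
    mean: float
    sd: float = 0.0
    min: Optional[float] = None
    max: Optional[float] = None
    mode: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "beta", "gamma", "triangular"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "beta":
            moments_to_beta(self.mean, self.sd)  # validate feasibility
        elif self.kind == "gamma":
            moments_to_gamma(self.mean, self.sd)
        elif self.kind == "triangular":
            if self.min is None or self.max is None or self.mode is None:
                raise ValueError("triangular requires min, mode and max")
            if not self.min <= self.mode <= self.max:
                raise ValueError(
                    f"triangular requires min <= mode <= max, got "
                    f"({self.min}, {self.mode}, {self.max})"
                )
        elif self.sd < 0.0:
            raise ValueError("sd must be >= 0")

    def sample(self, rng: np.random.Generator, size=None):
        """Draw from the distribution; "fixed" returns the mean exactly."""
        if self.kind == "fixed":
            return self.mean if size is None else np.full(size, self.mean)
        if self.kind == "beta":
            a, b = moments_to_beta(self.mean, self.sd)
            return rng.beta(a, b, size=size)
        if self.kind == "gamma":
            shape, scale = moments_to_gamma(self.mean, self.sd)
            return rng.gamma(shape, scale, size=size)
        # triangular
        return rng.triangular(self.min, self.mode, self.max, size=size)

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "mean": self.mean}
        if self.kind in ("beta", "gamma"):
            d["sd"] = self.sd
        if self.kind == "triangular":
            d.update(min=self.min, mode=self.mode, max=self.max)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionSpec":
        return cls(
            kind=d["kind"],
            mean=float(d["mean"]),
            sd=float(d.get("sd", 0.0)),
            min=d.get("min"),
            max=d.get("max"),
            mode=d.get("mode"),
        )


def sample_parameter(dist: DistributionSpec, rng: np.random.Generator) -> float:
    """Draw a single value from ``dist`` using ``rng``."""
    return float(dist.sample(rng))
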
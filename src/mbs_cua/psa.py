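"""Probabilistic sensitivity analysis.

Monte-Carlo propagation of parameter uncertainty: every parameter with a
published uncertainty distribution (utilities, drift probabilities,
costs, surgical mortality, initial age) is drawn from its moment-matched
Beta/Gamma or Triangular distribution, both strategies are re-evaluated
per draw, and the resulting cloud of (ΔQ, ΔC) pairs is summarized on the
cost-effectiveness plane.  The 12-month post-surgery transition
probabilities are fixed, as published.

Each parameter draws from its own counter-based random sub-stream keyed
by (seed, parameter index) in the canonical order of
:data:`mbs_cua.parameters.PSA_PARAMETERS`, so adding a new parameter at
the end of that list does not perturb existing draws and identical seeds
give bit-identical samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cea import classify_ce_plane
from .engine import run_cohort
from .lifetable import LifeTable
from .parameters import PSA_PARAMETERS, ParameterSet

__all__ = ["PSASummary", "run_psa", "credible_ellipse", "plot_ce_plane"]

_MAX_RESAMPLE_ROUNDS = 100


def _stream_order(params: ParameterSet) -> list[str]:
    names = [n for n in PSA_PARAMETERS if n in params.distributions]
    extras = sorted(set(params.distributions) - set(names))
    return names + extras


def _draw_matrix(params, n_draws, seed):
    """One column of n_draws values per distributed parameter."""
    cols = {}
    for name in _stream_order(params):
        idx = (
            PSA_PARAMETERS.index(name)
            if name in PSA_PARAMETERS
            else len(PSA_PARAMETERS) + sorted(
                set(params.distributions) - set(PSA_PARAMETERS)
            ).index(name)
        )
        rng = np.random.default_rng(np.random.SeedSequence((seed, idx)))
        cols[name] = (params.distributions[name].sample(rng, size=n_draws), rng)
    return cols


def _row_feasible(params: ParameterSet, row: dict) -> bool:
    up_uc = row.get("up_uc", params.up_uc)
    down_uc = row.get("down_uc", params.down_uc)
    up_s = row.get("up_surgery", params.up_surgery)
    if up_uc + down_uc > 1.0 or up_s + params.down_surgery > 1.0:
        return False
    if params.options.monotone_utilities:
        u = [
            row.get("utility_ow", params.utilities[0]),
            row.get("utility_ob1", params.utilities[1]),
            row.get("utility_ob2", params.utilities[2]),
            row.get("utility_ob3", params.utilities[3]),
        ]
        if any(a < b for a, b in zip(u, u[1:])):
            return False
    return True


def _apply_draw(base: ParameterSet, row: dict) -> ParameterSet:
    changes: dict = {}
    utilities = base.utilities.copy()
    mgmt = base.management_cost.copy()
    surgery = dict(base.surgery_cost)
    for name, value in row.items():
        if name == "initial_age":
            changes["initial_age"] = round(float(value), 1)
        elif name == "utility_ow":
            utilities[0] = value
        elif name == "utility_ob1":
            utilities[1] = value
        elif name == "utility_ob2":
            utilities[2] = value
        elif name == "utility_ob3":
            utilities[3] = value
        elif name == "management_cost_ow":
            mgmt[0] = value
        elif name == "management_cost_ob1":
            mgmt[1] = value
        elif name == "management_cost_ob2_ob3":
            mgmt[2] = mgmt[3] = value
        elif name == "surgery_cost_ob1_ob2":
            surgery["OB1"] = surgery["OB2"] = value
        elif name == "surgery_cost_ob3":
            surgery["OB3"] = value
        else:
            changes[name] = float(value)
    changes["utilities"] = utilities
    changes["management_cost"] = mgmt
    changes["surgery_cost"] = surgery
    return base.replace(**changes)


@dataclass(frozen=True)
class PSASummary:
    """CE-plane summary of a PSA run.

    Quadrant groups partition the draws: SE (cost-saving, QALY-gaining),
    NE below the threshold, SW (cheaper, less effective, counted below
    the threshold under the composite rule) and everything else.
    """

    n_draws: int
    prop_se: float
    prop_ne_below: float
    prop_sw: float
    prop_other: float
    prop_below_wtp: float
    prop_cost_saving: float
    mean_delta_cost: float
    mean_delta_qaly: float
    n_resampled: int = 0
    ellipse: Optional[dict] = field(default=None)

    def to_dict(self) -> dict:
        d = {
            "n_draws": self.n_draws,
            "prop_se": self.prop_se,
            "prop_ne_below": self.prop_ne_below,
            "prop_sw": self.prop_sw,
            "prop_other": self.prop_other,
            "prop_below_wtp": self.prop_below_wtp,
            "prop_cost_saving": self.prop_cost_saving,
            "mean_delta_cost": self.mean_delta_cost,
            "mean_delta_qaly": self.mean_delta_qaly,
            "n_resampled": self.n_resampled,
        }
        if self.ellipse is not None:
            d["ellipse"] = {
                "center": list(self.ellipse["center"]),
                "cov": [list(r) for r in self.ellipse["cov"]],
                "scale": self.ellipse["scale"],
                "coverage": self.ellipse["coverage"],
            }
        return d


def run_psa(
    params: ParameterSet,
    lifetable: LifeTable,
    n_draws: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, PSASummary]:
    """Run the PSA and summarize the CE plane.

    Returns the per-draw samples (draw index, sampled parameter values,
    ΔC, ΔQ, quadrant, below-WTP flag) and a :class:`PSASummary`.
    Identical (seed, n_draws) yield bit-identical output.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    cols = _draw_matrix(params, n_draws, seed)
    names = list(cols)
    values = {k: v[0] for k, v in cols.items()}

    n_resampled = 0
    rows = []
    for i in range(n_draws):
        row = {k: float(values[k][i]) for k in names}
        if "initial_age" in row:
            row["initial_age"] = round(row["initial_age"], 1)
        rounds = 0
        while not _row_feasible(params, row):
            rounds += 1
            if rounds > _MAX_RESAMPLE_ROUNDS:
                raise RuntimeError(
                    f"draw {i}: no feasible parameter set after "
                    f"{_MAX_RESAMPLE_ROUNDS} resampling rounds"
                )
            for k in names:
                row[k] = float(params.distributions[k].sample(cols[k][1]))
            if "initial_age" in row:
                row["initial_age"] = round(row["initial_age"], 1)
        n_resampled += rounds
        rows.append(row)

    records = []
    for i, row in enumerate(rows):
        ps = _apply_draw(params, row)
        uc = run_cohort("UC", ps, lifetable)
        surg = run_cohort("SURGERY", ps, lifetable)
        dc = surg.total_cost - uc.total_cost
        dq = surg.total_qaly - uc.total_qaly
        quadrant, below = classify_ce_plane(
            dc, dq, params.wtp, sw_rule=params.options.sw_below_wtp
        )
        rec = {"draw_index": i, **row}
        rec.update(
            delta_cost=dc, delta_qaly=dq, quadrant=quadrant, below_wtp=below
        )
        records.append(rec)
    samples = pd.DataFrame.from_records(records)

    quadrant = samples["quadrant"].to_numpy()
    below = samples["below_wtp"].to_numpy()
    dc = samples["delta_cost"].to_numpy()
    dq = samples["delta_qaly"].to_numpy()
    se = quadrant == "SE"
    ne_below = (quadrant == "NE") & below
    sw = quadrant == "SW"
    other = ~(se | ne_below | sw)
    ellipse = credible_ellipse(np.column_stack([dq, dc]), 0.95)
    summary = PSASummary(
        n_draws=n_draws,
        prop_se=float(se.mean()),
        prop_ne_below=float(ne_below.mean()),
        prop_sw=float(sw.mean()),
        prop_other=float(other.mean()),
        prop_below_wtp=float(below.mean()),
        prop_cost_saving=float((dc < 0).mean()),
        mean_delta_cost=float(dc.mean()),
        mean_delta_qaly=float(dq.mean()),
        n_resampled=n_resampled,
        ellipse=ellipse,
    )
    return samples, summary


def credible_ellipse(samples: np.ndarray, coverage: float = 0.95) -> Optional[dict]:
    """Bivariate-normal credible ellipse for a cloud of (ΔQ, ΔC) points.

    Returns the sample mean, sample covariance and the chi-square(2 df)
    quantile that scales the covariance to the requested coverage; None
    if the covariance is degenerate.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2 or samples.shape[0] < 3:
        raise ValueError("need an (n >= 3, 2) array of CE-plane points")
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must lie in (0, 1)")
    center = samples.mean(axis=0)
    cov = np.cov(samples, rowvar=False)
    if not np.all(np.isfinite(cov)) or np.linalg.det(cov) <= 0:
        return None
    return {
        "center": center,
        "cov": cov,
        "scale": float(stats.chi2.ppf(coverage, df=2)),
        "coverage": coverage,
    }


def plot_ce_plane(samples: pd.DataFrame, wtp: float, path) -> None:
    """Scatter the PSA draws on the CE plane with the WTP line and ellipse."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dq = samples["delta_qaly"].to_numpy()
    dc = samples["delta_cost"].to_numpy()
    fig, ax = plt.subplots(figsize=(7, 5))
    colors = np.where(samples["below_wtp"], "tab:green", "tab:gray")
    ax.scatter(dq, dc, s=4, c=colors, alpha=0.4, linewidths=0)
    span = np.array([min(dq.min(), 0) * 1.05, max(dq.max(), 0) * 1.05])
    ax.plot(span, wtp * span, "k--", lw=1, label=f"WTP ${wtp:,.0f}/QALY")
    ell = credible_ellipse(np.column_stack([dq, dc]), 0.95)
    if ell is not None:
        vals, vecs = np.linalg.eigh(ell["cov"])
        theta = np.linspace(0, 2 * np.pi, 200)
        circle = np.column_stack([np.cos(theta), np.sin(theta)])
        pts = ell["center"] + circle * np.sqrt(vals * ell["scale"]) @ vecs.T
        ax.plot(pts[:, 0], pts[:, 1], color="tab:blue", lw=1.5,
                label="95% credible ellipse")
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (AUD)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
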
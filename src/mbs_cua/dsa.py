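"""Deterministic one-way sensitivity analysis (tornado diagram).

Each parameter is moved one at a time to its low and high sensitivity
value, both strategies are re-evaluated, and the net monetary benefit at
the willingness-to-pay threshold is recorded; entries sorted by bar
width give the tornado table.  Ranges follow the published protocol:
transition/drift probabilities ±50% of base (clamped to [0, 1]), utility
and disutility weights ±1 standard deviation (clamped to [0, 1]), costs
from 70% of base to base + 1 standard deviation, and structural
parameters (discount rate, horizon, mortality risk ratio, post-surgery
diabetes fraction, the class-cost inflators and initial age) over their
explicitly printed pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cea import compare
from .engine import run_cohort
from .lifetable import LifeTable
from .parameters import ParameterSet

__all__ = ["TornadoEntry", "dsa_ranges", "run_dsa", "plot_tornado"]

# parameter name -> how its one-way range is derived
_PROB_PARAMS = ("up_surgery", "up_uc", "down_uc", "surgical_mortality")
_WEIGHT_PARAMS = (
    "utility_ow",
    "utility_ob1",
    "utility_ob2",
    "utility_ob3",
    "disutility_diabetes",
    "disutility_age",
)
_COST_PARAMS = (
    "surgery_cost_ob1_ob2",
    "surgery_cost_ob3",
    "management_cost_ow",
    "management_cost_ob1",
    "management_cost_ob2_ob3",
    "diabetes_cost",
)

_BASE_VALUES = {
    "up_surgery": lambda p: p.up_surgery,
    "up_uc": lambda p: p.up_uc,
    "down_uc": lambda p: p.down_uc,
    "surgical_mortality": lambda p: p.surgical_mortality,
    "utility_ow": lambda p: p.utilities[0],
    "utility_ob1": lambda p: p.utilities[1],
    "utility_ob2": lambda p: p.utilities[2],
    "utility_ob3": lambda p: p.utilities[3],
    "disutility_diabetes": lambda p: p.disutility_diabetes,
    "disutility_age": lambda p: p.disutility_age,
    "surgery_cost_ob1_ob2": lambda p: p.surgery_cost["OB1"],
    "surgery_cost_ob3": lambda p: p.surgery_cost["OB3"],
    "management_cost_ow": lambda p: p.management_cost[0],
    "management_cost_ob1": lambda p: p.management_cost[1],
    "management_cost_ob2_ob3": lambda p: p.management_cost[2],
    "diabetes_cost": lambda p: p.diabetes_cost,
}


def base_value(params: ParameterSet, name: str) -> float:
    if name in _BASE_VALUES:
        return float(_BASE_VALUES[name](params))
    return float(getattr(params, name))


def dsa_ranges(params: ParameterSet) -> dict[str, tuple[float, float]]:
    """Low/high one-way value per parameter."""
    ranges: dict[str, tuple[float, float]] = {}
    for name in _PROB_PARAMS:
        base = base_value(params, name)
        ranges[name] = (max(0.0, 0.5 * base), min(1.0, 1.5 * base))
    for name in _WEIGHT_PARAMS:
        base = base_value(params, name)
        sd = params.distributions[name].sd if name in params.distributions else 0.0
        ranges[name] = (max(0.0, base - sd), min(1.0, base + sd))
    for name in _COST_PARAMS:
        base = base_value(params, name)
        sd = params.distributions[name].sd if name in params.distributions else 0.0
        ranges[name] = (0.7 * base, base + sd)
    # structural parameters carry explicitly printed pairs
    for name, pair in params.sa_ranges.items():
        ranges[name] = (float(pair[0]), float(pair[1]))
    return ranges


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_input: float
    high_input: float
    nmb_low: float
    nmb_high: float

    @property
    def width(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def _nmb_at(params: ParameterSet, lifetable: LifeTable, name: str, value: float) -> float:
    ps = params.with_value(name, value)
    uc = run_cohort("UC", ps, lifetable)
    surg = run_cohort("SURGERY", ps, lifetable)
    return compare(uc, surg, params.wtp).nmb


def run_dsa(params: ParameterSet, lifetable: LifeTable) -> list[TornadoEntry]:
    """One-way sensitivity of NMB to every parameter.

    Entries are sorted by descending bar width, ties broken
    alphabetically by parameter name.
    """
    entries = []
    for name, (low, high) in dsa_ranges(params).items():
        entries.append(
            TornadoEntry(
                parameter=name,
                low_input=low,
                high_input=high,
                nmb_low=_nmb_at(params, lifetable, name, low),
                nmb_high=_nmb_at(params, lifetable, name, high),
            )
        )
    entries.sort(key=lambda e: (-e.width, e.parameter))
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low_input": e.low_input,
                "high_input": e.high_input,
                "nmb_low": e.nmb_low,
                "nmb_high": e.nmb_high,
                "width": e.width,
            }
            for e in entries
        ]
    )


def plot_tornado(entries: list[TornadoEntry], base_nmb: float, path) -> None:
    """Horizontal tornado plot of NMB excursions about the base case."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = [e for e in entries if e.width > 0][::-1]
    fig, ax = plt.subplots(figsize=(7, 0.35 * max(len(shown), 4) + 1.2))
    for i, e in enumerate(shown):
        lo, hi = sorted((e.nmb_low, e.nmb_high))
        ax.barh(i, hi - lo, left=lo, color="tab:blue", alpha=0.7)
    ax.axvline(base_nmb, color="k", lw=1, ls="--", label="base-case NMB")
    ax.set_yticks(range(len(shown)))
    ax.set_yticklabels([e.parameter for e in shown], fontsize=7)
    ax.set_xlabel("Net monetary benefit (AUD)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
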
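"""Incremental cost-effectiveness statistics for a pair of strategies.

Pairs the surgery and usual-care cohort traces into the standard
decision-analytic summary: incremental cost ΔC and QALYs ΔQ, the ICER
ΔC/ΔQ with dominance labelling, net monetary benefit λ·ΔQ − ΔC at the
willingness-to-pay threshold λ, and the cost-effectiveness-plane
quadrant (ΔQ horizontal, ΔC vertical).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Union

from .engine import CohortTrace

__all__ = [
    "CEAResult",
    "icer",
    "nmb",
    "classify_ce_plane",
    "compare",
    "DOMINANT",
    "DOMINATED",
    "EQUIVALENT",
]

#: Intervention is cheaper and more effective (comparator dominated).
DOMINANT = "dominant"
#: Intervention is costlier and less effective.
DOMINATED = "dominated"
#: No difference in either dimension.
EQUIVALENT = "equivalent"


def icer(delta_cost: float, delta_qaly: float) -> Union[float, str]:
    """ICER ΔC/ΔQ, or a dominance label where the ratio is uninformative."""
    if delta_qaly > 0 and delta_cost < 0:
        return DOMINANT
    if delta_qaly < 0 and delta_cost > 0:
        return DOMINATED
    if delta_qaly == 0 and delta_cost == 0:
        return EQUIVALENT
    if delta_qaly == 0:
        return math.inf if delta_cost > 0 else -math.inf
    return delta_cost / delta_qaly


def nmb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Net monetary benefit λ·ΔQ − ΔC at willingness-to-pay λ."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * delta_qaly - delta_cost


def classify_ce_plane(
    delta_cost: float,
    delta_qaly: float,
    wtp: float,
    sw_rule: str = "always",
) -> tuple[str, bool]:
    """CE-plane quadrant and below-threshold flag for one (ΔC, ΔQ) point.

    Quadrants follow the plotting convention (ΔQ on the horizontal axis,
    ΔC on the vertical): SE is cost-saving and QALY-gaining.  Boundary
    points (ΔC = 0 or ΔQ = 0) deterministically count with the
    cost-saving / QALY-gaining side.  A point is below the threshold if
    it is in SE, in NE with ICER < λ, or in SW — the published composite
    rule; ``sw_rule="nmb"`` instead requires positive NMB in SW.
    """
    east = delta_qaly >= 0
    south = delta_cost <= 0
    quadrant = ("S" if south else "N") + ("E" if east else "W")
    if quadrant == "SE":
        below = True
    elif quadrant == "NE":
        below = delta_qaly > 0 and delta_cost / delta_qaly < wtp
    elif quadrant == "SW":
        below = True if sw_rule == "always" else nmb(delta_cost, delta_qaly, wtp) > 0
    else:  # NW: costlier and less effective
        below = False
    return quadrant, below


@dataclass(frozen=True)
class CEAResult:
    """Paired-arm cost-utility summary."""

    cost_uc: float
    cost_surgery: float
    qaly_uc: float
    qaly_surgery: float
    delta_cost: float
    delta_qaly: float
    icer: Union[float, str]
    nmb: float
    wtp: float
    quadrant: str
    below_wtp: bool

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["icer"], float) and not math.isfinite(d["icer"]):
            d["icer"] = str(d["icer"])
        return d

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def compare(
    uc: CohortTrace, surgery: CohortTrace, wtp: float, sw_rule: str = "always"
) -> CEAResult:
    """Summarize surgery vs usual care from their cohort traces."""
    dc = surgery.total_cost - uc.total_cost
    dq = surgery.total_qaly - uc.total_qaly
    quadrant, below = classify_ce_plane(dc, dq, wtp, sw_rule=sw_rule)
    return CEAResult(
        cost_uc=uc.total_cost,
        cost_surgery=surgery.total_cost,
        qaly_uc=uc.total_qaly,
        qaly_surgery=surgery.total_qaly,
        delta_cost=dc,
        delta_qaly=dq,
        icer=icer(dc, dq),
        nmb=nmb(dc, dq, wtp),
        wtp=wtp,
        quadrant=quadrant,
        below_wtp=below,
    )
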
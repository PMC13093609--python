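"""Markov cohort engine: transition matrices, cohort evolution, accruals.

The cohort starts in a mix of BMI classes and evolves over annual
cycles.  The surgery strategy applies the 12-month post-surgery
class-change matrix once (by default at model entry, combined with
surgical and first-year background mortality as independent competing
risks) and a slow upward BMI drift thereafter; usual care applies a
two-sided annual drift throughout.  Background mortality comes from the
life table, scaled by the diabetes mortality risk ratio for the diabetic
fraction of the cohort.  Per-cycle costs and QALYs accrue on
start-of-cycle occupancy and are discounted at the annual rate with
cycle 0 undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lifetable import LifeTable
from .parameters import ParameterSet, ValidationError
from .states import ALIVE_STATES, N_STATES, HealthState

__all__ = [
    "TransitionMatrix",
    "CohortTrace",
    "build_year1_surgery_matrix",
    "build_drift_matrix",
    "annual_mortality",
    "apply_mortality",
    "cycle_utility",
    "cycle_cost",
    "run_cohort",
]

STRATEGIES = ("SURGERY", "UC")
_ROW_ATOL = 1e-12

TransitionMatrix = np.ndarray  # 5x5 row-stochastic, DEAD absorbing


def _check_strategy(strategy: str) -> None:
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}, got {strategy!r}")


def _validate_matrix(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (N_STATES, N_STATES):
        raise ValidationError(f"transition matrix must be 5x5, got {m.shape}")
    if np.any((m < -_ROW_ATOL) | (m > 1 + _ROW_ATOL)):
        raise ValidationError("transition probabilities must lie in [0, 1]")
    sums = m.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-9):
        raise ValidationError(f"transition matrix rows must sum to 1, got {sums}")
    return m


def build_year1_surgery_matrix(params: ParameterSet) -> TransitionMatrix:
    """12-month post-surgery BMI class-change matrix.

    Rows carry the observed year-1 redistribution for each entry class;
    mortality is not part of this matrix (it is combined at entry via
    :func:`apply_mortality`).  The OW row is identity — no patients enter
    surgery from the overweight class.
    """
    m = np.zeros((N_STATES, N_STATES))
    m[HealthState.OW, HealthState.OW] = 1.0
    m[HealthState.DEAD, HealthState.DEAD] = 1.0
    for origin, row in params.year1_surgery_transitions.items():
        i = HealthState[origin]
        for dest, p in row.items():
            m[i, HealthState[dest]] = p
    return _validate_matrix(m)


def build_drift_matrix(up: float, down: float) -> TransitionMatrix:
    """Annual one-class BMI drift matrix over alive states.

    Each alive row moves up one class with probability ``up``, down one
    with ``down``, and stays otherwise.  At the boundaries (OW cannot
    move down, OB3 cannot move up) the blocked mass stays put.
    """
    if not 0.0 <= up <= 1.0 or not 0.0 <= down <= 1.0:
        raise ValidationError("drift probabilities must lie in [0, 1]")
    if up + down > 1.0 + _ROW_ATOL:
        raise ValidationError(f"up + down must be <= 1, got {up} + {down}")
    m = np.zeros((N_STATES, N_STATES))
    for s in ALIVE_STATES:
        u = up if s < HealthState.OB3 else 0.0
        d = down if s > HealthState.OW else 0.0
        m[s, s] = 1.0 - u - d
        if u:
            m[s, s + 1] = u
        if d:
            m[s, s - 1] = d
    m[HealthState.DEAD, HealthState.DEAD] = 1.0
    return _validate_matrix(m)


def annual_mortality(
    age: float,
    diabetic_fraction: float,
    params: ParameterSet,
    lifetable: LifeTable,
) -> float:
    """Cohort-weighted annual death probability at a given age.

    The diabetic fraction faces the population hazard scaled by the
    diabetes mortality risk ratio (capped at 1); the remainder faces the
    population hazard:  q = f·min(1, qx·RR) + (1−f)·qx.
    """
    if not 0.0 <= diabetic_fraction <= 1.0:
        raise ValidationError("diabetic_fraction must lie in [0, 1]")
    qx = float(lifetable.lookup(age))
    q_dm = min(1.0, qx * params.rr_diabetes_mortality)
    return diabetic_fraction * q_dm + (1.0 - diabetic_fraction) * qx


def apply_mortality(m: TransitionMatrix, q: float) -> TransitionMatrix:
    """Fold an annual death probability into a transition matrix.

    Alive-destination entries of every alive row are scaled by (1−q) and
    the freed mass moves to DEAD; rows stay stochastic.
    """
    if not 0.0 <= q <= 1.0:
        raise ValidationError(f"death probability must lie in [0, 1], got {q}")
    out = np.asarray(m, dtype=float).copy()
    alive = slice(0, HealthState.DEAD)
    out[alive, alive] = out[alive, alive] * (1.0 - q)
    out[alive, HealthState.DEAD] = m[alive, HealthState.DEAD] * (1.0 - q) + q
    return _validate_matrix(out)


def cycle_utility(
    state: HealthState,
    age: float,
    diabetic_fraction: float,
    params: ParameterSet,
) -> float:
    """QALY weight for one year in ``state`` at ``age``.

    The state utility is decremented 0.003 (default) per year of age
    beyond the cohort's entry age and by the diabetes disutility weighted
    by the diabetic fraction, floored at zero.  DEAD contributes 0.
    """
    if state == HealthState.DEAD:
        return 0.0
    u = (
        params.utilities[state]
        - params.disutility_age * (age - params.initial_age)
        - params.disutility_diabetes * diabetic_fraction
    )
    return max(0.0, float(u))


def cycle_cost(
    state: HealthState,
    strategy: str,
    cycle: int,
    entry_state: HealthState,
    diabetic_fraction: float,
    params: ParameterSet,
) -> float:
    """Cost (AUD) accrued for one year in ``state``.

    Surgery cycle 0 charges the first-year surgery cost of the entry
    class (which by default replaces the state management cost, since
    the micro-costed figure covers the six months before and twelve
    months after surgery) plus diabetes costs.  All other cycles charge
    the state management cost — with the OB2/OB3 class-cost inflators
    applied per :class:`~mbs_cua.parameters.ModelOptions` — plus the
    diabetic fraction's diabetes management cost, growing 5% per year of
    diabetes when compounding is enabled.  DEAD contributes 0.
    """
    _check_strategy(strategy)
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    if state == HealthState.DEAD:
        return 0.0
    if params.options.compound_diabetes_cost:
        dm = params.diabetes_cost * (1.0 + params.diabetes_cost_growth) ** cycle
    else:
        dm = params.diabetes_cost
    dm *= diabetic_fraction
    if strategy == "SURGERY" and cycle == 0:
        cost = params.surgery_cost[entry_state.name] + dm
        if not params.options.surgery_cost_replaces_management:
            cost += float(
                params.management_cost[state]
                * params.class_cost_multiplier(cycle)[state]
            )
        return cost
    return float(
        params.management_cost[state] * params.class_cost_multiplier(cycle)[state] + dm
    )


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy and reward accruals for one strategy."""

    strategy: str
    occupancy: np.ndarray  # (T, 5)
    cycle_cost: np.ndarray  # (T,) undiscounted
    cycle_qaly: np.ndarray  # (T,) undiscounted
    disc_cost: np.ndarray  # (T,)
    disc_qaly: np.ndarray  # (T,)
    total_cost: float
    total_qaly: float

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.occupancy, columns=[s.name for s in HealthState]
        )
        df.insert(0, "cycle", np.arange(self.n_cycles))
        df["cycle_cost"] = self.cycle_cost
        df["cycle_qaly"] = self.cycle_qaly
        df["disc_cost"] = self.disc_cost
        df["disc_qaly"] = self.disc_qaly
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _reward_vectors(strategy, cycle, params):
    """Per-alive-state (utility, cost) vectors for one cycle."""
    f = params.diabetic_fraction(strategy, cycle)
    age = params.initial_age + cycle
    u = np.array(
        [cycle_utility(s, age, f, params) for s in ALIVE_STATES]
    )
    if strategy == "SURGERY" and cycle == 0:
        c = None  # entry cost handled on the entry distribution
    else:
        c = np.array(
            [
                cycle_cost(s, strategy, cycle, s, f, params)
                for s in ALIVE_STATES
            ]
        )
    return u, c


def run_cohort(
    strategy: str, params: ParameterSet, lifetable: LifeTable
) -> CohortTrace:
    """Evolve the cohort for one strategy and accrue discounted rewards.

    Rewards accrue on start-of-cycle occupancy.  With the default entry
    timing the surgery arm's cycle-0 occupancy already reflects the
    12-month post-surgery class distribution and the combined surgical +
    first-year background mortality, 1 − (1−p_surg)(1−q); quality-of-life
    gains therefore begin in the year of surgery while management-cost
    savings begin the year after.
    """
    _check_strategy(strategy)
    T = params.effective_horizon()
    r = params.discount_rate
    entry_timing = strategy == "SURGERY" and params.options.year1_timing == "entry"

    n = params.initial_occupancy
    if strategy == "SURGERY":
        year1 = build_year1_surgery_matrix(params)
        q0 = annual_mortality(
            params.initial_age, params.diabetic_fraction(strategy, 0), params, lifetable
        )
        q_entry = 1.0 - (1.0 - params.surgical_mortality) * (1.0 - q0)
        entry_matrix = apply_mortality(year1, q_entry)
        drift = build_drift_matrix(params.up_surgery, params.down_surgery)
        if entry_timing:
            n = n @ entry_matrix
    else:
        drift = build_drift_matrix(params.up_uc, params.down_uc)

    occ = np.zeros((T, N_STATES))
    cyc_cost = np.zeros(T)
    cyc_qaly = np.zeros(T)
    entry_cost = params.entry_surgery_cost()

    def _step(n_curr, cycle):
        """Transition out of ``cycle`` into the next one."""
        if strategy == "SURGERY" and not entry_timing and cycle == 0:
            return n_curr @ entry_matrix
        f = params.diabetic_fraction(strategy, cycle)
        q = annual_mortality(params.initial_age + cycle, f, params, lifetable)
        return n_curr @ apply_mortality(drift, q)

    for t in range(T):
        occ[t] = n
        u_vec, c_vec = _reward_vectors(strategy, t, params)
        cyc_qaly[t] = float(n[:4] @ u_vec)
        if c_vec is None:
            f = params.diabetic_fraction(strategy, 0)
            dm = params.diabetes_cost  # growth factor is 1 at cycle 0
            cost0 = entry_cost + f * dm
            if not params.options.surgery_cost_replaces_management:
                mgmt = params.management_cost * params.class_cost_multiplier(0)
                cost0 += float(n[:4] @ mgmt)
            cyc_cost[t] = cost0
        else:
            cyc_cost[t] = float(n[:4] @ c_vec)
        if t < T - 1:
            n = _step(n, t)

    disc = (1.0 + r) ** -np.arange(T)
    weights = np.ones(T)
    tail_cost = tail_qaly = 0.0
    if params.options.half_cycle_correction:
        weights[0] = 0.5
        n_end = _step(occ[-1], T - 1)
        u_vec, c_vec = _reward_vectors(strategy, T, params)
        tail_qaly = 0.5 * float(n_end[:4] @ u_vec) * (1.0 + r) ** -T
        tail_cost = 0.5 * float(n_end[:4] @ c_vec) * (1.0 + r) ** -T

    disc_cost = cyc_cost * disc * weights
    disc_qaly = cyc_qaly * disc * weights
    return CohortTrace(
        strategy=strategy,
        occupancy=occ,
        cycle_cost=cyc_cost,
        cycle_qaly=cyc_qaly,
        disc_cost=disc_cost,
        disc_qaly=disc_qaly,
        total_cost=float(disc_cost.sum() + tail_cost),
        total_qaly=float(disc_qaly.sum() + tail_qaly),
    )
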
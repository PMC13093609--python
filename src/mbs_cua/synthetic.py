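"""Synthetic inputs and a microsimulation oracle.

Everything the pipeline needs that is not a printed point value is
generated here: the packaged Gompertz life table (interpolated between
the two printed anchor rates), named parameter fixtures used across the
test suite, and an individual-level microsimulation that realizes the
cohort model patient by patient.  The microsimulation shares the cohort
engine's per-cycle probabilities, costs and utilities exactly, so its
Monte-Carlo means are an unbiased brute-force check on the cohort
engine's expectations.

The cohort model treats the diabetic share of survivors as a static
mixing fraction f each cycle.  The microsimulation realizes this by
redrawing each patient's diabetes indicator Bernoulli(f) independently
every cycle: because mortality, cost and utility are all linear in the
indicator, the per-cycle expectations then match the cohort's exactly.
(A once-per-patient indicator would interact with the diabetes mortality
risk ratio and let the surviving diabetic fraction drift below f,
biasing the comparison.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .engine import (
    annual_mortality,
    build_drift_matrix,
    build_year1_surgery_matrix,
    cycle_cost,
    cycle_utility,
)
from .lifetable import DEFAULT_ANCHORS, LifeTable, build_lifetable
from .parameters import ParameterSet, default_parameters
from .states import HealthState

__all__ = [
    "generate_default_lifetable",
    "constant_lifetable",
    "simulate_individuals",
    "MicrosimResult",
    "make_fixture",
    "FIXTURE_NAMES",
]


def generate_default_lifetable(min_age: int = 18, max_age: int = 90) -> LifeTable:
    """Gompertz life table through the printed anchors (ages 18–90).

    Ends at 90 so that engine lookups clamp to the age-90 rate for older
    cycles, matching the modelled horizon "to age 90".
    """
    return build_lifetable(DEFAULT_ANCHORS, max_age=max_age, min_age=min_age)


def constant_lifetable(q: float, min_age: int = 0, max_age: int = 120) -> LifeTable:
    """Flat annual death probability at every age (0 disables mortality)."""
    ages = np.arange(min_age, max_age + 1, dtype=float)
    return LifeTable(ages, np.full(ages.size, float(q)))


@dataclass(frozen=True)
class MicrosimResult:
    """Monte-Carlo means and standard errors of discounted totals."""

    n: int
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    states: Optional[np.ndarray] = None  # (n, T) int codes if requested


def simulate_individuals(
    strategy: str,
    params: ParameterSet,
    lifetable: LifeTable,
    n: int,
    seed: int = 0,
    keep_states: bool = False,
) -> MicrosimResult:
    """Simulate ``n`` patients through the model, cycle by cycle.

    Uses exactly the cohort engine's per-cycle transition probabilities,
    costs and utilities (same entry timing, same diabetic-fraction rule)
    with an independent Bernoulli diabetes indicator per patient-cycle.
    Returns discounted per-patient totals as means with standard errors.
    Identical seeds give identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if params.options.half_cycle_correction:
        raise NotImplementedError("microsimulation assumes no half-cycle correction")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA11CE)))
    T = params.effective_horizon()
    r = params.discount_rate
    a0 = params.initial_age
    dead = int(HealthState.DEAD)

    if strategy == "SURGERY":
        drift = build_drift_matrix(params.up_surgery, params.down_surgery)
        year1 = build_year1_surgery_matrix(params)
    elif strategy == "UC":
        drift = build_drift_matrix(params.up_uc, params.down_uc)
        year1 = None
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    cum_drift = np.cumsum(drift[:4, :], axis=1)
    cum_year1 = np.cumsum(year1[:4, :], axis=1) if year1 is not None else None

    # entry states drawn from the initial distribution
    entry = rng.choice(4, size=n, p=params.initial_distribution)
    state = entry.copy()
    cost = np.zeros(n)
    qaly = np.zeros(n)

    # per-cycle reward lookup tables (alive states), split into the
    # diabetes-independent part and the diabetes add-on, so the Bernoulli
    # indicator can be applied per patient
    surgery_entry = strategy == "SURGERY" and params.options.year1_timing == "entry"

    def _death_probs(cycle):
        qx = float(lifetable.lookup(a0 + cycle))
        return min(1.0, qx * params.rr_diabetes_mortality), qx

    def _apply_entry(state, alive):
        """Year-1 surgery redistribution with surgical + background mortality."""
        q_dm, qx = _death_probs(0)
        f0 = params.diabetic_fraction("SURGERY", 0)
        diabetic = rng.random(n) < f0
        q_bg = np.where(diabetic, q_dm, qx)
        q_comb = 1.0 - (1.0 - params.surgical_mortality) * (1.0 - q_bg)
        dies = rng.random(n) < q_comb
        survivors = alive & ~dies
        u = rng.random(n)
        new = state.copy()
        for s in range(4):
            mask = survivors & (state == s)
            if mask.any():
                new[mask] = np.searchsorted(cum_year1[s], u[mask], side="right")
        new[alive & dies] = dead
        return new

    if surgery_entry:
        state = _apply_entry(state, np.ones(n, dtype=bool))

    for t in range(T):
        disc = (1.0 + r) ** -t
        f = params.diabetic_fraction(strategy, t)
        alive = state != dead
        diabetic = rng.random(n) < f

        # rewards on start-of-cycle state
        age = a0 + t
        u_free = np.array([cycle_utility(s, age, 0.0, params) for s in HealthState])
        u_dm = np.array([cycle_utility(s, age, 1.0, params) for s in HealthState])
        u_now = np.where(diabetic, u_dm[state], u_free[state])
        qaly += disc * np.where(alive, u_now, 0.0)

        if strategy == "SURGERY" and t == 0:
            # surgery cost of the entry class is charged to everyone who
            # entered (as in the cohort accrual), plus diabetes costs
            c_entry = np.array(
                [
                    cycle_cost(HealthState(s), "SURGERY", 0, HealthState(s), 0.0, params)
                    if s != HealthState.OW
                    else 0.0
                    for s in range(4)
                ]
            )
            dm0 = params.diabetes_cost
            cost += c_entry[entry] + np.where(diabetic, dm0, 0.0)
        else:
            c_free = np.array(
                [cycle_cost(HealthState(s), strategy, t, HealthState(s), 0.0, params) for s in range(4)]
                + [0.0]
            )
            c_dm_only = np.array(
                [
                    cycle_cost(HealthState(s), strategy, t, HealthState(s), 1.0, params)
                    - c_free[s]
                    for s in range(4)
                ]
                + [0.0]
            )
            c_now = c_free[state] + np.where(diabetic, c_dm_only[state], 0.0)
            cost += disc * np.where(alive, c_now, 0.0)

        if t == T - 1:
            break

        # transition: death first, then BMI drift among survivors
        if strategy == "SURGERY" and not surgery_entry and t == 0:
            state = _apply_entry(state, alive)
            continue
        q_dm, qx = _death_probs(t)
        q_i = np.where(diabetic, q_dm, qx)
        dies = alive & (rng.random(n) < q_i)
        survivors = alive & ~dies
        u = rng.random(n)
        new = state.copy()
        for s in range(4):
            mask = survivors & (state == s)
            if mask.any():
                new[mask] = np.searchsorted(cum_drift[s], u[mask], side="right")
        new[dies] = dead
        state = new

    return MicrosimResult(
        n=n,
        mean_cost=float(cost.mean()),
        mean_qaly=float(qaly.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        states=None,
    )


FIXTURE_NAMES = (
    "table1_base",
    "no_mortality",
    "no_discount",
    "degenerate_psa",
    "two_cycle_hand_case",
)


def make_fixture(name: str) -> ParameterSet:
    """Named deterministic parameter fixtures used across the test suite.

    - ``table1_base``: the packaged point estimates.
    - ``no_mortality``: surgical mortality and the diabetes mortality
      ratio neutralized (pair with ``constant_lifetable(0.0)``).
    - ``no_discount``: base values with a 0% discount rate.
    - ``degenerate_psa``: every PSA distribution replaced by a point mass
      at its mean.
    - ``two_cycle_hand_case``: a 2-cycle, zero-mortality, undiscounted
      setup with flat costs/utilities whose totals are hand-computable
      (pair with ``constant_lifetable(0.0)``).
    """
    if name == "table1_base":
        return default_parameters()
    if name == "no_mortality":
        return default_parameters(surgical_mortality=0.0, rr_diabetes_mortality=1.0)
    if name == "no_discount":
        return default_parameters(discount_rate=0.0)
    if name == "degenerate_psa":
        base = default_parameters()
        from .distributions import DistributionSpec

        fixed = {
            k: DistributionSpec("fixed", mean=float(v.mean) if v.kind != "triangular" else float(v.mode))
            for k, v in base.distributions.items()
        }
        return base.replace(distributions=fixed)
    if name == "two_cycle_hand_case":
        return default_parameters(
            horizon_cycles=2,
            discount_rate=0.0,
            initial_distribution=np.array([0.0, 0.0, 1.0, 0.0]),
            up_uc=0.5,
            down_uc=0.0,
            up_surgery=0.0,
            surgical_mortality=0.0,
            rr_diabetes_mortality=1.0,
            disutility_age=0.0,
            disutility_diabetes=0.0,
            diabetes_cost=0.0,
            inflator_ob2=0.0,
            inflator_ob3=0.0,
        )
    raise KeyError(f"unknown fixture {name!r}; valid names: {FIXTURE_NAMES}")
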
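"""Markov cohort engine: matrices, mortality, rewards, cohort evolution."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbs_cua.engine import (
    annual_mortality,
    apply_mortality,
    build_drift_matrix,
    build_year1_surgery_matrix,
    cycle_cost,
    cycle_utility,
    run_cohort,
)
from mbs_cua.parameters import ValidationError, default_parameters
from mbs_cua.states import HealthState
from mbs_cua.synthetic import constant_lifetable, make_fixture

OW, OB1, OB2, OB3, DEAD = HealthState


def with_options(params, **opts):
    return params.replace(options=dataclasses.replace(params.options, **opts))


class TestTransitionMatrices:
    def test_year1_rows_match_observed_redistribution(self, params):
        m = build_year1_surgery_matrix(params)
        np.testing.assert_allclose(m[OB3], [0.34, 0.23, 0.19, 0.24, 0.0])
        np.testing.assert_allclose(m[OB2], [0.64, 0.31, 0.05, 0.0, 0.0])
        np.testing.assert_allclose(m[OB1], [1.0, 0.0, 0.0, 0.0, 0.0])
        np.testing.assert_allclose(m[OW], [1.0, 0.0, 0.0, 0.0, 0.0])  # unused
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_year1_row_sum_violation_rejected(self, params):
        bad = params.to_dict()
        from mbs_cua.parameters import load_parameters

        bad["year1_surgery_transitions"]["OB2"]["OW"] = 0.5
        with pytest.raises(ValidationError):
            load_parameters(bad)

    def test_drift_interior_row(self):
        m = build_drift_matrix(0.018, 0.0)
        np.testing.assert_allclose(m[OB2], [0.0, 0.0, 0.982, 0.018, 0.0])

    def test_drift_boundary_blocked_mass_stays(self):
        """OB3 cannot move up: the up-mass is reassigned to 'stay'."""
        m = build_drift_matrix(0.0603, 0.0557)
        np.testing.assert_allclose(m[OB3], [0.0, 0.0, 0.0557, 0.9443, 0.0])
        np.testing.assert_allclose(m[OW], [0.9397, 0.0603, 0.0, 0.0, 0.0])

    def test_zero_drift_is_identity_on_alive(self):
        np.testing.assert_allclose(build_drift_matrix(0.0, 0.0), np.eye(5))

    def test_up_plus_down_over_one_rejected(self):
        with pytest.raises(ValidationError):
            build_drift_matrix(0.6, 0.6)

    @given(up=st.floats(0, 1), down=st.floats(0, 1))
    @settings(max_examples=60, derandomize=True)
    def test_drift_always_row_stochastic(self, up, down):
        if up + down > 1:
            return
        m = build_drift_matrix(up, down)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((m >= 0) & (m <= 1))
        np.testing.assert_allclose(m[DEAD], [0, 0, 0, 0, 1])


class TestMortality:
    def test_nondiabetic_limit_is_population_rate(self, params, lifetable):
        assert annual_mortality(30, 0.0, params, lifetable) == pytest.approx(0.00053)

    def test_diabetic_rate_scaled_by_risk_ratio(self, params, lifetable):
        q = annual_mortality(30, 1.0, params, lifetable)
        assert q == pytest.approx(0.00053 * 1.54, rel=1e-9)

    def test_unit_risk_ratio_is_identity(self, lifetable):
        params = default_parameters(rr_diabetes_mortality=1.0)
        q = annual_mortality(70, 1.0, params, lifetable)
        assert q == pytest.approx(float(lifetable.lookup(70)))

    def test_scaled_rate_capped_at_one(self, lifetable):
        params = default_parameters(rr_diabetes_mortality=10.0)
        assert annual_mortality(90, 1.0, params, lifetable) <= 1.0

    def test_apply_mortality_scale_and_append(self):
        row = build_drift_matrix(0.018, 0.0)
        q = 0.0008162
        out = apply_mortality(row, q)
        np.testing.assert_allclose(
            out[OB2],
            [0.0, 0.0, 0.982 * (1 - q), 0.018 * (1 - q), q],
            rtol=1e-12,
        )
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_apply_mortality_limits(self):
        m = build_drift_matrix(0.1, 0.1)
        np.testing.assert_allclose(apply_mortality(m, 0.0), m)
        dead_all = apply_mortality(m, 1.0)
        for s in (OW, OB1, OB2, OB3):
            np.testing.assert_allclose(dead_all[s], [0, 0, 0, 0, 1])
        with pytest.raises(ValidationError):
            apply_mortality(m, 1.5)


class TestCycleRewards:
    def test_utility_at_entry_age(self, params):
        assert cycle_utility(OW, 52.4, 0.0, params) == pytest.approx(0.782)

    def test_diabetes_disutility_subtracted(self, params):
        assert cycle_utility(OW, 52.4, 1.0, params) == pytest.approx(0.666)

    def test_age_decrement_anchored_at_entry(self, params):
        u = cycle_utility(OB2, 62.4, 0.5, params)
        assert u == pytest.approx(0.599 - 0.003 * 10 - 0.116 * 0.5)

    def test_utility_floored_at_zero(self, params):
        ps = default_parameters(disutility_age=0.05)
        assert cycle_utility(OB3, 52.4 + 30, 1.0, ps) == 0.0

    def test_dead_contributes_nothing(self, params):
        assert cycle_utility(DEAD, 60.0, 1.0, params) == 0.0
        assert cycle_cost(DEAD, "UC", 3, DEAD, 1.0, params) == 0.0

    def test_surgery_entry_cost_plus_diabetes(self, params):
        c = cycle_cost(OB3, "SURGERY", 0, OB3, 1.0, params)
        assert c == pytest.approx(18242 + 3997)

    def test_uc_base_year_cost(self, params):
        assert cycle_cost(OW, "UC", 0, OW, 0.0, params) == pytest.approx(6762)

    def test_compound_inflators(self, params):
        """Compounding mode: 8926*1.10^2 + 3997*1.05^2 = 15207.15."""
        ps = with_options(params, class_inflator_mode="compound")
        c = cycle_cost(OB3, "UC", 2, OB3, 1.0, ps)
        assert c == pytest.approx(15207.1483, abs=0.01)

    def test_differential_inflators(self, params):
        """Default mode: static class multipliers, compounding diabetes cost."""
        c = cycle_cost(OB3, "UC", 2, OB3, 1.0, params)
        assert c == pytest.approx(8926 * 1.10 + 3997 * 1.05**2, rel=1e-12)
        c2 = cycle_cost(OB2, "UC", 7, OB2, 0.0, params)
        assert c2 == pytest.approx(8926 * 1.05, rel=1e-12)

    def test_static_diabetes_cost_option(self, params):
        ps = with_options(params, compound_diabetes_cost=False)
        c = cycle_cost(OB1, "UC", 10, OB1, 1.0, ps)
        assert c == pytest.approx(7574 + 3997, rel=1e-12)


class TestRunCohort:
    def test_occupancy_conserved_and_dead_monotone(self, params, lifetable):
        for strategy in ("UC", "SURGERY"):
            trace = run_cohort(strategy, params, lifetable)
            np.testing.assert_allclose(
                trace.occupancy.sum(axis=1), 1.0, atol=1e-9
            )
            assert np.all(np.diff(trace.occupancy[:, DEAD]) >= -1e-12)

    def test_totals_equal_sum_of_discounted_accruals(self, params, lifetable):
        trace = run_cohort("UC", params, lifetable)
        assert trace.total_cost == pytest.approx(trace.disc_cost.sum(), abs=1e-6)
        assert trace.total_qaly == pytest.approx(trace.disc_qaly.sum(), abs=1e-9)

    def test_two_cycle_hand_case(self, zero_mortality):
        """Frozen pencil-and-paper evaluation of a 2-cycle setup.

        UC: starts in OB2 (u 0.599, cost 8926), moves up with p=0.5.
        Cycle 1 mix is half OB2 / half OB3 with equal costs, so
        QALYs = 0.599 + (0.599+0.550)/2 = 1.1735 and cost = 2*8926.
        Surgery: the year-1 matrix sends OB2 to (0.64, 0.31, 0.05) over
        (OW, OB1, OB2); with zero drift both cycles share that mix.
        """
        ps = make_fixture("two_cycle_hand_case")
        uc = run_cohort("UC", ps, zero_mortality)
        assert uc.total_qaly == pytest.approx(1.1735, abs=1e-12)
        assert uc.total_cost == pytest.approx(17852.0, abs=1e-9)
        surg = run_cohort("SURGERY", ps, zero_mortality)
        u_mix = 0.64 * 0.782 + 0.31 * 0.730 + 0.05 * 0.599
        assert surg.total_qaly == pytest.approx(2 * u_mix, abs=1e-12)
        c_mix = 0.64 * 6762 + 0.31 * 7574 + 0.05 * 8926
        assert surg.total_cost == pytest.approx(15734 + c_mix, abs=1e-9)

    def test_geometric_series_limit(self, zero_mortality):
        """No mortality, drift or growth: totals follow the closed form.

        With a static cohort the discounted totals are reward * annuity
        where annuity = sum_{t<T} (1+r)^-t.
        """
        ps = make_fixture("table1_base").replace(
            up_uc=0.0,
            down_uc=0.0,
            surgical_mortality=0.0,
            rr_diabetes_mortality=1.0,
            disutility_age=0.0,
            inflator_ob2=0.0,
            inflator_ob3=0.0,
        )
        ps = with_options(ps, compound_diabetes_cost=False)
        trace = run_cohort("UC", ps, zero_mortality)
        r, T = ps.discount_rate, ps.horizon_cycles
        annuity = (1 - (1 + r) ** -T) / (1 - 1 / (1 + r))
        pi = ps.initial_distribution
        u = float(pi @ ps.utilities) - ps.disutility_diabetes
        c = float(pi @ ps.management_cost) + ps.diabetes_cost
        assert trace.total_qaly == pytest.approx(u * annuity, rel=1e-12)
        assert trace.total_cost == pytest.approx(c * annuity, rel=1e-12)

    def test_discount_rate_monotonicity(self, lifetable):
        lo = run_cohort("UC", default_parameters(discount_rate=0.03), lifetable)
        hi = run_cohort("UC", default_parameters(discount_rate=0.07), lifetable)
        assert hi.total_cost < lo.total_cost
        assert hi.total_qaly < lo.total_qaly

    def test_everyone_dies_immediately_accrues_only_cycle_zero(self, params):
        """With q=1 the cohort is absorbed after one cycle; DEAD accrues 0."""
        lt = constant_lifetable(1.0)
        trace = run_cohort("UC", params, lt)
        assert np.all(trace.cycle_cost[1:] == 0)
        assert np.all(trace.cycle_qaly[1:] == 0)
        np.testing.assert_allclose(trace.occupancy[1:, DEAD], 1.0)

    def test_surgery_cycle0_reflects_post_surgery_distribution(
        self, params, lifetable
    ):
        trace = run_cohort("SURGERY", params, lifetable)
        # OW occupancy at entry: 0.795*0.34 + 0.200*0.64 + 0.005*1, scaled
        # by survival of the combined surgical + background entry risk
        q0 = annual_mortality(52.4, 1.0, params, lifetable)
        survival = (1 - params.surgical_mortality) * (1 - q0)
        expected_ow = (0.795 * 0.34 + 0.200 * 0.64 + 0.005 * 1.0) * survival
        assert trace.occupancy[0, OW] == pytest.approx(expected_ow, rel=1e-12)
        assert trace.occupancy[0, DEAD] > 0  # surgical + background mortality

    def test_surgery_cycle0_cost_is_entry_cost_plus_diabetes(
        self, params, lifetable
    ):
        trace = run_cohort("SURGERY", params, lifetable)
        assert trace.cycle_cost[0] == pytest.approx(
            params.entry_surgery_cost() + params.diabetes_cost
        )

    def test_first_cycle_timing_defers_redistribution(self, params, lifetable):
        ps = with_options(params, year1_timing="first-cycle")
        trace = run_cohort("SURGERY", ps, lifetable)
        np.testing.assert_allclose(
            trace.occupancy[0], np.append(params.initial_distribution, 0.0)
        )
        default = run_cohort("SURGERY", params, lifetable)
        np.testing.assert_allclose(
            trace.occupancy[1], default.occupancy[0], rtol=1e-12
        )

    def test_half_cycle_correction_changes_totals(self, params, lifetable):
        hcc = with_options(params, half_cycle_correction=True)
        a = run_cohort("UC", params, lifetable)
        b = run_cohort("UC", hcc, lifetable)
        assert b.total_qaly != pytest.approx(a.total_qaly)
        # first cycle half-weighted, half a terminal cycle added
        assert b.disc_qaly[0] == pytest.approx(0.5 * a.disc_qaly[0])

    def test_trace_frame_schema(self, params, lifetable):
        df = run_cohort("UC", params, lifetable).to_frame()
        assert list(df.columns[:6]) == ["cycle", "OW", "OB1", "OB2", "OB3", "DEAD"]
        assert len(df) == params.horizon_cycles
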
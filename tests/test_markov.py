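"""Markov cohort engine: matrices, traces, rewards, discounting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tavicea as tv
from conftest import random_valid_config
from tavicea.markov import (
    accumulate,
    build_transition_matrix,
    cycle_rewards,
    death_probability,
    discount_factor,
    run_arm,
    run_cohort,
)
from tavicea.states import ALIVE_INDICES, DEAD_INDEX, Arm


class TestDiscountFactor:
    def test_known_values(self):
        assert discount_factor(0, 0.065) == 1.0
        assert discount_factor(1, 0.065) == pytest.approx(0.938967, abs=5e-7)

    @given(t=st.integers(0, 100))
    def test_rate_zero_is_unity(self, t):
        assert discount_factor(t, 0.0) == 1.0

    def test_negative_cycle_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.065)


class TestTransitionMatrix:
    def test_rows_sum_to_one_and_dead_absorbing(self, default_cfg):
        for arm in (Arm.TAVI, Arm.SAVR):
            m = build_transition_matrix(arm, 1, default_cfg).matrix
            np.testing.assert_allclose(m.sum(axis=1), np.ones(9), atol=1e-12)
            assert m[DEAD_INDEX, DEAD_INDEX] == 1.0
            assert m[DEAD_INDEX, :DEAD_INDEX].sum() == 0.0

    def test_identical_death_probability_across_alive_states(self, default_cfg):
        m = build_transition_matrix(Arm.TAVI, 3, default_cfg).matrix
        deaths = m[list(ALIVE_INDICES), DEAD_INDEX]
        assert np.ptp(deaths) == 0.0

    def test_nyha1_row_support(self, default_cfg):
        m = build_transition_matrix(Arm.TAVI, 1, default_cfg).matrix
        support = np.nonzero(m[0])[0]
        np.testing.assert_array_equal(support, [0, 4, DEAD_INDEX])

    def test_zero_stroke_rate_makes_stroke_states_unreachable(self, default_cfg):
        default_cfg.events.TAVI.stroke = 0.0
        m = build_transition_matrix(Arm.TAVI, 1, default_cfg).matrix
        assert m[0:4, 4:8].sum() == 0.0

    def test_multiplicative_competing_risk_composition(self, default_cfg):
        # death 0.25, annualized five-year stroke 0.153 -> 0.0327
        m = build_transition_matrix(Arm.TAVI, 1, default_cfg).matrix
        p_stroke = 1 - 0.847**0.2
        assert m[0, 4] == pytest.approx(0.75 * p_stroke, rel=1e-12)
        assert m[0, 4] == pytest.approx(0.0245, abs=5e-5)

    def test_stroke_states_never_revert(self, default_cfg):
        m = build_transition_matrix(Arm.SAVR, 2, default_cfg).matrix
        assert m[4:8, 0:4].sum() == 0.0

    def test_user_table_long_term_mortality(self, default_cfg):
        default_cfg.knobs.longterm_death_mode = "USER_TABLE"
        default_cfg.knobs.death_table = {"TAVI": [[2, 0.4], [10, 0.6]]}
        assert death_probability(Arm.TAVI, 1, default_cfg) == 0.25  # entry year
        assert death_probability(Arm.TAVI, 2, default_cfg) == 0.4
        assert death_probability(Arm.TAVI, 30, default_cfg) == 0.6


class TestCycleRewards:
    def test_stroke_disutility_floored_and_deferred(self, default_cfg):
        # NYHA4 + stroke from cycle 2: max(0, 0.47 - 0.39)
        r3 = cycle_rewards(Arm.TAVI, 3, default_cfg)
        assert r3.qaly[7] == pytest.approx(0.08, abs=1e-12)
        # rehabilitation year: decrement deferred
        r1 = cycle_rewards(Arm.TAVI, 1, default_cfg)
        assert r1.qaly[5] == pytest.approx(0.72, rel=1e-12)

    def test_floor_at_zero(self, default_cfg):
        default_cfg.utilities.stroke_disutility = 0.9
        r = cycle_rewards(Arm.TAVI, 2, default_cfg)
        assert (r.qaly[4:8] == 0.0).all()

    def test_dead_rewards_are_zero(self, default_cfg):
        for cycle in (1, 2, 10):
            r = cycle_rewards(Arm.SAVR, cycle, default_cfg)
            assert r.qaly[DEAD_INDEX] == 0.0
            assert r.cost[DEAD_INDEX] == 0.0

    def test_rehospitalization_recurring_knob(self, default_cfg):
        on = cycle_rewards(Arm.TAVI, 2, default_cfg).cost[0]
        default_cfg.knobs.rehospitalization_recurring = False
        off2 = cycle_rewards(Arm.TAVI, 2, default_cfg).cost[0]
        off1 = cycle_rewards(Arm.TAVI, 1, default_cfg).cost[0]
        assert on > 0.0 and off2 == 0.0 and off1 == on


class TestRunCohort:
    def test_all_dead_entry_stays_dead(self, default_cfg):
        entry = tv.StateDistribution(np.eye(9)[DEAD_INDEX])
        trace = run_cohort(entry, Arm.TAVI, default_cfg)
        assert trace.occupancy[:, DEAD_INDEX].min() == 1.0

    def test_geometric_survival_decay(self, default_cfg):
        default_cfg.events.TAVI.stroke = 0.0  # pure death process
        trace = run_cohort(
            tv.entry_distribution(Arm.TAVI, default_cfg), Arm.TAVI, default_cfg
        )
        s = trace.survival
        for t in range(1, trace.stop_cycle + 1):
            assert s[t] == pytest.approx(0.75 * 0.75**t, rel=1e-9)

    def test_rows_sum_to_one_and_mortality_monotone(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            cfg = random_valid_config(rng)
            for arm in (Arm.TAVI, Arm.SAVR):
                trace = run_cohort(tv.entry_distribution(arm, cfg), arm, cfg)
                sums = trace.occupancy.sum(axis=1)
                np.testing.assert_allclose(sums, 1.0, atol=1e-9)
                dead = trace.occupancy[:, DEAD_INDEX]
                assert (np.diff(dead) >= -1e-15).all()

    def test_non_convergent_config_warns_not_raises(self, default_cfg):
        e = default_cfg.entry.TAVI
        e.NYHA1, e.death = 0.61, 0.0
        default_cfg.knobs.annual_death_override = 0.0
        trace = run_cohort(
            tv.entry_distribution(Arm.TAVI, default_cfg), Arm.TAVI, default_cfg
        )
        assert not trace.converged
        assert trace.warnings and "max_cycles" in trace.warnings[0]

    def test_death_override_one_kills_cohort_in_one_cycle(self, default_cfg):
        default_cfg.knobs.annual_death_override = 1.0
        trace = run_cohort(
            tv.entry_distribution(Arm.TAVI, default_cfg), Arm.TAVI, default_cfg
        )
        assert trace.stop_cycle == 1
        assert trace.survival[1] == 0.0


class TestAccumulate:
    def test_single_cycle_closed_form(self, default_cfg):
        # 100% NYHA1 at entry, one cycle horizon: QALYs = 0.72/1.065
        e = default_cfg.entry.TAVI
        e.NYHA1, e.NYHA2, e.NYHA3, e.NYHA4, e.death = 1.0, 0.0, 0.0, 0.0, 0.0
        default_cfg.knobs.annual_death_override = 0.0
        default_cfg.econ.max_cycles = 1
        default_cfg.events.TAVI.stroke = 0.0
        res = run_arm(Arm.TAVI, default_cfg)
        assert res.discounted_qalys == pytest.approx(0.72 / 1.065, rel=1e-12)

    def test_zero_utilities_give_zero_qalys(self, default_cfg):
        for cls in ("I", "II", "III", "IV"):
            setattr(default_cfg.utilities.mean_by_nyha, cls, 0.0)
            setattr(default_cfg.utilities.sd_by_nyha, cls, 0.0)
        assert run_arm(Arm.TAVI, default_cfg).discounted_qalys == 0.0

    def test_geometric_series_closed_form(self, default_cfg):
        # single-utility, constant-hazard, stroke-free cohort:
        # QALYs = u * s0 * sum_t ((1-p)/(1+r))^t
        u, p, r, s0 = 0.6, 0.25, 0.065, 0.75
        for cls in ("I", "II", "III", "IV"):
            setattr(default_cfg.utilities.mean_by_nyha, cls, u)
            setattr(default_cfg.utilities.sd_by_nyha, cls, 0.0)
        default_cfg.events.TAVI.stroke = 0.0
        res = run_arm(Arm.TAVI, default_cfg)
        T = res.trace.stop_cycle
        expected = u * s0 * sum(((1 - p) / (1 + r)) ** t for t in range(1, T + 1))
        assert res.discounted_qalys == pytest.approx(expected, rel=1e-9)

    def test_zero_rate_discounted_equals_undiscounted(self, default_cfg):
        default_cfg.econ.discount_rate = 0.0
        res = run_arm(Arm.SAVR, default_cfg)
        occ = res.trace.occupancy
        undisc = sum(
            float(occ[t] @ cycle_rewards(Arm.SAVR, t, default_cfg).qaly)
            for t in range(1, occ.shape[0])
        )
        assert res.discounted_qalys == pytest.approx(undisc, rel=1e-12)

    def test_costs_at_least_acute_and_discounting_shrinks_qalys(
        self, base_results, default_cfg
    ):
        for arm, res in base_results.items():
            acute = tv.acute_cost(arm, default_cfg).expected_cost
            assert res.discounted_cost >= acute
            assert res.discounted_qalys <= res.life_years

    def test_half_cycle_correction_increases_qalys(self, default_cfg):
        off = run_arm(Arm.TAVI, default_cfg).discounted_qalys
        default_cfg.econ.half_cycle_correction = True
        on = run_arm(Arm.TAVI, default_cfg).discounted_qalys
        assert on > off  # averaging with the richer previous row adds mass

    def test_trace_csv_round_trip(self, default_cfg, tmp_path):
        import pandas as pd

        res = run_arm(Arm.TAVI, default_cfg)
        path = tmp_path / "trace.csv"
        res.trace.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns[1:]) == [s.value for s in tv.STATES]
        np.testing.assert_allclose(df.iloc[:, 1:].to_numpy(), res.trace.occupancy)
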
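"""Survival, reward and QALY accounting, event counts, increments."""

import numpy as np
import pytest

from acsmarkov import run_model
from acsmarkov.markov import CohortTrace
from acsmarkov.outcomes import (
    compute_qalys,
    compute_survival,
    cycle_reward,
    events_per_cohort,
    incremental,
    run_arm,
    state_utilities,
)
from acsmarkov.parameters import ModelSettings, random_parameter_set, set_base_value
from acsmarkov.scenarios import scenario
from acsmarkov.states import HealthState as S


def closed_form_year1_qaly(p_mi, p_stroke, p_ua, p_death, u, d_mi=0.127,
                           d_stroke=0.139, d_ua=0.117):
    """Half the utility-weighted end-of-year-1 occupancy, straight from the
    published tables: an oracle independent of the Markov engine."""
    ef = 1 - p_mi - p_stroke - p_ua - p_death
    return 0.5 * (ef * u + p_mi * (u - d_mi) + p_stroke * (u - d_stroke)
                  + p_ua * (u - d_ua))


class TestStateUtilities:
    def test_event_states_subtract_disutility(self, base_params):
        w = state_utilities(base_params.utilities, "chm")
        assert w[S.EVENT_FREE] == 0.818
        assert w[S.NEW_MI] == w[S.POST_MI] == pytest.approx(0.818 - 0.127)
        assert w[S.NEW_STROKE] == pytest.approx(0.818 - 0.139)
        assert w[S.NEW_UA] == pytest.approx(0.818 - 0.117)
        assert w[S.DEAD] == 0.0

    def test_one_off_mode_restores_post_state_utility(self, base_params):
        w = state_utilities(base_params.utilities, "conv", "one-off")
        assert w[S.NEW_MI] == pytest.approx(0.809 - 0.127)
        assert w[S.POST_MI] == w[S.POST_STROKE] == w[S.POST_UA] == 0.809


class TestCycleReward:
    def test_all_event_free_gives_arm_utility(self, base_params):
        row = np.zeros(8)
        row[S.EVENT_FREE] = 1.0
        assert cycle_reward(row, base_params.utilities, "chm") == 0.818
        assert cycle_reward(row, base_params.utilities, "conv") == 0.809

    def test_all_dead_gives_zero(self, base_params):
        row = np.zeros(8)
        row[S.DEAD] = 1.0
        assert cycle_reward(row, base_params.utilities, "chm") == 0.0

    def test_year1_occupancy_reward(self, base_params):
        # 2 x the closed-form year-1 QALY for the CHM arm
        row = np.zeros(8)
        row[S.EVENT_FREE], row[S.NEW_MI] = 0.9677, 0.005
        row[S.NEW_STROKE], row[S.NEW_UA], row[S.DEAD] = 0.0074, 0.0149, 0.005
        assert cycle_reward(row, base_params.utilities, "chm") == pytest.approx(
            0.8105, abs=5e-4)


class TestSurvival:
    def test_no_mortality_keeps_everyone_alive(self):
        res = run_model(scenario("zero_mortality"))
        assert (res.chm.survival_curve == 1.0).all()
        assert res.chm.survival_10y_pct == 100.0

    def test_terminal_value_is_percent_of_last_cycle(self, base_results):
        curve, pct = compute_survival(base_results.chm.trace)
        assert pct == pytest.approx(curve[-1] * 100)
        assert (np.diff(curve) <= 0).all()


class TestQalys:
    def test_year1_matches_closed_form_oracle(self, base_params, base_results):
        for arm, u in (("chm", 0.818), ("conv", 0.809)):
            probs = base_params.arm(arm).base_values()
            oracle = closed_form_year1_qaly(
                probs["p_nonfatal_mi"], probs["p_nonfatal_stroke"],
                probs["p_nonfatal_ua"], probs["p_death"], u)
            assert base_results.arm(arm).qaly_year1 == pytest.approx(oracle, abs=1e-12)

    def test_discounting_never_increases_qalys(self, base_params, base_results):
        ps = base_params.model_copy(deep=True)
        ps.settings = ModelSettings(discount_rate=0.0)
        undiscounted = run_model(ps)
        for arm in ("chm", "conv"):
            assert undiscounted.arm(arm).qaly_total >= base_results.arm(arm).qaly_total

    def test_half_cycle_variants_ordering(self, base_params):
        totals = {}
        for convention in ("none", "entry-half", "trapezoid"):
            ps = base_params.model_copy(deep=True)
            ps.settings = ModelSettings(half_cycle=convention)
            totals[convention] = run_model(ps).chm.qaly_total
        # rewards decline over time, so averaging with the richer earlier
        # cycle (trapezoid) exceeds end-of-cycle accounting except for the
        # halved first cycle; 'none' is always the largest
        assert totals["none"] > totals["trapezoid"] > totals["entry-half"]

    def test_monotone_in_utilities_disutilities_and_mortality(self, base_params):
        for seed in range(15):
            ps = random_parameter_set(seed)
            base = run_model(ps).chm.qaly_total
            up = set_base_value(ps, "utilities.u_event_free_chm",
                                min(ps.utilities.u_event_free_chm.base + 0.02, 1.0))
            assert run_model(up).chm.qaly_total >= base
            worse_d = set_base_value(ps, "utilities.d_ua",
                                     ps.utilities.d_ua.base + 0.02)
            assert run_model(worse_d).chm.qaly_total <= base
            deadlier = set_base_value(ps, "long_term.event_free.p_death",
                                      ps.long_term.event_free.p_death.base + 0.02)
            assert run_model(deadlier).chm.qaly_total <= base

    def test_zero_horizon_one_total_is_discounted_year1(self, base_params):
        ps = base_params.model_copy(deep=True)
        ps.settings = ModelSettings(horizon_years=1)
        res = run_model(ps)
        r = ps.settings.discount_rate
        assert res.chm.qaly_total == pytest.approx(res.chm.qaly_year1 / (1 + r))


class TestEventsAndIncrements:
    def test_identical_traces_give_zero_differences(self, base_results):
        counts = events_per_cohort(base_results.chm.trace, base_results.chm.trace)
        assert set(counts.values()) == {0}
        inc = incremental(base_results.chm, base_results.chm)
        assert set(inc.values()) == {0.0}

    def test_horizon_mismatch_rejected(self, base_results):
        short = CohortTrace(occupancy=base_results.chm.trace.occupancy[:5])
        with pytest.raises(ValueError):
            events_per_cohort(short, base_results.conv.trace)

    def test_equal_arms_scenario_has_null_increments(self):
        res = run_model(scenario("equal_arms"))
        assert res.incremental["qaly_total"] == 0.0
        assert set(res.events_per_1000.values()) == {0}

    def test_dominance_when_chm_probabilities_elementwise_lower(self, base_params):
        # the published CHM column is elementwise below the conventional one
        res = run_model(base_params)
        assert res.incremental["qaly_total"] > 0
        assert res.incremental["survival_10y_pct_points"] > 0
        # and reversing the arms reverses every increment
        rev = run_model(scenario("reversed_dominance"))
        assert rev.incremental["qaly_total"] == pytest.approx(
            -res.incremental["qaly_total"])

    def test_counts_round_to_whole_patients(self, base_results):
        assert all(isinstance(v, int) for v in base_results.events_per_1000.values())
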
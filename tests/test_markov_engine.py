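"""Semi-Markov cohort mechanics, cost and QALY accounting."""

import numpy as np
import pytest

from cdxcea.markov_engine import (CycleConfig, StrategyDefinition,
                                  TreatmentLine, accumulate_costs,
                                  accumulate_qalys, run_cohort)
from cdxcea.survival_models import (TransitionSchedule, WeibullModel,
                                    to_transition_schedule)


def const_schedule(p, horizon):
    return TransitionSchedule(tuple([p] * horizon))


def bsc_line(p_death, horizon, cost=0.0, utility=0.0, ae=0.0):
    return TreatmentLine("BSC", os_schedule=const_schedule(p_death, horizon),
                         cost_admin_per_cycle=cost, cost_nonadmin_per_cycle=cost,
                         admin_cycles=horizon, utility=utility,
                         ae_disutility_total=ae)


def single_line_strategy(line, horizon, test_cost=0.0, name="s"):
    return StrategyDefinition(name, [(1.0, (line,))], test_cost=test_cost)


class TestCohortDynamics:
    def test_no_events_cohort_stays_put(self):
        H = 60
        line = TreatmentLine("L1", os_schedule=const_schedule(0.0, H),
                             pfs_schedule=const_schedule(0.0, H))
        strat = StrategyDefinition("s", [(1.0, (line, bsc_line(0.0, H)))])
        trace = run_cohort(strat, CycleConfig(horizon=H))
        occ = trace.arms[0].occupancy
        assert occ[H, 0, H] == pytest.approx(1.0)
        assert trace.dead()[H] == 0.0

    def test_immediate_death_absorbing(self):
        line = bsc_line(1.0, 2)
        trace = run_cohort(single_line_strategy(line, 2), CycleConfig(horizon=2))
        assert trace.dead()[1] == pytest.approx(1.0)
        assert trace.dead()[2] == pytest.approx(1.0)

    def test_two_cycle_toy_hand_computed(self):
        """p_pfs=0.5, p_death=0.2 → stay 0.5, die 0.2, progress to BSC 0.3."""
        H = 2
        chemo = TreatmentLine("chemo", os_schedule=const_schedule(0.2, H),
                              pfs_schedule=const_schedule(0.5, H))
        strat = StrategyDefinition("toy", [(1.0, (chemo, bsc_line(0.1, H)))])
        trace = run_cohort(strat, CycleConfig(horizon=H))
        arm = trace.arms[0]
        assert arm.occupancy[1, 0, 1] == pytest.approx(0.5)
        assert arm.dead[1] == pytest.approx(0.2)
        assert arm.occupancy[1, 1, 0] == pytest.approx(0.3)

    def test_occupancy_conserved_and_death_monotone(self):
        H = 60
        rng = np.random.default_rng(9)
        l1 = TreatmentLine("a", os_schedule=TransitionSchedule(rng.uniform(0, 0.1, H)),
                           pfs_schedule=TransitionSchedule(rng.uniform(0, 0.3, H)))
        l2 = TreatmentLine("b", os_schedule=TransitionSchedule(rng.uniform(0, 0.2, H)),
                           pfs_schedule=TransitionSchedule(rng.uniform(0, 0.3, H)))
        strat = StrategyDefinition("s", [(1.0, (l1, l2, bsc_line(0.15, H)))])
        trace = run_cohort(strat, CycleConfig(horizon=H))
        arm = trace.arms[0]
        total = arm.alive() + arm.dead
        assert np.allclose(total, 1.0, atol=1e-10)
        assert np.all(np.diff(arm.dead) >= -1e-15)

    def test_survival_consistency_without_progression(self):
        """With progression disabled the alive fraction is the OS curve."""
        H = 60
        m = WeibullModel(1.3, 14)
        sched = to_transition_schedule(m, H)
        line = TreatmentLine("only", os_schedule=sched, admin_cycles=H)
        trace = run_cohort(single_line_strategy(line, H), CycleConfig(horizon=H))
        assert np.allclose(trace.alive(), m.survival(np.arange(H + 1)), atol=1e-10)

    def test_clock_resets_on_line_entry(self):
        """A line entered at cycle k sees its schedule from index 0."""
        H = 5
        first = TreatmentLine(
            "first", os_schedule=const_schedule(0.0, H),
            pfs_schedule=TransitionSchedule((0.0, 0.0, 1.0, 0.0, 0.0)))
        # distinctive death prob at clock 0 of the second line
        second = bsc_line(0.0, H)
        second = TreatmentLine("BSC", os_schedule=TransitionSchedule(
            (0.7, 0.0, 0.0, 0.0, 0.0)), admin_cycles=H)
        strat = StrategyDefinition("s", [(1.0, (first, second))])
        trace = run_cohort(strat, CycleConfig(horizon=H))
        arm = trace.arms[0]
        # whole cohort progresses during cycle 2, enters BSC with clock 0 at
        # cycle 3, and 70% die during cycle 3
        assert arm.occupancy[3, 1, 0] == pytest.approx(1.0)
        assert arm.dead[4] == pytest.approx(0.7)

    def test_negative_progression_clamped(self):
        H = 3
        line = TreatmentLine("x", os_schedule=const_schedule(0.5, H),
                             pfs_schedule=const_schedule(0.2, H))
        strat = StrategyDefinition("s", [(1.0, (line, bsc_line(0.0, H)))])
        trace = run_cohort(strat, CycleConfig(horizon=H))
        assert trace.arms[0].occupancy[:, 1, :].sum() == 0.0  # nobody progressed

    def test_short_schedule_rejected(self):
        line = bsc_line(0.1, 10)
        with pytest.raises(ValueError, match="shorter than horizon"):
            run_cohort(single_line_strategy(line, 10), CycleConfig(horizon=30))


class TestCosts:
    def test_oral_therapy_all_cycles_undiscounted(self):
        H = 60
        line = TreatmentLine("ERT", os_schedule=const_schedule(0.0, H),
                             cost_admin_per_cycle=2113, cost_nonadmin_per_cycle=2113,
                             admin_cycles=H, is_oral=True)
        strat = single_line_strategy(line, H)
        cfg = CycleConfig(horizon=H, annual_discount_rate=0.0)
        trace = run_cohort(strat, cfg)
        assert accumulate_costs(trace, strat, cfg) == pytest.approx(60 * 2113)

    def test_test_cost_only_is_undiscounted(self):
        H = 12
        line = bsc_line(0.0, H)
        strat = single_line_strategy(line, H, test_cost=104.0)
        cfg = CycleConfig(horizon=H, annual_discount_rate=0.07)
        trace = run_cohort(strat, cfg)
        assert accumulate_costs(trace, strat, cfg) == pytest.approx(104.0)

    def test_chemo_admin_then_nonadmin(self):
        H = 10
        line = TreatmentLine("CPEM", os_schedule=const_schedule(0.0, H),
                             cost_admin_per_cycle=4157, cost_nonadmin_per_cycle=503,
                             admin_cycles=4)
        strat = single_line_strategy(line, H)
        cfg = CycleConfig(horizon=H, annual_discount_rate=0.0)
        trace = run_cohort(strat, cfg)
        assert accumulate_costs(trace, strat, cfg) == pytest.approx(
            4 * 4157 + 6 * 503)


class TestQalys:
    def test_one_year_at_fixed_utility(self):
        H = 12
        line = bsc_line(0.0, H, utility=0.6)
        strat = single_line_strategy(line, H)
        cfg = CycleConfig(horizon=H, annual_discount_rate=0.0)
        trace = run_cohort(strat, cfg)
        assert accumulate_qalys(trace, strat, cfg) == pytest.approx(0.6)

    def test_oral_adjustment_enters_effective_utility(self):
        line = TreatmentLine("ERT", os_schedule=const_schedule(0.0, 12),
                             utility=0.6532, utility_adjustment=0.02, is_oral=True)
        assert line.effective_utility == pytest.approx(0.6732)

    def test_effective_utility_guard(self):
        line = TreatmentLine("bad", os_schedule=const_schedule(0.0, 12),
                             utility=0.5, utility_adjustment=0.9)
        with pytest.raises(ValueError, match="effective utility"):
            _ = line.effective_utility

    def test_ae_disutility_entry_cycle_only(self):
        H = 12
        cfg = CycleConfig(horizon=H, annual_discount_rate=0.0)
        with_ae = bsc_line(0.0, H, utility=0.6, ae=0.09)
        without = bsc_line(0.0, H, utility=0.6)
        s_ae = single_line_strategy(with_ae, H)
        s_no = single_line_strategy(without, H)
        q_ae = accumulate_qalys(run_cohort(s_ae, cfg), s_ae, cfg)
        q_no = accumulate_qalys(run_cohort(s_no, cfg), s_no, cfg)
        assert q_no - q_ae == pytest.approx(0.09 / 12)


class TestDiscountingAndMixing:
    def _value(self, r, half_cycle=False):
        H = 24
        line = bsc_line(0.02, H, cost=1000.0, utility=0.6)
        strat = single_line_strategy(line, H)
        cfg = CycleConfig(horizon=H, annual_discount_rate=r,
                          half_cycle_correction=half_cycle)
        trace = run_cohort(strat, cfg)
        return (accumulate_costs(trace, strat, cfg),
                accumulate_qalys(trace, strat, cfg))

    def test_totals_decrease_with_discount_rate(self):
        vals = [self._value(r) for r in (0.0, 0.03, 0.06, 0.10)]
        costs = [v[0] for v in vals]
        qalys = [v[1] for v in vals]
        assert all(b < a for a, b in zip(costs, costs[1:]))
        assert all(b < a for a, b in zip(qalys, qalys[1:]))

    def test_zero_rate_reproduces_raw_sums(self):
        H = 24
        line = bsc_line(0.02, H, cost=1000.0, utility=0.6)
        strat = single_line_strategy(line, H)
        cfg = CycleConfig(horizon=H, annual_discount_rate=0.0)
        trace = run_cohort(strat, cfg)
        alive = trace.arms[0].alive()[:H]
        assert accumulate_costs(trace, strat, cfg) == pytest.approx(
            1000.0 * alive.sum())
        assert accumulate_qalys(trace, strat, cfg) == pytest.approx(
            0.6 / 12 * alive.sum())

    def test_half_cycle_correction_shifts_discounting(self):
        plain = self._value(0.06)[0]
        hcc = self._value(0.06, half_cycle=True)[0]
        assert hcc < plain  # mid-cycle discounting discounts cycle 0 too

    def test_strategy_mixing_linearity(self):
        H = 24
        a = bsc_line(0.05, H, cost=500.0, utility=0.5)
        b = bsc_line(0.10, H, cost=2000.0, utility=0.7)
        cfg = CycleConfig(horizon=H)
        mixed = StrategyDefinition("mix", [(0.3, (a,)), (0.7, (b,))])
        only_a = single_line_strategy(a, H, name="a")
        only_b = single_line_strategy(b, H, name="b")
        cm = accumulate_costs(run_cohort(mixed, cfg), mixed, cfg)
        ca = accumulate_costs(run_cohort(only_a, cfg), only_a, cfg)
        cb = accumulate_costs(run_cohort(only_b, cfg), only_b, cfg)
        assert cm == pytest.approx(0.3 * ca + 0.7 * cb)

    def test_arm_weights_must_sum_to_one(self):
        line = bsc_line(0.0, 5)
        with pytest.raises(ValueError, match="weights sum"):
            StrategyDefinition("bad", [(0.3, (line,)), (0.3, (line,))])
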
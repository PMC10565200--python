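"""Markov cohort engine: matrices, propagation, discounting, microsim oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graftcea.engine import (
    InfeasibleTransitionError,
    build_matrices,
    discount_factor,
    run_cohort,
)
from graftcea.mortality import MortalitySchedule
from graftcea.parameters import ModelSettings, StrategyParameters, total_revision_surgery_cost


def make_strategy(**overrides):
    defaults = dict(
        graft_price_per_head=1000.0,
        annual_re_revision_probability=0.0064,
        surgery_base_cost=10_000.0,
        annual_post_revision_care_cost=54.19,
        utility_post_revision=0.685,
        utility_re_revision=0.397,
    )
    defaults.update(overrides)
    return StrategyParameters(**defaults)


def flat_schedule(horizon, q_post, q_rev):
    return MortalitySchedule(
        post_revision_death=np.full(horizon, q_post),
        revision_state_death=np.full(horizon, q_rev),
    )


class TestBuildMatrices:
    def test_post_revision_row_is_forced_complement(self):
        matrices = build_matrices(
            make_strategy(annual_re_revision_probability=0.0064),
            flat_schedule(1, 0.0195, 0.047),
        )
        assert matrices.matrices[0, 0] == pytest.approx([0.9741, 0.0064, 0.0195])

    def test_no_transitions_keeps_cohort_alive_in_post_revision(self):
        matrices = build_matrices(
            make_strategy(annual_re_revision_probability=0.0), flat_schedule(3, 0.0, 0.0)
        )
        # post-revision is self-absorbing; a re-revision year is followed by
        # a post-revision year (the first row position is "to post_revision")
        assert matrices.matrices[0, 0, 0] == 1.0
        assert matrices.matrices[0, 1, 0] == 1.0

    def test_infeasible_row_raises_naming_the_year(self):
        with pytest.raises(InfeasibleTransitionError, match="year 1"):
            build_matrices(
                make_strategy(annual_re_revision_probability=0.5), flat_schedule(1, 0.6, 0.6)
            )

    def test_certain_death_year_is_fully_absorbing(self):
        matrices = build_matrices(
            make_strategy(annual_re_revision_probability=0.3), flat_schedule(1, 1.0, 1.0)
        )
        assert np.array_equal(matrices.matrices[0, 0], [0.0, 0.0, 1.0])
        assert np.array_equal(matrices.matrices[0, 1], [0.0, 0.0, 1.0])

    def test_rows_sum_to_one(self):
        matrices = build_matrices(make_strategy(), flat_schedule(10, 0.05, 0.08))
        assert np.allclose(matrices.matrices.sum(axis=2), 1.0, atol=1e-12)


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "year, rate, expected",
        [(0, 0.035, 1.0), (1, 0.035, 0.96618), (7, 0.0, 1.0)],
    )
    def test_values(self, year, rate, expected):
        assert discount_factor(year, rate) == pytest.approx(expected, abs=5e-6)

    def test_negative_year_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.035)


class TestRunCohort:
    def test_mass_conserved_and_death_monotone(self):
        matrices = build_matrices(make_strategy(), flat_schedule(25, 0.03, 0.06))
        trace = run_cohort(make_strategy(), matrices, ModelSettings())
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(np.diff(trace.occupancy[:, 2]) >= -1e-12)

    def test_closed_form_qalys_without_mortality_or_discounting(self):
        strategy = make_strategy(annual_re_revision_probability=0.0)
        matrices = build_matrices(strategy, flat_schedule(10, 0.0, 0.0))
        trace = run_cohort(strategy, matrices, ModelSettings(discount_rate=0.0))
        # 10 post-revision years plus the year-0 revision-year utility
        assert trace.total_qaly == pytest.approx(10 * 0.685 + 0.397, abs=1e-12)
        trace_no_y0 = run_cohort(
            strategy, matrices, ModelSettings(discount_rate=0.0), year0_utility=False
        )
        assert trace_no_y0.total_qaly == pytest.approx(10 * 0.685, abs=1e-12)

    def test_discounting_never_increases_totals(self):
        strategy = make_strategy()
        matrices = build_matrices(strategy, flat_schedule(20, 0.02, 0.05))
        discounted = run_cohort(strategy, matrices, ModelSettings(discount_rate=0.035))
        undiscounted = run_cohort(strategy, matrices, ModelSettings(discount_rate=0.0))
        assert discounted.total_cost < undiscounted.total_cost
        assert discounted.total_qaly < undiscounted.total_qaly

    def test_no_revisions_incremental_cost_is_exactly_the_graft_increment(self):
        # with no re-revisions in either arm the only cost difference is the
        # year-0 graft bill, whatever the mortality and discounting
        schedule = flat_schedule(15, 0.03, 0.06)
        settings_ = ModelSettings(discount_rate=0.035)
        traces = {}
        for name, price in (("decell", 10_040.72), ("fresh", 709.71)):
            strategy = make_strategy(
                graft_price_per_head=price, annual_re_revision_probability=0.0
            )
            traces[name] = run_cohort(strategy, build_matrices(strategy, schedule), settings_)
        d_cost = traces["decell"].total_cost - traces["fresh"].total_cost
        assert d_cost == pytest.approx(2.43 * (10_040.72 - 709.71), rel=1e-12)
        assert traces["decell"].total_qaly == pytest.approx(traces["fresh"].total_qaly, abs=1e-12)

    @given(
        q_post=st.floats(min_value=0.0, max_value=0.3),
        q_rev=st.floats(min_value=0.0, max_value=0.4),
        p_rev=st.floats(min_value=0.0, max_value=0.3),
        rate=st.floats(min_value=0.0, max_value=0.1),
    )
    @settings(derandomize=True, max_examples=30)
    def test_qalys_bounded_by_discount_sum_times_max_utility(self, q_post, q_rev, p_rev, rate):
        strategy = make_strategy(annual_re_revision_probability=p_rev)
        matrices = build_matrices(strategy, flat_schedule(12, q_post, q_rev))
        trace = run_cohort(strategy, matrices, ModelSettings(discount_rate=rate))
        bound = sum(discount_factor(t, rate) for t in range(13)) * 0.685
        assert trace.total_qaly <= bound + 1e-9

    def test_trace_frame_shape(self):
        strategy = make_strategy()
        matrices = build_matrices(strategy, flat_schedule(5, 0.02, 0.05))
        frame = run_cohort(strategy, matrices, ModelSettings()).to_frame()
        assert list(frame.columns) == [
            "year", "post_revision", "re_revision", "death", "discounted_cost", "discounted_qaly",
        ]
        assert len(frame) == 6


def microsimulate(strategy, matrices, settings_, n, seed):
    """Individual-level Monte-Carlo oracle for the cohort engine.

    Simulates n independent patients through the same yearly transition
    matrices, starting in the revision state at year 0, and accrues the
    same discounted rewards.  Returns occupancy fractions and per-patient
    discounted totals.
    """
    rng = np.random.default_rng(seed)
    horizon = matrices.horizon
    surgery = total_revision_surgery_cost(strategy)
    care = strategy.annual_post_revision_care_cost
    u_post, u_rev = strategy.utility_post_revision, strategy.utility_re_revision

    states = np.ones(n, dtype=np.int64)  # everyone has surgery at year 0
    occupancy = np.zeros((horizon + 1, 3))
    occupancy[0, 1] = 1.0
    cost = np.full(n, surgery)
    qaly = np.full(n, u_rev)
    for year in range(1, horizon + 1):
        cum = matrices.matrices[year - 1].cumsum(axis=1)
        u = rng.random(n)
        states = (u[:, None] > cum[states]).sum(axis=1)
        occupancy[year] = np.bincount(states, minlength=3) / n
        factor = discount_factor(year, settings_.discount_rate)
        cost += factor * np.where(states == 0, care, np.where(states == 1, surgery, 0.0))
        qaly += factor * np.where(states == 0, u_post, np.where(states == 1, u_rev, 0.0))
    return occupancy, cost, qaly


class TestMicrosimulationOracle:
    def test_cohort_trace_matches_individual_simulation(self):
        """5-year toy model, 100k simulated patients, agreement within 3 MC SEs."""
        n = 100_000
        strategy = make_strategy(annual_re_revision_probability=0.08)
        matrices = build_matrices(strategy, flat_schedule(5, 0.05, 0.1))
        settings_ = ModelSettings(discount_rate=0.035)
        trace = run_cohort(strategy, matrices, settings_)
        occupancy, cost, qaly = microsimulate(strategy, matrices, settings_, n, seed=20260925)

        for year in range(6):
            for state in range(3):
                p = trace.occupancy[year, state]
                se = max(np.sqrt(p * (1 - p) / n), 1e-6)
                assert abs(occupancy[year, state] - p) < 3 * se, (year, state)

        for expected, sample in ((trace.total_cost, cost), (trace.total_qaly, qaly)):
            se = sample.std(ddof=1) / np.sqrt(n)
            assert abs(sample.mean() - expected) < 3 * se
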
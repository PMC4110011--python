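"""Sufficient statistics and the three confidence-interval constructions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multisense.stats import (
    BOUND_METHODS,
    ConfigError,
    RewardRange,
    RewardRangeError,
    SufficientStats,
    UndefinedStatisticError,
    ci_bernstein,
    ci_chebyshev,
    ci_student,
    confidence_interval,
    interval_rows,
    q_value,
    sample_std,
    t_quantile_table,
    update_stats,
)

rewards_lists = st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=50)


class TestUpdateStats:
    def test_first_sample(self):
        s = update_stats(SufficientStats(), 1.0)
        assert (s.n, s.sum_r, s.sum_r2) == (1, 1.0, 1.0)

    def test_sequence_gives_sample_mean(self, make_stats):
        s = make_stats([0, 1, 1, 0])
        assert q_value(s) == 0.5

    def test_matches_two_pass_mean(self, rng, make_stats):
        xs = rng.uniform(0, 1, size=1000)
        s = make_stats(xs)
        assert abs(q_value(s) - xs.mean()) < 1e-12

    def test_out_of_range_reward_rejected(self):
        with pytest.raises(RewardRangeError):
            update_stats(SufficientStats(), 1.5)
        with pytest.raises(RewardRangeError):
            update_stats(SufficientStats(), -3.0, RewardRange(0, 2))

    @given(rewards_lists)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mean_and_sd_match_two_pass_oracles(self, xs):
        s = SufficientStats()
        for x in xs:
            s = update_stats(s, x)
        assert q_value(s) == pytest.approx(float(np.mean(xs)), rel=1e-9, abs=1e-12)
        if len(xs) >= 2:
            assert sample_std(s) == pytest.approx(float(np.std(xs, ddof=1)), rel=1e-9, abs=1e-9)


class TestPointStatistics:
    def test_q_value_examples(self):
        assert q_value(SufficientStats(4, 2.0, 1.2)) == 0.5
        assert q_value(SufficientStats(1, 0.3, 0.09)) == pytest.approx(0.3)

    def test_q_value_empty_cell(self):
        with pytest.raises(UndefinedStatisticError):
            q_value(SufficientStats())

    def test_sample_std_closed_form(self):
        # (sum_r2 - n q^2)/(n-1) = (1.2 - 4*0.25)/3 = 0.2/3
        assert sample_std(SufficientStats(4, 2.0, 1.2)) == pytest.approx(math.sqrt(0.2 / 3))

    def test_sample_std_constant_rewards(self, make_stats):
        assert sample_std(make_stats([0.7] * 10)) == 0.0

    def test_sample_std_large_sample_two_pass(self, rng, make_stats):
        xs = np.clip(rng.normal(0.5, 0.15, size=10_000), 0, 1)
        s = make_stats(xs)
        assert sample_std(s) == pytest.approx(float(np.std(xs, ddof=1)), rel=1e-9)

    def test_sample_std_needs_two_samples(self):
        with pytest.raises(UndefinedStatisticError):
            sample_std(SufficientStats(1, 0.5, 0.25))


class TestStudentInterval:
    def test_closed_form_example(self):
        # q = 0.5, s = sqrt(0.2/3), t_{0.025,3} = 3.18245
        ci = ci_student(SufficientStats(4, 2.0, 1.2), 0.05)
        assert ci.lower == pytest.approx(0.089, abs=5e-4)
        assert ci.upper == pytest.approx(0.911, abs=5e-4)

    def test_zero_variance_degenerates_to_point(self, make_stats):
        ci = ci_student(make_stats([0.5] * 5), 0.05)  # dyadic reward: variance exactly 0
        assert ci.lower == ci.upper == 0.5
        # non-dyadic rewards accumulate float dust; the interval stays a near-point
        ci = ci_student(make_stats([0.4] * 5), 0.05)
        assert ci.length < 1e-6
        assert ci.lower == pytest.approx(0.4) and ci.upper == pytest.approx(0.4)

    def test_single_sample_unbounded(self):
        ci = ci_student(SufficientStats(1, 0.5, 0.25), 0.05)
        assert ci.is_unbounded and ci.lower == -math.inf and ci.upper == math.inf

    def test_invalid_alpha(self):
        with pytest.raises(ConfigError):
            ci_student(SufficientStats(4, 2.0, 1.2), 1.5)


class TestChebyshevInterval:
    def test_closed_form_example(self):
        # half-width = 1 / (2 sqrt(25 * 0.04)) = 0.5
        s = SufficientStats(25, 12.5, 6.5)
        ci = ci_chebyshev(s, 0.04, RewardRange(0, 1))
        assert ci.lower == pytest.approx(0.0)
        assert ci.upper == pytest.approx(1.0)

    def test_halfwidth_shrinks_with_n(self):
        widths = [ci_chebyshev(SufficientStats(n, n * 0.5, n * 0.3), 0.05).length for n in (10, 100, 10_000)]
        assert widths[0] > widths[1] > widths[2]
        assert widths[2] < 0.15

    def test_empty_cell_unbounded(self):
        assert ci_chebyshev(SufficientStats(), 0.05).is_unbounded


class TestBernsteinInterval:
    def test_zero_variance_closed_form(self):
        # s = 0: half-width = 3 ln(60) / 100
        s = SufficientStats(100, 50.0, 25.0)  # all rewards 0.5, zero variance
        ci = ci_bernstein(s, 0.05)
        assert ci.length / 2 == pytest.approx(3 * math.log(60) / 100)

    def test_halfwidth_monotone_in_sample_sd(self):
        n = 100
        lo_var = SufficientStats(n, 50.0, 25.0)  # s = 0
        hi_var = SufficientStats(n, 50.0, 25.0 + (n - 1) * 0.25)  # s = 0.5
        assert ci_bernstein(lo_var, 0.05).length < ci_bernstein(hi_var, 0.05).length

    def test_single_sample_unbounded(self):
        assert ci_bernstein(SufficientStats(1, 1.0, 1.0), 0.05).is_unbounded


@pytest.mark.parametrize("method", BOUND_METHODS)
def test_interval_length_non_increasing_in_n(method):
    """For fixed sample SD, more samples can only tighten the interval."""
    q, sd = 0.5, 0.2
    prev = math.inf
    for n in (2, 5, 10, 100, 1000, 10_000):
        s = SufficientStats(n, n * q, (n - 1) * sd**2 + n * q**2)
        length = confidence_interval(s, 0.05, method).length
        assert length <= prev + 1e-12
        prev = length


@pytest.mark.parametrize("method", BOUND_METHODS)
@given(st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=2, max_size=30))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_finite_intervals_bracket_the_sample_mean(method, xs):
    s = SufficientStats()
    for x in xs:
        s = update_stats(s, x)
    ci = confidence_interval(s, 0.05, method)
    assert ci.lower <= q_value(s) <= ci.upper


class TestVectorisedRows:
    """interval_rows must agree cell-for-cell with the scalar constructors."""

    @pytest.mark.parametrize("method", BOUND_METHODS)
    def test_matches_scalar_path(self, rng, method):
        n = rng.integers(0, 50, size=40)
        cells = []
        for ni in n:
            xs = rng.uniform(0, 1, size=ni)
            cells.append(SufficientStats(int(ni), float(xs.sum()), float((xs**2).sum())))
        lo, up = interval_rows(
            np.array([c.n for c in cells], dtype=float),
            np.array([c.sum_r for c in cells]),
            np.array([c.sum_r2 for c in cells]),
            method=method,
            alpha=0.1,
        )
        for i, c in enumerate(cells):
            ref = confidence_interval(c, 0.1, method)
            assert lo[i] == pytest.approx(ref.lower, rel=1e-9, abs=1e-12)
            assert up[i] == pytest.approx(ref.upper, rel=1e-9, abs=1e-12)

    def test_t_quantile_table_exact_region(self):
        from scipy import stats as sps

        tq = t_quantile_table(0.05, 500)
        dofs = np.array([1, 2, 10, 100, 500])
        assert np.allclose(tq[dofs], sps.t.ppf(0.975, dofs))

    def test_t_quantile_asymptotic_region_accurate(self):
        from scipy import stats as sps

        tq = t_quantile_table(0.05, 20_000)
        for dof in (5000, 20_000):
            assert tq[dof] == pytest.approx(float(sps.t.ppf(0.975, dof)), rel=1e-5)
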
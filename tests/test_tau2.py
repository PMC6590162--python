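import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from hetci.simulate import SimCondition, simulate_meta
from hetci.tau2 import (
    BracketError,
    Interval,
    IntervalStatus,
    MetaSample,
    WeightScheme,
    generalized_q,
    genq_ci,
    genq_lambdas,
    genq_statistic,
    genq_tail_probability,
    paule_mandel,
    q_profile_ci,
    weighted_chisq_sf,
    weighted_mean,
)


class TestWeightedMean:
    def test_equal_weights(self):
        assert weighted_mean([0.0, 2.0], [1.0, 1.0]) == 1.0

    def test_single_value(self):
        assert weighted_mean([5.0], [0.3]) == 5.0

    def test_unequal_weights(self):
        assert weighted_mean([1.0, 2.0, 3.0], [1.0, 2.0, 1.0]) == 2.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            weighted_mean([], [])

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_mean([1.0, 2.0], [1.0, 0.0])


class TestGeneralizedQ:
    def test_identical_effects_give_zero(self):
        s = MetaSample(y=[1.3, 1.3, 1.3], var=[0.5, 1.0, 2.0])
        assert generalized_q(s, 0.0) == pytest.approx(0.0, abs=1e-12)
        assert generalized_q(s, 0.7) == pytest.approx(0.0, abs=1e-12)

    def test_cochran_q_at_zero(self, simple_sample):
        assert generalized_q(simple_sample, 0.0) == pytest.approx(2.0)

    def test_at_tau2_one(self, simple_sample):
        assert generalized_q(simple_sample, 1.0) == pytest.approx(1.0)

    def test_negative_tau2_rejected(self, simple_sample):
        with pytest.raises(ValueError):
            generalized_q(simple_sample, -0.1)

    def test_strictly_decreasing_in_tau2(self, random_samples):
        grid = np.linspace(0.0, 5.0, 40)
        for s in random_samples:
            if np.ptp(s.y) == 0:
                continue
            values = [generalized_q(s, t2) for t2 in grid]
            assert np.all(np.diff(values) < 0)


class TestPauleMandel:
    def test_closed_form_two_studies(self, simple_sample):
        tau2, truncated = paule_mandel(simple_sample)
        assert tau2 == pytest.approx(1.0, abs=1e-8)
        assert not truncated

    def test_truncates_for_identical_effects(self):
        s = MetaSample(y=[0.2, 0.2, 0.2], var=[1.0, 1.0, 1.0])
        tau2, truncated = paule_mandel(s)
        assert tau2 == 0.0 and truncated

    def test_against_grid_scan_oracle(self, rng):
        # independent oracle: scan Q(tau2) on a fine grid for the k-1 crossing
        s = MetaSample(y=rng.normal(0, 1.5, size=5), var=rng.uniform(0.1, 1.0, size=5))
        tau2, truncated = paule_mandel(s)
        if truncated:
            assert generalized_q(s, 0.0) <= s.k - 1
            return
        grid = np.arange(0.0, tau2 + 1.0, 1e-4)
        q_vals = np.array([generalized_q(s, t2) for t2 in grid])
        crossing = grid[np.searchsorted(-q_vals, -(s.k - 1))]
        assert tau2 == pytest.approx(crossing, abs=2e-4)

    def test_solution_property(self, random_samples):
        for s in random_samples:
            tau2, truncated = paule_mandel(s)
            if not truncated:
                assert generalized_q(s, tau2) == pytest.approx(s.k - 1, abs=1e-6)

    def test_estimate_inside_q_profile_ci(self, random_samples):
        for s in random_samples:
            tau2, _ = paule_mandel(s)
            interval = q_profile_ci(s, 0.95)
            if interval.status is not IntervalStatus.NULL_SET:
                assert interval.lb - 1e-9 <= tau2 <= interval.ub + 1e-9


class TestQProfileCI:
    def test_closed_form_upper_bound(self, simple_sample):
        # Q(tau2) = 2/(1+tau2); invert at the implementer's chi2_1 quantiles
        interval = q_profile_ci(simple_sample, 0.95)
        expected_ub = 2.0 / chi2.ppf(0.025, 1) - 1.0
        assert interval.status is IntervalStatus.LOWER_TRUNCATED
        assert interval.lb == 0.0
        assert interval.ub == pytest.approx(expected_ub, rel=1e-6)
        assert interval.ub == pytest.approx(2035.5, abs=0.5)

    def test_null_set_when_q0_below_lower_quantile(self):
        s = MetaSample(y=[0.5, 0.5, 0.5001, 0.5], var=[1.0, 1.0, 1.0, 1.0])
        assert generalized_q(s, 0.0) < chi2.ppf(0.025, 3)
        assert q_profile_ci(s, 0.95).status is IntervalStatus.NULL_SET

    def test_regular_interval_solves_inversion_equations(self, rng):
        s = MetaSample(y=rng.normal(0, 3.0, size=8), var=rng.uniform(0.1, 0.5, size=8))
        interval = q_profile_ci(s, 0.95)
        assert interval.status is IntervalStatus.REGULAR
        assert generalized_q(s, interval.lb) == pytest.approx(chi2.ppf(0.975, 7), abs=1e-5)
        assert generalized_q(s, interval.ub) == pytest.approx(chi2.ppf(0.025, 7), abs=1e-5)

    def test_level_bounds_validated(self, simple_sample):
        for level in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                q_profile_ci(simple_sample, level)

    def test_identical_effects_yield_null_set(self):
        s = MetaSample(y=[0.4, 0.4, 0.4], var=[0.2, 0.4, 0.9])
        assert q_profile_ci(s, 0.95).status is IntervalStatus.NULL_SET


class TestGenqStatistic:
    def test_zero_for_identical_effects(self):
        s = MetaSample(y=[1.0, 1.0], var=[0.5, 2.0])
        assert genq_statistic(s, WeightScheme.INVERSE_VARIANCE) == pytest.approx(0.0)

    def test_inverse_variance(self, simple_sample):
        assert genq_statistic(simple_sample, WeightScheme.INVERSE_VARIANCE) == pytest.approx(2.0)

    def test_inverse_se(self):
        s = MetaSample(y=[0.0, 2.0], var=[4.0, 4.0])
        assert genq_statistic(s, WeightScheme.INVERSE_SE) == pytest.approx(1.0)


class TestGenqLambdas:
    def test_centering_matrix_eigenvalues(self):
        s = MetaSample(y=[0.0, 1.0, 2.0], var=[1.0, 1.0, 1.0])
        lam = np.sort(genq_lambdas(s, WeightScheme.INVERSE_VARIANCE, 0.0))
        assert lam == pytest.approx([0.0, 1.0, 1.0], abs=1e-10)

    def test_trace_identity(self, random_samples):
        for s in random_samples:
            for scheme in WeightScheme:
                for tau2 in (0.0, 0.3, 2.0):
                    a = scheme.weights(s.var)
                    srow = tau2 + s.var
                    expected = np.sum(a * srow) - np.sum(a**2 * srow) / np.sum(a)
                    lam = genq_lambdas(s, scheme, tau2)
                    assert np.sum(lam) == pytest.approx(expected, rel=1e-10)
                    assert np.all(lam >= 0)

    def test_equal_variance_scalar_case(self):
        c, t = 0.7, 0.4
        s = MetaSample(y=[0.0, 1.0, 2.0, 3.0], var=[c] * 4)
        lam = np.sort(genq_lambdas(s, WeightScheme.INVERSE_VARIANCE, t))[::-1]
        assert lam[:3] == pytest.approx([(t + c) / c] * 3, rel=1e-10)
        assert lam[3] == pytest.approx(0.0, abs=1e-10)


class TestWeightedChisqSF:
    def test_single_lambda_is_chi2_1(self):
        for q in (0.1, 1.0, 4.0):
            assert weighted_chisq_sf([1.0], q) == pytest.approx(chi2.sf(q, 1), abs=1e-12)
            assert weighted_chisq_sf([2.5], q) == pytest.approx(chi2.sf(q / 2.5, 1), abs=1e-12)

    @pytest.mark.parametrize("m", [2, 4, 7, 30, 159])
    def test_equal_lambdas_match_chi2(self, m):
        for q in (0.5, m / 2, m, 2 * m, 4 * m):
            assert weighted_chisq_sf(np.ones(m), q) == pytest.approx(
                chi2.sf(q, m), abs=1e-8
            )

    def test_monte_carlo_oracle(self, rng):
        lam = np.array([1.0, 2.0, 3.0])
        draws = rng.chisquare(1, size=(10**6, 3)) @ lam
        for q in (2.0, 5.0, 12.0):
            p_mc = float(np.mean(draws >= q))
            se = np.sqrt(p_mc * (1 - p_mc) / draws.size)
            assert abs(weighted_chisq_sf(lam, q) - p_mc) < 3 * se

    def test_monotone_nonincreasing_in_q(self, rng):
        lam = rng.uniform(0.2, 3.0, size=12)
        qs = np.linspace(0.0, 60.0, 80)
        probs = [weighted_chisq_sf(lam, q) for q in qs]
        assert np.all(np.diff(probs) <= 1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            weighted_chisq_sf([0.0, 0.0], 1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            weighted_chisq_sf([1.0, -0.5], 1.0)

    def test_spread_spectrum_fallback_consistency(self, rng):
        # a spectrum forcing the Imhof path agrees with Monte Carlo
        lam = np.concatenate([rng.uniform(0.05, 5.0, size=80)])
        draws = rng.chisquare(1, size=(200_000, lam.size)) @ lam
        q = float(np.median(draws))
        p_mc = float(np.mean(draws >= q))
        se = np.sqrt(p_mc * (1 - p_mc) / draws.size)
        assert abs(weighted_chisq_sf(lam, q) - p_mc) < 4 * se


class TestGenqCI:
    def test_equal_variance_matches_q_profile(self, rng):
        # with all variances equal both methods invert a scaled chi2_{k-1}
        for k in (3, 5, 12):
            s = MetaSample(y=rng.normal(0, 1.2, size=k), var=np.full(k, 0.6))
            qp = q_profile_ci(s, 0.95)
            gq = genq_ci(s, WeightScheme.INVERSE_VARIANCE, 0.95)
            assert gq.status == qp.status
            if qp.status is not IntervalStatus.NULL_SET:
                assert gq.lb == pytest.approx(qp.lb, abs=1e-6)
                assert gq.ub == pytest.approx(qp.ub, abs=2e-5)

    def test_two_study_example_matches_q_profile(self, simple_sample):
        qp = q_profile_ci(simple_sample, 0.95)
        gq = genq_ci(simple_sample, WeightScheme.INVERSE_VARIANCE, 0.95)
        assert gq.lb == qp.lb == 0.0
        assert gq.ub == pytest.approx(qp.ub, rel=1e-5)

    def test_null_set_for_near_identical_effects(self):
        s = MetaSample(y=[0.5, 0.5001, 0.5, 0.5], var=[1.0, 1.0, 1.0, 1.0])
        for scheme in WeightScheme:
            assert genq_ci(s, scheme, 0.95).status is IntervalStatus.NULL_SET

    def test_tail_probability_nondecreasing_in_tau2(self, random_samples):
        grid = np.linspace(0.0, 4.0, 25)
        for s in random_samples[::3]:
            for scheme in WeightScheme:
                probs = [genq_tail_probability(s, scheme, t2) for t2 in grid]
                assert np.all(np.diff(probs) >= -1e-9)

    def test_bounds_solve_inversion_equations(self, rng):
        s = MetaSample(y=rng.normal(0, 2.0, size=6), var=rng.uniform(0.2, 0.8, size=6))
        for scheme in WeightScheme:
            interval = genq_ci(s, scheme, 0.95)
            assert interval.status is IntervalStatus.REGULAR
            assert genq_tail_probability(s, scheme, interval.lb) == pytest.approx(0.025, abs=1e-6)
            assert genq_tail_probability(s, scheme, interval.ub) == pytest.approx(0.975, abs=1e-6)

    def test_level_validated(self, simple_sample):
        with pytest.raises(ValueError):
            genq_ci(simple_sample, WeightScheme.INVERSE_SE, 1.2)


def _covered_by_pivot_qprofile(sample, tau2, lo, hi):
    q = generalized_q(sample, tau2)
    return lo <= q <= hi


def _covered_by_pivot_genq(sample, scheme, tau2, alpha):
    p = genq_tail_probability(sample, scheme, tau2)
    return alpha / 2 <= p <= 1 - alpha / 2


class TestCoverageExactness:
    """Exactness under the ideal normal model with known variances.

    The per-repetition coverage indicator is evaluated through the
    monotone pivots (one statistic evaluation instead of a full
    interval inversion); the test below first proves on random samples
    that the pivot indicator coincides with interval containment for
    all three methods, then checks nominal coverage at 20,000
    repetitions with the cheap indicator.
    """

    def test_pivot_indicator_matches_interval_containment(self, rng):
        lo, hi = chi2.ppf(0.025, 4), chi2.ppf(0.975, 4)
        for _ in range(60):
            s = MetaSample(
                y=rng.normal(0, rng.uniform(0.3, 2.0), size=5),
                var=rng.uniform(0.1, 1.5, size=5),
            )
            tau2 = rng.uniform(0.0, 1.5)
            assert q_profile_ci(s, 0.95).contains(tau2) == _covered_by_pivot_qprofile(
                s, tau2, lo, hi
            )
            for scheme in WeightScheme:
                assert genq_ci(s, scheme, 0.95).contains(tau2) == _covered_by_pivot_genq(
                    s, scheme, tau2, 0.05
                )

    @pytest.mark.parametrize("tau", [0.0, 0.5])
    def test_nominal_coverage_at_20000_reps(self, tau):
        reps = 20_000
        condition = SimCondition(
            mu=0.0, tau=tau, pi_c=0.5, k=5, reps=reps, seed=42,
            generator_mode="ideal_normal",
        )
        lo, hi = chi2.ppf(0.025, 4), chi2.ppf(0.975, 4)
        root = np.random.SeedSequence(condition.seed)
        hits = {"qprofile": 0, "genq_variance": 0, "genq_se": 0}
        for child in root.spawn(reps):
            meta = simulate_meta(condition, np.random.default_rng(child))
            s = meta.sample
            hits["qprofile"] += _covered_by_pivot_qprofile(s, tau**2, lo, hi)
            hits["genq_variance"] += _covered_by_pivot_genq(
                s, WeightScheme.INVERSE_VARIANCE, tau**2, 0.05
            )
            hits["genq_se"] += _covered_by_pivot_genq(
                s, WeightScheme.INVERSE_SE, tau**2, 0.05
            )
        for method, count in hits.items():
            assert count / reps == pytest.approx(0.95, abs=0.005), method


class TestMetaSampleValidation:
    def test_requires_two_studies(self):
        with pytest.raises(ValueError):
            MetaSample(y=[1.0], var=[1.0])

    def test_rejects_nonpositive_variance(self):
        with pytest.raises(ValueError):
            MetaSample(y=[0.0, 1.0], var=[1.0, 0.0])

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            MetaSample(y=[0.0, 1.0, 2.0], var=[1.0, 1.0])

    def test_from_estimates(self):
        from hetci.effects import EffectEstimate

        s = MetaSample.from_estimates(
            [EffectEstimate(0.1, 0.5, 0), EffectEstimate(-0.2, 0.3, 1)]
        )
        assert s.k == 2 and s.var[1] == 0.3


class TestInterval:
    def test_null_set_has_no_bounds_and_covers_nothing(self):
        interval = Interval.null_set(0.95)
        assert interval.status is IntervalStatus.NULL_SET
        assert not interval.contains(0.0)
        assert np.isnan(interval.width)

    def test_truncated_requires_zero_lb(self):
        with pytest.raises(ValueError):
            Interval(0.1, 0.5, IntervalStatus.LOWER_TRUNCATED, 0.95)

    def test_rejects_inverted_bounds(self):
        with pytest.raises(ValueError):
            Interval(1.0, 0.5, IntervalStatus.REGULAR, 0.95)


class TestBracketCap:
    def test_bracket_error_on_pathological_target(self):
        from hetci.tau2 import _bracket_and_solve

        with pytest.raises(BracketError):
            _bracket_and_solve(lambda t2: 1.0)  # never crosses zero


@settings(max_examples=25, deadline=None)
@given(
    st.lists(st.floats(-3, 3), min_size=3, max_size=8),
    st.lists(st.floats(0.05, 2.0), min_size=8, max_size=8),
)
def test_q_profile_interval_invariants(y_values, variances):
    y = np.asarray(y_values)
    if np.ptp(y) < 1e-6:
        return
    s = MetaSample(y=y, var=np.asarray(variances[: y.size]))
    interval = q_profile_ci(s, 0.95)
    if interval.status is IntervalStatus.NULL_SET:
        assert generalized_q(s, 0.0) < chi2.ppf(0.025, s.k - 1)
    else:
        assert 0.0 <= interval.lb <= interval.ub
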
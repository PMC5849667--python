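"""Passing-Bablok estimator against exhaustive enumeration and its
method-comparison invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbsval.passing_bablok import (
    DegenerateDataError,
    PassingBablok,
    analytic_ci_indices,
    classify_bias,
    fit_passing_bablok,
    pairwise_slopes,
    pearson_correlation,
)

from oracles import pb_enumerate


def random_instance(rng, n):
    x = rng.uniform(0.5, 30.0, n)
    y = 0.9 * x + rng.normal(0, 1.0, n)
    # occasionally introduce ties in x to exercise the degenerate-pair rule
    if rng.random() < 0.3 and n >= 4:
        x[1] = x[0]
    return x, np.abs(y) + 0.01


class TestPairwiseSlopes:
    def test_identity_line_gives_unit_slopes(self):
        s, k = pairwise_slopes([1, 2, 3], [1, 2, 3])
        assert np.allclose(s, 1.0) and len(s) == 3 and k == 0

    def test_five_point_toy_matches_enumeration(self):
        x = np.array([1, 2, 3, 4, 10.0])
        y = np.array([1.1, 1.9, 3.2, 4.0, 9.8])
        s, k = pairwise_slopes(x, y)
        ref = pb_enumerate(x, y)
        assert len(s) == 10
        np.testing.assert_allclose(s, ref["slopes"])
        assert k == ref["k"] == 0

    def test_equal_x_pair_discarded(self):
        s, _ = pairwise_slopes([1, 1, 2], [1, 2, 3])
        assert len(s) == 2

    def test_slopes_of_exactly_minus_one_discarded_and_k_counts_below(self):
        # y = -2x gives all slopes -2 (< -1, retained); y = -x all discarded
        s, k = pairwise_slopes([1, 2, 3], [-2, -4, -6])
        assert np.allclose(s, -2.0) and k == 3
        with pytest.raises(DegenerateDataError):
            pairwise_slopes([1, 2, 3], [-1, -2, -3])

    def test_all_x_equal_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            pairwise_slopes([2, 2, 2], [1, 2, 3])


class TestFit:
    def test_identity_data_recovers_identity(self):
        x = np.arange(1.0, 11.0)
        fit = fit_passing_bablok(x, x)
        assert fit.slope == 1.0
        assert fit.intercept == 0.0
        assert fit.slope_ci[0] <= 1.0 <= fit.slope_ci[1]

    def test_exact_proportionality_small_n(self):
        with pytest.warns(UserWarning, match="analytic"):
            fit = fit_passing_bablok([1, 2, 3, 4], [2, 4, 6, 8])
        assert fit.slope == 2.0
        assert fit.intercept == 0.0
        assert fit.slope_ci is None  # too few points for the analytic CI

    def test_five_point_toy_matches_shifted_median_oracle(self):
        x = np.array([1, 2, 3, 4, 10.0])
        y = np.array([1.1, 1.9, 3.2, 4.0, 9.8])
        ref = pb_enumerate(x, y)
        fit = fit_passing_bablok(x, y, ci=None)
        assert fit.slope == pytest.approx(ref["slope"], abs=1e-14)
        assert fit.intercept == pytest.approx(ref["intercept"], abs=1e-14)

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_oracle_equivalence_small_instances(self, n):
        rng = np.random.default_rng(n)
        for _ in range(100):
            x, y = random_instance(rng, n)
            try:
                ref = pb_enumerate(x, y)
            except ZeroDivisionError:
                continue
            fit = fit_passing_bablok(x, y, ci=None)
            assert fit.slope == pytest.approx(ref["slope"], rel=1e-12)
            assert fit.intercept == pytest.approx(ref["intercept"], rel=1e-12, abs=1e-12)
            assert fit.offset_k == ref["k"]
            assert fit.n_slopes == len(ref["slopes"])

    def test_full_ci_matches_oracle_at_moderate_n(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            x, y = random_instance(rng, 12)
            ref = pb_enumerate(x, y)
            assert ref["ci_feasible"]
            fit = fit_passing_bablok(x, y)
            np.testing.assert_allclose(fit.slope_ci, ref["slope_ci"])
            np.testing.assert_allclose(fit.intercept_ci, ref["intercept_ci"])

    def test_ci_contains_point_estimates(self):
        rng = np.random.default_rng(1)
        x, y = random_instance(rng, 30)
        fit = fit_passing_bablok(x, y)
        assert fit.slope_ci[0] <= fit.slope <= fit.slope_ci[1]
        assert fit.intercept_ci[0] <= fit.intercept <= fit.intercept_ci[1]
        assert fit.n_slopes <= fit.n * (fit.n - 1) // 2

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(5)

        def width(n):
            x = rng.uniform(1, 30, n)
            y = (0.5 + 0.9 * x) * np.exp(rng.normal(0, 0.09, n))
            fit = fit_passing_bablok(x, y)
            return fit.slope_ci[1] - fit.slope_ci[0]

        assert width(200) < width(20)

    def test_bootstrap_ci_available_at_small_n(self):
        rng = np.random.default_rng(2)
        x, y = random_instance(rng, 6)
        fit = fit_passing_bablok(x, y, ci="bootstrap")
        assert fit.slope_ci is not None
        assert fit.slope_ci[0] <= fit.slope_ci[1]

    def test_bootstrap_is_seeded_and_reproducible(self):
        rng = np.random.default_rng(3)
        x, y = random_instance(rng, 8)
        f1 = fit_passing_bablok(x, y, ci="bootstrap")
        f2 = fit_passing_bablok(x, y, ci="bootstrap")
        assert f1.slope_ci == f2.slope_ci

    def test_negative_correlation_warns_and_cannot_be_fitted(self):
        # the shifted-median construction targets positive relationships;
        # a negative one warns and then fails rather than silently fitting
        x = np.arange(1.0, 11.0)
        with pytest.warns(UserWarning, match="negatively"):
            with pytest.raises(DegenerateDataError):
                fit_passing_bablok(x, 25.0 - 1.5 * x, ci=None)


class TestProperties:
    @given(
        scale=st.floats(0.1, 50),
        seed=st.integers(0, 1000),
    )
    @settings(derandomize=True, max_examples=40)
    def test_scale_equivariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        x, y = random_instance(rng, 10)
        base = fit_passing_bablok(x, y, ci=None)
        scaled = fit_passing_bablok(scale * x, scale * y, ci=None)
        assert scaled.slope == pytest.approx(base.slope, rel=1e-9)
        assert scaled.intercept == pytest.approx(scale * base.intercept, rel=1e-9, abs=1e-9)

    @given(seed=st.integers(0, 1000))
    @settings(derandomize=True, max_examples=40)
    def test_swap_symmetry_maps_slope_to_reciprocal(self, seed):
        # n=11 distinct x gives an odd slope count; minimum x-gap 0.5 and
        # bounded noise keep every pairwise slope positive, so the
        # reciprocal identity holds without tie-handling caveats
        rng = np.random.default_rng(seed)
        x = np.cumsum(rng.uniform(0.5, 2.0, 11)) + 1.0
        y = 0.2 + 0.9 * x + rng.uniform(-0.1, 0.1, 11)
        fwd = fit_passing_bablok(x, y, ci=None)
        rev = fit_passing_bablok(y, x, ci=None)
        assert rev.slope == pytest.approx(1.0 / fwd.slope, rel=1e-9)

    @given(
        a=st.floats(-5, 5),
        b=st.floats(0.1, 5),
        seed=st.integers(0, 1000),
    )
    @settings(derandomize=True, max_examples=40)
    def test_exact_linear_data_recovered(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(1, 30, 12)
        y = a + b * x
        fit = fit_passing_bablok(x, y, ci=None)
        assert fit.slope == pytest.approx(b, rel=1e-9)
        assert fit.intercept == pytest.approx(a, rel=1e-9, abs=1e-9)


class TestSklearnCompat:
    def test_fit_predict_roundtrip(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(1, 30, (15, 1))
        y = 0.5 + 0.9 * X[:, 0]
        est = PassingBablok(ci=None).fit(X, y)
        assert est.slope_ == pytest.approx(0.9)
        np.testing.assert_allclose(est.predict(X), y, rtol=1e-9)
        params = est.get_params()
        assert params["level"] == 0.95
        est2 = PassingBablok(**params).fit(X, y)
        assert est2.slope_ == est.slope_

    def test_rejects_multifeature_input(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="single-feature"):
            PassingBablok().fit(X, np.arange(10.0))


class TestBiasClassification:
    @pytest.mark.parametrize(
        "slope_ci, intercept_ci, prop, const",
        [
            # the study's principal comparison: small proportional bias only
            ((0.76, 0.99), (-0.93, 1.35), True, False),
            # DBS_wb comparison: no bias of either kind
            ((0.87, 1.04), (-1.37, 0.51), False, False),
            ((1.01, 1.20), (0.10, 0.90), True, True),
        ],
    )
    def test_ci_exclusion_rules(self, slope_ci, intercept_ci, prop, const):
        fit = fit_passing_bablok(np.arange(1.0, 13.0), np.arange(1.0, 13.0), ci=None)
        fit = type(fit)(
            slope=fit.slope, intercept=fit.intercept, slope_ci=slope_ci,
            intercept_ci=intercept_ci, n=fit.n, n_slopes=fit.n_slopes,
            offset_k=fit.offset_k, level=0.95,
        )
        call = classify_bias(fit)
        assert call.proportional_bias is prop
        assert call.constant_bias is const

    def test_missing_ci_is_an_error(self):
        fit = fit_passing_bablok([1, 2, 3, 4.0], [1, 2, 3, 4.0], ci=None)
        with pytest.raises(ValueError):
            classify_bias(fit)


class TestPearson:
    def test_perfect_lines(self):
        x = np.arange(1.0, 11.0)
        r, r2 = pearson_correlation(x, 2 * x)
        assert r == pytest.approx(1.0, abs=1e-12)
        r, r2 = pearson_correlation(x, -2 * x + 30)
        assert r == pytest.approx(-1.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_five_point_toy_matches_direct_formula(self):
        x = np.array([1, 2, 3, 4, 10.0])
        y = np.array([1.1, 1.9, 3.2, 4.0, 9.8])
        sx, sy = x - x.mean(), y - y.mean()
        expect = float(np.sum(sx * sy) / np.sqrt(np.sum(sx**2) * np.sum(sy**2)))
        r, r2 = pearson_correlation(x, y)
        assert r == pytest.approx(expect, rel=1e-12)
        assert r2 == pytest.approx(expect**2, rel=1e-12)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_correlation([1, 1, 1], [1, 2, 3])
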
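"""Segmented regression: exact recovery, WLS identities, AIC selection,
confidence intervals, predictions and outlier diagnostics."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from mitolife import (
    breakpoint_ci,
    detect_outliers,
    fit_segmented,
    grid_search_rss,
    predict_with_ci,
    select_by_aic,
)
from mitolife.segmented import aic_wls

from conftest import two_segment_data


def exact_kink(n=60, psi=50.0, s1=-0.02, s2=0.06, b0=-3.0):
    x = np.linspace(0.0, 100.0, n)
    y = b0 + s1 * x + (s2 - s1) * np.maximum(x - psi, 0.0)
    return x, y


class TestExactRecovery:
    def test_noiseless_kink_recovered(self):
        x, y = exact_kink()
        fit = fit_segmented(x, y, K=1)
        assert fit.converged
        assert abs(fit.psi[0] - 50.0) < 1e-4
        assert fit.rss < 1e-16
        assert np.allclose(fit.slopes, [-0.02, 0.06], atol=1e-8)

    def test_noiseless_ci_collapses(self):
        x, y = exact_kink()
        fit = fit_segmented(x, y, K=1)
        ci = breakpoint_ci(fit)
        assert ci[0, 1] - ci[0, 0] < 1e-3

    def test_two_kinks_recovered(self):
        x = np.linspace(0, 100, 80)
        y = 1.0 + 0.01 * x + 0.05 * np.maximum(x - 30, 0) - 0.08 * np.maximum(x - 70, 0)
        fit = fit_segmented(x, y, K=2)
        assert np.allclose(fit.psi, [30.0, 70.0], atol=1e-3)


class TestWLSIdentities:
    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(0)
        x, y = two_segment_data(rng)
        w = rng.uniform(1, 10, len(x))
        f1 = fit_segmented(x, y, w, K=1)
        f2 = fit_segmented(x, y, 2.0 * w, K=1)
        assert np.allclose(f1.psi, f2.psi, atol=1e-8)
        assert np.allclose(f1.coef, f2.coef, atol=1e-10)
        assert f1.r2 == pytest.approx(f2.r2, abs=1e-12)
        assert f1.aic == pytest.approx(f2.aic, abs=1e-8)  # AIC weight invariance

    def test_k0_is_plain_wls(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 40)
        y = 2.0 + 0.5 * x + rng.normal(0, 0.3, 40)
        w = rng.uniform(1, 5, 40)
        fit = fit_segmented(x, y, w, K=0)
        ref = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        assert np.allclose(fit.coef, ref.params, atol=1e-10)
        assert fit.r2 == pytest.approx(ref.rsquared, abs=1e-10)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_weight_invariance_property(self, seed):
        rng = np.random.default_rng(seed)
        x, y = two_segment_data(rng, n=30)
        f1 = fit_segmented(x, y, None, K=1)
        f2 = fit_segmented(x, y, np.full_like(x, 7.5), K=1)
        if f1.converged and f2.converged:
            assert np.allclose(f1.psi, f2.psi, atol=1e-6)
            assert f1.aic == pytest.approx(f2.aic, abs=1e-6)


class TestAICSelection:
    def test_returned_fit_is_argmin(self):
        rng = np.random.default_rng(2)
        x, y = two_segment_data(rng)
        best = select_by_aic(x, y, K_max=2)
        for K in range(3):
            cand = fit_segmented(x, y, K=K)
            if cand.converged:
                assert best.aic <= cand.aic + 1e-8

    def test_parsimony_tie_break(self):
        # noiseless straight line: K=0 fits perfectly; larger K cannot win
        x = np.linspace(0, 100, 50)
        y = 1.0 + 0.04 * x + np.random.default_rng(3).normal(0, 0.05, 50)
        best = select_by_aic(x, y, K_max=2)
        assert best.K == 0

    def test_preconditions(self):
        with pytest.raises(ValueError, match="too small"):
            fit_segmented([1, 2, 3, 4], [1, 2, 3, 4], K=1)
        with pytest.raises(ValueError, match="all equal"):
            fit_segmented(np.ones(10), np.arange(10.0), K=0)
        with pytest.raises(ValueError, match="weights"):
            fit_segmented(np.arange(10.0), np.arange(10.0), np.zeros(10), K=1)


class TestBreakpointCI:
    def test_width_grows_with_noise(self):
        rng1 = np.random.default_rng(42)
        x1, y1 = two_segment_data(rng1, sigma=0.02)
        rng2 = np.random.default_rng(42)
        x2, y2 = two_segment_data(rng2, sigma=0.08)
        w1 = breakpoint_ci(fit_segmented(x1, y1, K=1))
        w2 = breakpoint_ci(fit_segmented(x2, y2, K=1))
        assert (w2[0, 1] - w2[0, 0]) > (w1[0, 1] - w1[0, 0])

    def test_requires_breakpoints(self):
        x = np.linspace(0, 10, 20)
        fit = fit_segmented(x, 2 * x, K=0)
        with pytest.raises(ValueError, match="no breakpoints"):
            breakpoint_ci(fit)


class TestPrediction:
    def test_k0_centroid_property(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 30)
        y = 1 + 0.3 * x + rng.normal(0, 0.2, 30)
        w = rng.uniform(1, 4, 30)
        fit = fit_segmented(x, y, w, K=0)
        xbar = np.average(x, weights=w)
        pred, _, _ = predict_with_ci(fit, [xbar])
        assert pred[0] == pytest.approx(np.average(y, weights=w), abs=1e-10)

    def test_ci_width_minimal_near_centroid(self):
        rng = np.random.default_rng(6)
        x = np.linspace(0, 10, 30)
        y = 1 + 0.3 * x + rng.normal(0, 0.2, 30)
        fit = fit_segmented(x, y, K=0)
        p, lo, hi = predict_with_ci(fit, [np.mean(x), x.min(), x.max()])
        w_centroid = hi[0] - lo[0]
        assert w_centroid <= hi[1] - lo[1]
        assert w_centroid <= hi[2] - lo[2]

    def test_extrapolation_rejected(self):
        x = np.linspace(0, 10, 20)
        fit = fit_segmented(x, 2 * x, K=0)
        with pytest.raises(ValueError, match="outside"):
            predict_with_ci(fit, [11.0])


class TestOutliers:
    def test_planted_outlier_flagged_and_aic_improves(self):
        rng = np.random.default_rng(7)
        x, y = two_segment_data(rng, n=40, sigma=0.05)
        y = y.copy()
        y[12] += 10 * 0.05  # 10-sigma displacement
        fit = fit_segmented(x, y, K=1)
        rep = detect_outliers(fit)
        assert 12 in rep.flagged
        assert rep.aic_without[12] < rep.aic_with

    def test_refit_r2_does_not_decrease(self):
        rng = np.random.default_rng(8)
        x, y = two_segment_data(rng, n=40)
        y = y.copy()
        y[5] += 0.6
        fit = fit_segmented(x, y, K=1)
        rep = detect_outliers(fit)
        for i in rep.flagged:
            keep = np.ones(fit.n, bool)
            keep[i] = False
            refit = fit_segmented(x[keep], y[keep], K=1, init=fit.psi)
            assert refit.r2 >= fit.r2 - 1e-9


class TestGridOracle:
    def test_iterative_fit_matches_brute_force(self):
        """On a small instance the converged RSS equals the exhaustive
        interval-search optimum."""
        rng = np.random.default_rng(9)
        x, y = two_segment_data(rng, n=30)
        fit = fit_segmented(x, y, K=1)
        _, rss_oracle = grid_search_rss(x, y, K=1)
        assert fit.rss == pytest.approx(rss_oracle, rel=1e-6)


def test_aic_formula_matches_gaussian_loglik():
    """aic_wls agrees with the weighted Gaussian log-likelihood evaluated
    directly at the MLE variance."""
    rng = np.random.default_rng(10)
    n = 25
    w = rng.uniform(0.5, 2.0, n)
    rss = 3.7
    s2 = rss / n
    ll = np.sum(0.5 * np.log(w)) - 0.5 * n * np.log(2 * np.pi * s2) - rss / (2 * s2)
    assert aic_wls(rss, w, 2, 0) == pytest.approx(-2 * ll + 2 * 3, abs=1e-10)
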
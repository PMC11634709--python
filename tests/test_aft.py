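"""Parametric survival regression: closed-form oracles, likelihood
identities, Type-III tests, backward elimination, marginal means and
per-population contrasts."""

import numpy as np
import pandas as pd
import pytest
from lifelines import LogLogisticFitter, LogNormalFitter, WeibullFitter
from scipy import stats

from mitolife import (
    emmeans_and_contrasts,
    fast_backward,
    fit_aft,
    per_population_tests,
    select_distribution,
    type3_anova,
)
from mitolife.aft import _loglik
from mitolife.design import FULL_TERMS, design_matrix
from mitolife.simulate import SimTruth, simulate_survival


def frame(days, status=None, **cols):
    n = len(days)
    out = {"day": np.asarray(days, float),
           "status": np.ones(n, int) if status is None else np.asarray(status, int)}
    out.update(cols)
    return pd.DataFrame(out)


def factorial_frame(rng, n_per_cell, effect=None, loc=50.0, scale=5.0):
    """Gaussian cohort over the 2x2x2 design with one optional term effect."""
    rows = []
    for m in "AB":
        for nuc in "AB":
            for t in ("control", "rapamycin"):
                rows.append(pd.DataFrame({
                    "mito": m, "nuclear": nuc, "treatment": t,
                    "day": np.zeros(n_per_cell), "status": 1,
                }))
    df = pd.concat(rows, ignore_index=True)
    mu = loc + np.zeros(len(df))
    if effect:
        term, size = effect
        from mitolife.design import term_column
        mu = mu + size * term_column(df, term)
    df["day"] = np.maximum(mu + rng.normal(0, scale, len(df)), 0.5)
    return df


class TestClosedFormOracles:
    def test_censored_exponential_mle(self):
        """Intercept-only exponential: fitted mean time = total observed
        time / number of deaths (the classical censored-exponential MLE)."""
        days = [3.0, 7.0, 10.0, 2.0, 8.0, 12.0, 5.0]
        status = [1, 1, 0, 1, 0, 1, 1]
        fit = fit_aft(frame(days, status), terms=(), distribution="exponential")
        closed_form = np.sum(days) / np.sum(status)
        assert np.exp(fit.coef[0]) == pytest.approx(closed_form, rel=1e-6)

    def test_gaussian_uncensored_equals_ols(self):
        rng = np.random.default_rng(0)
        df = factorial_frame(rng, 40)
        fit = fit_aft(df, FULL_TERMS, "gaussian")
        X = design_matrix(df, FULL_TERMS).to_numpy()
        beta_ols, *_ = np.linalg.lstsq(X, df["day"].to_numpy(), rcond=None)
        assert np.allclose(fit.coef, beta_ols, atol=1e-6)
        rss = np.sum((df["day"].to_numpy() - X @ beta_ols) ** 2)
        assert fit.scale**2 == pytest.approx(rss / len(df), rel=1e-5)

    @pytest.mark.parametrize("dist,fitter", [
        ("weibull", WeibullFitter),
        ("lognormal", LogNormalFitter),
        ("loglogistic", LogLogisticFitter),
    ])
    def test_log_families_cross_checked_against_lifelines(self, dist, fitter):
        """Intercept-only log-scale fits agree with the independent
        lifelines maximum-likelihood fitters."""
        rng = np.random.default_rng(1)
        t = np.exp(3.9 + 0.3 * rng.standard_normal(400))
        status = (rng.uniform(size=400) > 0.15).astype(int)
        df = frame(t, status)
        fit = fit_aft(df, terms=(), distribution=dist)
        ref = fitter().fit(t, status)
        assert fit.loglik == pytest.approx(ref.log_likelihood_, rel=1e-5)


class TestLikelihoodProperties:
    @pytest.mark.parametrize("dist", ["logistic", "gaussian", "weibull",
                                      "exponential", "lognormal", "loglogistic"])
    def test_ascent_from_least_squares_start(self, dist, default_events):
        sub = default_events.sample(600, random_state=4)
        fit = fit_aft(sub, FULL_TERMS, dist)
        assert fit.converged  # convergence implies ll >= start ll

    def test_profile_fit_reproduces_beta(self, default_events):
        sub = default_events.sample(600, random_state=5)
        fit = fit_aft(sub, FULL_TERMS, "logistic")
        prof = fit_aft(sub, FULL_TERMS, "logistic", fix_scale=fit.scale)
        assert np.allclose(prof.coef, fit.coef, atol=1e-6)

    def test_information_doubles_when_data_duplicated(self, default_events):
        sub = default_events.sample(500, random_state=6)
        double = pd.concat([sub, sub], ignore_index=True)
        f1 = fit_aft(sub, FULL_TERMS, "logistic")
        f2 = fit_aft(double, FULL_TERMS, "logistic")
        assert np.allclose(f2.coef, f1.coef, atol=1e-5)
        ratio = f1.coef_se / f2.coef_se
        assert np.allclose(ratio, np.sqrt(2.0), atol=1e-4)

    def test_all_censored_errors(self):
        with pytest.raises(ValueError, match="censored"):
            fit_aft(frame([5.0, 6.0], [0, 0]), terms=())

    def test_aic_definition(self, default_events):
        fit = fit_aft(default_events.sample(300, random_state=7))
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * (len(fit.coef) + 1))


class TestSelectDistribution:
    def test_returns_argmin(self, default_events):
        sub = default_events.sample(400, random_state=8)
        best, table = select_distribution(sub)
        assert best.aic == pytest.approx(table["aic"].min())
        assert len(table) == 6


class TestType3:
    def test_orthogonal_balanced_equals_sequential_ss(self):
        """In a balanced 2x2x2 gaussian design without censoring the Wald
        chi-square equals the classical sequential SS / sigma^2."""
        rng = np.random.default_rng(9)
        df = factorial_frame(rng, 50, effect=("treatment", -3.0))
        fit = fit_aft(df, FULL_TERMS, "gaussian")
        tab = type3_anova(fit)
        X = design_matrix(df, FULL_TERMS).to_numpy()
        y = df["day"].to_numpy()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma2 = np.sum((y - X @ beta) ** 2) / len(y)
        for j, term in enumerate(FULL_TERMS, start=1):
            ss = beta[j] ** 2 * np.sum(X[:, j] ** 2)
            assert tab.loc[j - 1, "chisq"] == pytest.approx(ss / sigma2, rel=1e-4)

    def test_two_level_terms_have_one_df(self, default_events):
        fit = fit_aft(default_events.sample(300, random_state=10))
        assert (type3_anova(fit)["df"] == 1).all()


class TestFastBackward:
    def test_strong_effects_never_deleted(self):
        truth = SimTruth(beta={"intercept": 55.0, "mito": 4.0, "nuclear": 4.0,
                               "treatment": -4.0, "mito:nuclear": 3.0,
                               "mito:treatment": 3.0, "nuclear:treatment": 3.0,
                               "mito:nuclear:treatment": 3.0}, seed=12)
        ev = simulate_survival(truth)
        reduced, trace = fast_backward(ev)
        assert len(trace) == 0
        assert set(reduced.terms) == set(FULL_TERMS)

    def test_trace_improves_on_full_model_at_every_step(self, default_events):
        full = fit_aft(default_events)
        _, trace = fast_backward(default_events, full)
        assert len(trace) > 0  # null two-way terms exist under the default truth
        assert (trace["approx_aic"] < full.aic).all()
        assert (np.diff(trace["cum_chisq"]) >= -1e-9).all()


class TestEMMeans:
    def test_balanced_saturated_emms_equal_cell_means(self):
        rng = np.random.default_rng(13)
        df = factorial_frame(rng, 60, effect=("mito:nuclear:treatment", 2.0))
        fit = fit_aft(df, FULL_TERMS, "gaussian")
        emm, _ = emmeans_and_contrasts(fit)
        for _, row in emm.iterrows():
            cell = df[(df.mito == row.mito) & (df.nuclear == row.nuclear)
                      & (df.treatment == row.treatment)]
            assert row.emmean == pytest.approx(cell["day"].mean(), abs=1e-5)

    def test_sum_to_zero_identity(self, default_events):
        """Sum-to-zero coding: a factor's effect summed over its levels
        vanishes, so cell EMMs average back to the grand mean."""
        fit = fit_aft(default_events.sample(500, random_state=14))
        emm, _ = emmeans_and_contrasts(fit)
        assert emm["emmean"].mean() == pytest.approx(fit.coef[0], abs=1e-8)

    def test_contrast_sign_flip_reported(self, default_events):
        fit = fit_aft(default_events.sample(500, random_state=15))
        _, contrasts = emmeans_and_contrasts(fit)
        assert np.allclose(contrasts["estimate_reported"], -contrasts["estimate"])
        assert contrasts["sign_flipped"].all()


class TestPerPopulation:
    def test_adjustment_monotone(self, default_events):
        tab = per_population_tests(default_events)
        assert len(tab) == 12
        assert (tab["p_tukey"] >= tab["p_raw"] - 1e-12).all()

    def test_missing_arm_errors(self, default_events):
        broken = default_events[~((default_events.population == "AA1")
                                  & (default_events.treatment == "rapamycin"))]
        with pytest.raises(ValueError, match="lacks a treatment arm"):
            per_population_tests(broken)

    def test_separate_mode_agrees_on_sign(self, default_events):
        joint = per_population_tests(default_events, mode="joint")
        sep = per_population_tests(default_events, mode="separate")
        assert np.allclose(np.sign(joint["estimate"]), np.sign(sep["estimate"]))
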
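"""Parametric location-scale (accelerated failure time) survival
regression with right censoring, distribution selection by AIC, Type-III
Wald ANOVA under sum-to-zero contrasts, fast backward term elimination,
estimated marginal means with Tukey-adjusted contrasts, and
per-population treatment tests.

The model is Survival ~ rapamycin x mtDNA x nDNA: with y = t for the
raw-scale families (logistic, gaussian) and y = ln t for the log-scale
families (weibull, exponential, lognormal, loglogistic),

    y_i = x_i' beta + sigma * W_i

and the log likelihood sums ln f_W((y-mu)/sigma) - ln sigma (deaths,
with the d(ln t)/dt Jacobian for log families so AICs are comparable
across raw- and log-scale candidates) and ln S_W((y-mu)/sigma)
(censored). Death times are taken as exact at the scored day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess3

from .design import FULL_TERMS, GENOTYPES, TREATMENTS, design_matrix, reference_grid
from .families import FAMILIES, get_family

logger = logging.getLogger(__name__)

LL_TOL = 1e-8
MAX_RESTARTS = 5


@dataclass
class AFTFit:
    distribution: str
    terms: tuple[str, ...]            # non-intercept model terms
    coef: np.ndarray                  # (intercept, *terms)
    scale: float
    cov: np.ndarray                   # covariance of (coef, scale); scale row absent if fixed
    loglik: float
    aic: float
    n_events: int
    n_censored: int
    n: int
    converged: bool
    design_columns: tuple[str, ...] = field(default=())

    @property
    def n_params(self) -> int:
        fixed = get_family(self.distribution).fixed_scale is not None
        return len(self.coef) + (0 if fixed else 1)

    @property
    def coef_cov(self) -> np.ndarray:
        p = len(self.coef)
        return self.cov[:p, :p]

    @property
    def coef_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.coef_cov))


def _loglik(theta, fam, X, y, dead, jac_sum, fixed_scale):
    p = X.shape[1]
    beta = theta[:p]
    sigma = fixed_scale if fixed_scale is not None else np.exp(theta[p])
    w = (y - X @ beta) / sigma
    ll = np.sum(fam.logpdf(w[dead])) - dead.sum() * np.log(sigma) - jac_sum
    ll += np.sum(fam.logsf(w[~dead]))
    return ll


def _grad_nll(theta, fam, X, y, dead, fixed_scale):
    """Analytic gradient of the negative log-likelihood in (beta, ln sigma)."""
    p = X.shape[1]
    beta = theta[:p]
    sigma = fixed_scale if fixed_scale is not None else np.exp(theta[p])
    w = (y - X @ beta) / sigma
    score_w = np.where(dead, fam.dlogpdf(w), fam.dlogsf(w))
    g_beta = (X * score_w[:, None]).sum(axis=0) / sigma  # -dll/dbeta
    if fixed_scale is not None:
        return g_beta
    g_lnsigma = np.sum(score_w * w) + dead.sum()          # -dll/dlnsigma
    return np.concatenate([g_beta, [g_lnsigma]])


def fit_aft(
    records: pd.DataFrame,
    terms=FULL_TERMS,
    distribution: str = "logistic",
    fix_scale: float | None = None,
) -> AFTFit:
    """Maximum-likelihood location-scale survival fit.

    ``records`` needs columns ``day`` and ``status`` plus the factor
    columns named in ``terms``. Optimisation is quasi-Newton (BFGS) on
    (beta, ln sigma) from a least-squares start on the events, with up
    to 5 jittered restarts; the covariance is the inverse observed
    information. ``fix_scale`` holds sigma fixed (profile fit).
    """
    fam = get_family(distribution)
    terms = tuple(terms)
    X_df = design_matrix(records, terms)
    X = X_df.to_numpy()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    t = np.asarray(records["day"], dtype=float)
    dead = np.asarray(records["status"], dtype=int) == 1
    if not dead.any():
        raise ValueError("no events: all observations censored")
    y = np.log(t) if fam.log_scale else t
    jac_sum = np.sum(np.log(t[dead])) if fam.log_scale else 0.0
    fixed = fam.fixed_scale if fam.fixed_scale is not None else fix_scale

    # least-squares start on the events
    beta0, *_ = np.linalg.lstsq(X[dead], y[dead], rcond=None)
    resid = y[dead] - X[dead] @ beta0
    s0 = max(np.std(resid) / fam.sd, 1e-3)
    theta0 = np.concatenate([beta0, [] if fixed is not None else [np.log(s0)]])
    ll_start = _loglik(theta0, fam, X, y, dead, jac_sum, fixed)

    def nll(th):
        val = _loglik(th, fam, X, y, dead, jac_sum, fixed)
        return -val if np.isfinite(val) else 1e12

    def grad(th):
        g = _grad_nll(th, fam, X, y, dead, fixed)
        return np.where(np.isfinite(g), g, 0.0)

    best = None
    rng = np.random.default_rng(0)
    start = theta0
    for attempt in range(MAX_RESTARTS + 1):
        res = optimize.minimize(nll, start, jac=grad, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": 1000})
        ok = np.isfinite(res.fun)
        if ok and (best is None or res.fun < best.fun):
            best = res
        grad_small = ok and np.max(np.abs(grad(res.x))) < 1e-4 * max(1.0, abs(res.fun))
        if best is not None and -best.fun >= ll_start - 1e-9 and (res.success or grad_small):
            break
        start = theta0 + rng.normal(scale=0.05 * (1 + np.abs(theta0)))
    if best is None:
        raise RuntimeError("AFT optimisation failed")

    theta_hat = best.x
    p = X.shape[1]
    beta_hat = theta_hat[:p]
    sigma_hat = fixed if fixed is not None else float(np.exp(theta_hat[p]))

    # observed information in (beta, sigma) parameterisation
    if fixed is not None:
        def nll_nat(th):
            return nll(th)
        nat = beta_hat
    else:
        def nll_nat(th):
            return nll(np.concatenate([th[:p], [np.log(th[p])]]))
        nat = np.concatenate([beta_hat, [sigma_hat]])
    H = approx_hess3(nat, nll_nat)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    cov = (cov + cov.T) / 2.0

    ll = -best.fun
    npar = p + (0 if fixed is not None else 1)
    if fix_scale is not None and fam.fixed_scale is None:
        npar = p  # profile fit: sigma not counted
    grad_small = np.max(np.abs(grad(best.x))) < 1e-4 * max(1.0, abs(best.fun))
    return AFTFit(
        distribution=distribution,
        terms=terms,
        coef=beta_hat,
        scale=sigma_hat,
        cov=cov,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * npar,
        n_events=int(dead.sum()),
        n_censored=int((~dead).sum()),
        n=len(t),
        converged=bool((best.success or grad_small) and ll >= ll_start - 1e-9),
        design_columns=tuple(X_df.columns),
    )


def select_distribution(records: pd.DataFrame, terms=FULL_TERMS):
    """Fit all six candidate families and return (best fit, AIC table)."""
    fits = {}
    for name in FAMILIES:
        try:
            fits[name] = fit_aft(records, terms, name)
        except RuntimeError:
            logger.warning("distribution %s failed to fit; excluded", name)
    table = pd.DataFrame(
        {"distribution": list(fits), "aic": [f.aic for f in fits.values()],
         "loglik": [f.loglik for f in fits.values()]}
    ).sort_values("aic", ignore_index=True)
    best = min(fits.values(), key=lambda f: f.aic)
    return best, table


def type3_anova(fit: AFTFit) -> pd.DataFrame:
    """Type-III Wald chi-square table under the sum-to-zero coding.

    Each term's statistic is (L b)' (L V L')^{-1} (L b) with L selecting
    the term's contrast rows; for two-level factors every term has one
    degree of freedom.
    """
    V = fit.coef_cov
    rows = []
    for j, term in enumerate(fit.terms, start=1):
        L = np.zeros((1, len(fit.coef)))
        L[0, j] = 1.0
        M = L @ V @ L.T
        if np.linalg.det(M) <= 0:
            raise np.linalg.LinAlgError(f"singular contrast covariance for {term}")
        stat = float((L @ fit.coef).T @ np.linalg.inv(M) @ (L @ fit.coef))
        df = L.shape[0]
        rows.append({"term": term, "chisq": stat, "df": df,
                     "p": float(stats.chi2.sf(stat, df))})
    return pd.DataFrame(rows)


def fast_backward(records: pd.DataFrame, fit: AFTFit | None = None,
                  distribution: str = "logistic"):
    """Fast backward term elimination on Wald approximations.

    The classical fast-backward procedure: working entirely from the
    full model's coefficient vector and covariance (no refit per
    candidate), terms are deleted in ascending order of their Wald
    chi-square conditional on the terms already deleted, and deletion
    stops when the cumulative chi-square of the deleted set exceeds
    twice its cumulative degrees of freedom — i.e. while dropping the
    whole set still lowers the approximate AIC relative to the full
    model. A single refit of the surviving terms is done at the end.
    Hierarchy is NOT enforced: a three-way interaction can survive its
    two-way children, which is exactly the behaviour of interest in
    mito-nuclear x drug designs.

    Returns (reduced fit, trace frame); ``approx_aic`` in the trace is
    the full-model AIC plus the cumulative (chi-square - 2 df) of the
    deleted set, which stays below the full-model AIC at every accepted
    step.
    """
    if fit is None:
        fit = fit_aft(records, FULL_TERMS, distribution)
    b = fit.coef
    V = fit.coef_cov
    col_of = {term: j for j, term in enumerate(fit.terms, start=1)}

    def joint_chisq(term_set):
        if not term_set:
            return 0.0
        idx = [col_of[t] for t in term_set]
        sub = np.linalg.inv(V[np.ix_(idx, idx)])
        return float(b[idx] @ sub @ b[idx])

    remaining = list(fit.terms)
    deleted: list[str] = []
    trace = []
    cum_chisq = 0.0
    while remaining:
        conds = []
        base = joint_chisq(deleted)
        for term in remaining:
            conds.append(joint_chisq(deleted + [term]) - base)
        k = int(np.argmin(conds))
        cand_cum = base + conds[k]
        cand_df = len(deleted) + 1
        if cand_cum - 2.0 * cand_df >= 0.0:
            break  # deleting this term would no longer improve AIC overall
        deleted.append(remaining.pop(k))
        cum_chisq = cand_cum
        trace.append({
            "dropped": deleted[-1],
            "chisq": conds[k],
            "df": 1,
            "cum_chisq": cum_chisq,
            "cum_df": cand_df,
            "approx_aic": fit.aic + cum_chisq - 2.0 * cand_df,
        })
    reduced = fit_aft(records, tuple(remaining), fit.distribution)
    return reduced, pd.DataFrame(
        trace, columns=["dropped", "chisq", "df", "cum_chisq", "cum_df", "approx_aic"]
    )


def _t_df(fit: AFTFit) -> int:
    return max(fit.n - fit.n_params, 1)


def _tukey_p(tstat: float, k_means: int, df: int) -> float:
    """Studentized-range adjusted p for a pairwise-type contrast within a
    family spanning ``k_means`` cell means."""
    if k_means <= 2:
        return float(2.0 * stats.t.sf(abs(tstat), df))
    return float(stats.studentized_range.sf(abs(tstat) * np.sqrt(2.0), k_means, df))


def emmeans_and_contrasts(fit: AFTFit):
    """Estimated marginal means per factor cell plus the four
    within-mitonucleogenotype rapamycin-vs-control contrasts.

    EMMs are model predictions at each cell of the equally weighted
    2x2x2 reference grid, on the linear-predictor scale (days for
    raw-scale families, log-days otherwise). Contrast p-values carry a
    studentized-range (Tukey) adjustment over the 8-mean grid the family
    spans. Reported contrasts are sign-flipped (x -1) so that larger
    values mean longer survival under rapamycin.
    """
    grid = reference_grid()
    X = design_matrix(grid, fit.terms).to_numpy()
    V = fit.coef_cov
    pred = X @ fit.coef
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, V, X))
    df = _t_df(fit)
    tq = stats.t.ppf(0.975, df)
    emm = grid.copy()
    emm["emmean"] = pred
    emm["se"] = se
    emm["ci_lower"] = pred - tq * se
    emm["ci_upper"] = pred + tq * se

    rows = []
    for g in GENOTYPES:
        m = (grid["mito"] == g[0]) & (grid["nuclear"] == g[1])
        i_r = np.where(m & (grid["treatment"] == "rapamycin"))[0][0]
        i_c = np.where(m & (grid["treatment"] == "control"))[0][0]
        c = X[i_c] - X[i_r]  # pairwise convention: control minus rapamycin
        est = float(c @ fit.coef)
        cse = float(np.sqrt(c @ V @ c))
        tstat = est / cse
        rows.append({
            "genotype": g,
            "estimate": est,
            "se": cse,
            "t": tstat,
            "p_tukey": _tukey_p(tstat, len(grid), df),
            "estimate_reported": -est,   # x -1: higher = enhanced survival
            "sign_flipped": True,
        })
    contrasts = pd.DataFrame(rows)
    return emm, contrasts


def per_population_tests(records: pd.DataFrame, mode: str = "joint") -> pd.DataFrame:
    """Treatment effect within each replicate population.

    ``mode='joint'`` fits one model with population x treatment cell
    means and tests each population's rapamycin-vs-control difference by
    Wald; ``mode='separate'`` fits each population on its own. P-values
    are Tukey (studentized range) adjusted over the family of all
    population-arm means.
    """
    pops = sorted(records["population"].unique())
    for p in pops:
        arms = set(records.loc[records["population"] == p, "treatment"])
        if set(TREATMENTS) - arms:
            raise ValueError(f"population {p} lacks a treatment arm")

    rows = []
    if mode == "joint":
        fit, X_cols = _fit_cell_means(records, pops)
        V = fit.coef_cov
        df = _t_df(fit)
        for p in pops:
            c = np.zeros(len(fit.coef))
            c[X_cols.index(f"{p}:rapamycin")] = 1.0
            c[X_cols.index(f"{p}:control")] = -1.0
            est = float(c @ fit.coef)
            se = float(np.sqrt(c @ V @ c))
            tstat = est / se
            rows.append({"population": p, "estimate": est, "se": se, "t": tstat,
                         "p_raw": float(2 * stats.t.sf(abs(tstat), df)),
                         "p_tukey": _tukey_p(tstat, 2 * len(pops), df)})
    elif mode == "separate":
        for p in pops:
            sub = records[records["population"] == p]
            fit = fit_aft(sub, ("treatment",), "logistic")
            est = float(fit.coef[1] * -2.0)  # rapamycin - control under sum coding
            se = float(2.0 * fit.coef_se[1])
            tstat = est / se
            df = _t_df(fit)
            rows.append({"population": p, "estimate": est, "se": se, "t": tstat,
                         "p_raw": float(2 * stats.t.sf(abs(tstat), df)),
                         "p_tukey": _tukey_p(tstat, 2 * len(pops), df)})
    else:
        raise ValueError("mode must be 'joint' or 'separate'")
    return pd.DataFrame(rows)


def _fit_cell_means(records: pd.DataFrame, pops):
    """Logistic location-scale fit with one mean per population x arm."""
    labels = [f"{p}:{t}" for p in pops for t in TREATMENTS]
    key = records["population"].astype(str) + ":" + records["treatment"].astype(str)
    X = pd.get_dummies(key)[labels].to_numpy(dtype=float)

    fam = get_family("logistic")
    t = np.asarray(records["day"], dtype=float)
    dead = np.asarray(records["status"], dtype=int) == 1
    y = t

    beta0, *_ = np.linalg.lstsq(X[dead], y[dead], rcond=None)
    s0 = max(np.std(y[dead] - X[dead] @ beta0) / fam.sd, 1e-3)
    theta0 = np.concatenate([beta0, [np.log(s0)]])

    def nll(th):
        val = _loglik(th, fam, X, y, dead, 0.0, None)
        return -val if np.isfinite(val) else 1e12

    def grad(th):
        g = _grad_nll(th, fam, X, y, dead, None)
        return np.where(np.isfinite(g), g, 0.0)

    res = optimize.minimize(nll, theta0, jac=grad, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 2000})
    p = X.shape[1]
    beta_hat = res.x[:p]
    sigma_hat = float(np.exp(res.x[p]))

    def nll_nat(th):
        return nll(np.concatenate([th[:p], [np.log(th[p])]]))

    H = approx_hess3(np.concatenate([beta_hat, [sigma_hat]]), nll_nat)
    cov = np.linalg.pinv(H)
    ll = -res.fun
    fit = AFTFit(
        distribution="logistic", terms=tuple(labels), coef=beta_hat,
        scale=sigma_hat, cov=cov, loglik=ll, aic=-2 * ll + 2 * (p + 1),
        n_events=int(dead.sum()), n_censored=int((~dead).sum()), n=len(t),
        converged=bool(res.success), design_columns=tuple(labels),
    )
    return fit, labels
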
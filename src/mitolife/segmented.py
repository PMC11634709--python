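"""Weighted segmented (piecewise-linear) regression of mortality
trajectories: breakpoint estimation by iterative linearisation, AIC
selection of the number of inflections, delta-method breakpoint CIs,
prediction CIs at lifespan percentiles, CI-overlap comparisons and
outlier diagnostics.

The estimator is the classical iterative-linearisation scheme for
change-point regression: given current breakpoints psi, augment the
weighted linear model with

    U_k = max(x - psi_k, 0)        (slope change delta_k)
    V_k = -1[x > psi_k]            (gap coefficient gamma_k)

fit by WLS, and update psi_k <- psi_k + gamma_hat_k / delta_hat_k until
the gaps vanish. At convergence gamma ~ 0, the fitted mean is continuous
piecewise linear, and SE(psi_k) = SE(gamma_k)/|delta_k| (delta method).

Weights are the survivor counts entering each observation day, which
down-weights late-life mortality estimates computed from few flies.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

GAMMA_TOL = 1e-6
MAX_ITER = 50
MAX_RESTARTS = 10
#: minimal fraction of the data each segment must contain for a
#: breakpoint layout to be identifiable (the change-point literature's
#: standard trim); breakpoints leaving thinner segments flag the fit.
MIN_SEGMENT_FRAC = 0.15


def _min_segment_points(n: int, frac: float) -> int:
    return max(2, int(np.ceil(frac * n))) if frac > 0 else 0


def _segments_valid(x: np.ndarray, psi: np.ndarray, minseg: int) -> bool:
    if len(psi) == 0 or minseg == 0:
        return True
    edges = np.concatenate([[-np.inf], np.sort(psi), [np.inf]])
    for i in range(len(edges) - 1):
        if np.sum((x > edges[i]) & (x <= edges[i + 1])) < minseg:
            return False
    return True


@dataclass
class SegmentedFit:
    """A fitted piecewise-linear mean with K breakpoints.

    ``coef`` holds (intercept, base slope, slope changes delta_1..K) of
    the U-parameterised model at the converged breakpoints; segment
    slopes are the cumulative sums of (base slope, deltas).

    ``converged`` means the iteration terminated at an optimum: either
    the gap coefficients vanished (strict criterion, also recorded as
    ``gamma_converged``) or the damped step became stationary at a
    non-smooth optimum where the gap provably cannot vanish. Model
    selection additionally requires the strict criterion of its
    candidates.
    """

    K: int
    psi: np.ndarray            # (K,) ordered breakpoints
    psi_se: np.ndarray
    psi_ci: np.ndarray         # (K, 2)
    coef: np.ndarray           # (K+2,)
    cov: np.ndarray            # (K+2, K+2) WLS covariance at psi_hat
    gamma: np.ndarray          # gap coefficients at convergence
    rss: float                 # weighted RSS
    n: int
    aic: float
    r2: float
    x: np.ndarray
    y: np.ndarray
    weights: np.ndarray
    sigma2: float              # weighted residual variance estimate
    df_resid: int
    converged: bool = True
    gamma_converged: bool = True
    iterations: int = 0

    @property
    def slopes(self) -> np.ndarray:
        """Slope of each of the K+1 segments."""
        return np.cumsum(self.coef[1:])

    def design_row(self, x0: float) -> np.ndarray:
        row = np.empty(self.K + 2)
        row[0] = 1.0
        row[1] = x0
        for k in range(self.K):
            row[2 + k] = max(x0 - self.psi[k], 0.0)
        return row

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        X = np.vstack([self.design_row(float(v)) for v in np.atleast_1d(x_new)])
        return X @ self.coef


def _design(x: np.ndarray, psi: np.ndarray, with_gap: bool) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for p in psi:
        cols.append(np.maximum(x - p, 0.0))
    if with_gap:
        for p in psi:
            cols.append(-(x > p).astype(float))
    return np.column_stack(cols)


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    XtX = Xw.T @ Xw
    return beta, rss, XtX, rank


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: np.ndarray) -> np.ndarray:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cw = np.cumsum(ws) - 0.5 * ws
    cw /= np.sum(ws)
    return np.interp(q, cw, xs)


def aic_wls(rss: float, w: np.ndarray, n_mean_params: int, n_breakpoints: int) -> float:
    """AIC from the weighted Gaussian log-likelihood.

    l = 0.5*sum(ln w_i) - (n/2)*(ln 2pi + ln(RSS_w/n) + 1); parameters =
    mean parameters + breakpoints + 1 residual variance. Invariant to
    rescaling all weights by a constant.
    """
    n = len(w)
    ll = 0.5 * np.sum(np.log(w)) - 0.5 * n * (np.log(2 * np.pi) + np.log(rss / n) + 1.0)
    k = n_mean_params + n_breakpoints + 1
    return float(-2.0 * ll + 2.0 * k)


def _fit_line(x, y, w) -> SegmentedFit:
    X = _design(x, np.empty(0), with_gap=False)
    beta, rss, XtX, _ = _wls(X, y, w)
    n = len(x)
    df = n - 2
    sigma2 = rss / df if df > 0 else np.nan
    cov = sigma2 * np.linalg.inv(XtX)
    return SegmentedFit(
        K=0, psi=np.empty(0), psi_se=np.empty(0), psi_ci=np.empty((0, 2)),
        coef=beta, cov=cov, gamma=np.empty(0), rss=rss, n=n,
        aic=aic_wls(rss, w, 2, 0), r2=_weighted_r2(y, X @ beta, w),
        x=x, y=y, weights=w, sigma2=sigma2, df_resid=df,
        converged=True, iterations=0,
    )


def _weighted_r2(y, yhat, w) -> float:
    ybar = np.average(y, weights=w)
    tss = float(np.sum(w * (y - ybar) ** 2))
    rss = float(np.sum(w * (y - yhat) ** 2))
    return 1.0 - rss / tss if tss > 0 else np.nan


def fit_segmented(
    x,
    y,
    weights=None,
    K: int = 1,
    init: np.ndarray | None = None,
    seed: int | None = 0,
    min_segment_frac: float = MIN_SEGMENT_FRAC,
) -> SegmentedFit:
    """Fit a K-breakpoint weighted segmented regression.

    Breakpoints start at the k/(K+1) weighted quantiles of x unless
    ``init`` is given; the psi update is damped (halved while the
    no-gap RSS would increase) and breakpoints are kept ordered and
    strictly inside the data range. A converged layout must leave at
    least ``min_segment_frac`` of the observations in every segment
    (trim rule; pass 0 to disable) — thinner segments make the slope
    change unidentifiable. The quantile start plus 10 random interior
    restarts are all explored and the lowest-RSS converged valid fit is
    returned (the iteration only finds local optima; the contract is
    the global optimum); if nothing converges the best attempt is
    returned with ``converged=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal")
    n = len(x)
    if K == 0:
        return _fit_line(x, y, w)
    if n < 2 * K + 3:
        raise ValueError(f"n={n} too small for K={K} breakpoints (need >= {2 * K + 3})")
    minseg = _min_segment_points(n, min_segment_frac)

    qs = np.arange(1, K + 1) / (K + 1)
    starts = [np.asarray(init, dtype=float) if init is not None
              else _weighted_quantile(x, w, qs)]
    rng = np.random.default_rng(seed)
    lo, hi = x.min(), x.max()
    span = hi - lo
    for _ in range(MAX_RESTARTS):
        starts.append(np.sort(lo + span * rng.uniform(0.1, 0.9, size=K)))

    best = None
    best_any = None
    for s in starts:
        fit = _fit_once(x, y, w, K, s)
        if fit.converged and not _segments_valid(x, fit.psi, minseg):
            fit.converged = False  # degenerate layout: flag, maybe restart
        if best_any is None or fit.rss < best_any.rss:
            best_any = fit
        if fit.converged and (best is None or fit.rss < best.rss):
            best = fit
        if best is not None and best.rss <= 1e-14 * max(1.0, float(np.sum(w * y**2))):
            break  # essentially perfect fit; no better optimum exists
    if best is None:
        logger.warning("segmented fit with K=%d failed to converge; flagged", K)
        return best_any
    # deterministic neighbourhood polish: the iteration is local and the
    # RSS surface has one basin per data-interval layout, so try moving
    # each breakpoint to nearby intervals and keep any improvement
    psi_polished = _neighbourhood_polish(x, y, w, best.psi, minseg)
    if psi_polished is not None:
        refit = _fit_once(x, y, w, K, psi_polished)
        if (refit.converged and _segments_valid(x, refit.psi, minseg)
                and refit.rss < best.rss * (1 - 1e-12)):
            best = refit
    return best


def _neighbourhood_polish(x, y, w, psi, minseg, max_rounds=10):
    """Search interval layouts adjacent to ``psi`` for a lower weighted RSS.

    The RSS over breakpoint positions is piecewise smooth with one basin
    per assignment of breakpoints to inter-point intervals; the
    iterative fit only descends within a basin. This helper tries moving
    each breakpoint to nearby intervals (offsets of up to 2), refines
    within each candidate layout by bounded quasi-Newton, and returns an
    improved psi, or None when the current layout is already best.
    """
    from scipy import optimize

    xs = np.unique(x)
    if len(xs) < 3:
        return None
    eps = 1e-9 * (xs[-1] - xs[0])

    def rss_at(p):
        X = _design(x, np.sort(p), with_gap=False)
        _, rss, _, rank = _wls(X, y, w)
        return rss if rank == X.shape[1] else np.inf

    def refine(iv):
        los = xs[list(iv)] + eps
        his = xs[[i + 1 for i in iv]] - eps
        p0 = (los + his) / 2.0
        res = optimize.minimize(rss_at, p0, method="L-BFGS-B",
                                bounds=list(zip(los, his)),
                                options={"ftol": 1e-16, "gtol": 1e-12,
                                         "maxiter": 100})
        return np.clip(res.x, los, his), res.fun

    # current layout: interval index of each breakpoint
    cur_iv = tuple(int(np.clip(np.searchsorted(xs, p, side="right") - 1,
                               0, len(xs) - 2)) for p in np.sort(psi))
    rss_in = rss_at(psi)
    best_psi, best_rss = refine(cur_iv)
    if rss_in < best_rss:
        best_psi, best_rss = np.sort(np.asarray(psi, float)), rss_in
    improved_any = best_rss < rss_in * (1 - 1e-12)
    seen = {cur_iv}
    for _ in range(max_rounds):
        improved = False
        base_iv = tuple(int(np.clip(np.searchsorted(xs, p, side="right") - 1,
                                    0, len(xs) - 2)) for p in best_psi)
        for k in range(len(best_psi)):
            for off in (-2, -1, 1, 2):
                cand = list(base_iv)
                cand[k] = cand[k] + off
                if not 0 <= cand[k] <= len(xs) - 2:
                    continue
                cand = tuple(sorted(cand))
                if len(set(cand)) < len(cand) or cand in seen:
                    continue
                seen.add(cand)
                mids = (xs[list(cand)] + xs[[i + 1 for i in cand]]) / 2.0
                if not _segments_valid(x, mids, minseg):
                    continue
                p_new, rss_new = refine(cand)
                if rss_new < best_rss * (1 - 1e-12):
                    best_psi, best_rss = p_new, rss_new
                    improved = improved_any = True
        if not improved:
            break
    return best_psi if improved_any else None


def _fit_once(x, y, w, K, psi0) -> SegmentedFit:
    n = len(x)
    lo, hi = x.min(), x.max()
    eps = 1e-8 * (hi - lo)
    psi = np.sort(np.clip(np.asarray(psi0, float), lo + eps, hi - eps))

    def project(p):
        p = np.clip(p, lo + eps, hi - eps)
        return np.sort(p)

    def rss_nogap(p):
        Xn = _design(x, p, with_gap=False)
        _, rss, _, _ = _wls(Xn, y, w)
        return rss

    current_rss = rss_nogap(psi)
    converged = False
    strict = False
    it = 0
    stalled = 0
    gamma = np.full(K, np.nan)
    span = hi - lo
    for it in range(1, MAX_ITER + 1):
        X = _design(x, psi, with_gap=True)
        beta_aug, rss_aug, XtX, rank = _wls(X, y, w)
        if rank < X.shape[1]:
            break  # degenerate layout (empty segment); let restart handle it
        delta = beta_aug[2:2 + K].copy()
        delta[np.abs(delta) < 1e-12] = 1e-12
        gamma = beta_aug[2 + K:]
        if np.max(np.abs(gamma)) < GAMMA_TOL:
            converged = True
            strict = True
            break
        step = gamma / delta
        # damped update: halve until the continuous-model RSS does not worsen
        for _ in range(20):
            cand = project(psi + step)
            cand_rss = rss_nogap(cand)
            if cand_rss <= current_rss * (1 + 1e-12):
                break
            step = step / 2.0
        moved = np.max(np.abs(cand - psi))
        psi = cand
        current_rss = cand_rss
        # stalled at a non-smooth RSS optimum (psi pinned at a data point):
        # the gap cannot vanish there, but the breakpoints are stationary
        # (remaining possible movement is far below any meaningful scale)
        if moved < 1e-6 * span:
            stalled += 1
            if stalled >= 3:
                converged = True
                break
        else:
            stalled = 0

    # final continuous fit at converged psi
    Xf = _design(x, psi, with_gap=False)
    beta, rss, XtX_f, rank_f = _wls(Xf, y, w)
    p_mean = K + 2
    df = n - p_mean - K  # breakpoints count as estimated parameters
    sigma2 = rss / df if df > 0 else np.nan
    try:
        cov = sigma2 * np.linalg.inv(XtX_f)
    except np.linalg.LinAlgError:
        cov = np.full((p_mean, p_mean), np.nan)
        converged = False

    # delta-method SE for psi from the augmented model at convergence
    psi_se = np.full(K, np.nan)
    if converged:
        Xa = _design(x, psi, with_gap=True)
        beta_a, rss_a, XtX_a, rank_a = _wls(Xa, y, w)
        df_a = n - Xa.shape[1]
        if rank_a == Xa.shape[1] and df_a > 0:
            sigma2_a = rss_a / df_a
            cov_a = sigma2_a * np.linalg.inv(XtX_a)
            delta = beta_a[2:2 + K]
            se_gamma = np.sqrt(np.diag(cov_a)[2 + K:])
            with np.errstate(divide="ignore"):
                psi_se = np.where(
                    np.abs(delta) > 1e-10, se_gamma / np.abs(delta), np.inf
                )

    tq = stats.t.ppf(0.975, df) if df > 0 else np.nan
    ci = np.column_stack([psi - tq * psi_se, psi + tq * psi_se])
    ci[:, 0] = np.maximum(ci[:, 0], lo)
    ci[:, 1] = np.minimum(ci[:, 1], hi)

    yhat = Xf @ beta
    return SegmentedFit(
        K=K, psi=psi, psi_se=psi_se, psi_ci=ci, coef=beta, cov=cov,
        gamma=np.asarray(gamma, dtype=float), rss=rss, n=n,
        aic=aic_wls(rss, w, p_mean, K), r2=_weighted_r2(y, yhat, w),
        x=x, y=y, weights=w, sigma2=sigma2, df_resid=df,
        converged=converged, gamma_converged=strict and converged,
        iterations=it,
    )


def select_by_aic(x, y, weights=None, K_max: int = 3, seed: int | None = 0,
                  min_segment_frac: float = MIN_SEGMENT_FRAC) -> SegmentedFit:
    """Fit K = 0..K_max and return the minimum-AIC converged fit.

    Candidates must meet the strict convergence criterion (vanishing
    gap coefficients): a K whose best fit is non-converged, only
    stall-terminated at a non-smooth optimum, or degenerate
    (trim-violating) is excluded with a warning — a layout whose gap
    cannot be closed is not a trustworthy piecewise-linear description.
    AIC ties within 1e-8 resolve to the smaller K (parsimony).
    """
    x = np.asarray(x, dtype=float)
    candidates: list[SegmentedFit] = []
    for K in range(K_max + 1):
        if K > 0 and len(x) < 2 * K + 3:
            logger.warning("skipping K=%d: n=%d too small", K, len(x))
            continue
        fit = fit_segmented(x, y, weights, K=K, seed=seed,
                            min_segment_frac=min_segment_frac)
        if not fit.gamma_converged:
            logger.warning("excluding K=%d from AIC selection: not converged "
                           "(gap coefficients did not vanish)", K)
            continue
        candidates.append(fit)
    if not candidates:
        raise RuntimeError("no breakpoint count converged")
    best = candidates[0]
    for fit in candidates[1:]:
        if fit.aic < best.aic - 1e-8:
            best = fit
    return best


def breakpoint_ci(fit: SegmentedFit) -> np.ndarray:
    """95% breakpoint intervals (K, 2), truncated to the data range.

    Intervals are delta-method: psi_hat +/- t * SE(gamma)/|delta|; an
    ill-defined kink (|delta| < 1e-10) yields an infinite-width flag.
    """
    if fit.K < 1:
        raise ValueError("fit has no breakpoints")
    if not fit.converged:
        raise ValueError("fit did not converge; CIs undefined")
    return fit.psi_ci.copy()


def predict_with_ci(fit: SegmentedFit, x_query, alpha: float = 0.05):
    """Point predictions with CIs for the mean at x_query.

    The band is the WLS covariance of the mean parameters holding the
    breakpoints at their estimates (breakpoint uncertainty is not
    propagated, matching standard segmented-regression practice).
    Returns (pred, lower, upper).
    """
    xq = np.atleast_1d(np.asarray(x_query, dtype=float))
    lo, hi = fit.x.min(), fit.x.max()
    if np.any(xq < lo - 1e-9) or np.any(xq > hi + 1e-9):
        raise ValueError("prediction request outside the fitted range")
    X = np.vstack([fit.design_row(float(v)) for v in xq])
    pred = X @ fit.coef
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov, X))
    tq = stats.t.ppf(1 - alpha / 2, fit.df_resid)
    return pred, pred - tq * se, pred + tq * se


@dataclass
class MortalityComparison:
    """CI-overlap comparison of two conditions at fixed lifespan percentiles.

    Two conditions are declared to differ at a percentile exactly when
    their 95% prediction intervals are disjoint."""

    percentiles: np.ndarray
    pred_a: np.ndarray
    ci_a: np.ndarray  # (m, 2)
    pred_b: np.ndarray
    ci_b: np.ndarray
    differs: np.ndarray = field(init=False)

    def __post_init__(self):
        disjoint = (self.ci_a[:, 1] < self.ci_b[:, 0]) | (self.ci_b[:, 1] < self.ci_a[:, 0])
        self.differs = disjoint


def compare_at_percentiles(
    fit_a: SegmentedFit,
    fit_b: SegmentedFit,
    percentiles=(30.0, 50.0, 70.0),
) -> MortalityComparison:
    q = np.asarray(percentiles, dtype=float)
    pa, la, ua = predict_with_ci(fit_a, q)
    pb, lb, ub = predict_with_ci(fit_b, q)
    return MortalityComparison(q, pa, np.column_stack([la, ua]),
                               pb, np.column_stack([lb, ub]))


@dataclass
class OutlierReport:
    flagged: np.ndarray           # indices into fit.x
    std_residuals: np.ndarray
    cooks_d: np.ndarray
    aic_with: float
    aic_without: dict[int, float]  # flagged index -> AIC of refit without it


def detect_outliers(fit: SegmentedFit, resid_cut: float = 3.0) -> OutlierReport:
    """Flag high-influence points of a converged fit.

    A point is flagged when its standardised weighted residual exceeds 3
    in magnitude or its Cook's distance exceeds 4/n; for each flagged
    point the model is refit without it and both AICs reported, leaving
    the decision to exclude with the analyst.
    """
    X = _design(fit.x, fit.psi, with_gap=False)
    sw = np.sqrt(fit.weights)
    Xw = X * sw[:, None]
    H = Xw @ np.linalg.inv(Xw.T @ Xw) @ Xw.T
    h = np.diag(H)
    resid_w = sw * (fit.y - X @ fit.coef)
    p = X.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = resid_w / np.sqrt(fit.sigma2 * (1.0 - h))
        cook = r**2 * h / (p * (1.0 - h))
    n = fit.n
    flagged = np.where((np.abs(r) > resid_cut) | (cook > 4.0 / n))[0]

    aic_without = {}
    for i in flagged:
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        refit = fit_segmented(fit.x[keep], fit.y[keep], fit.weights[keep],
                              K=fit.K, init=fit.psi if fit.K else None)
        aic_without[int(i)] = refit.aic
    return OutlierReport(flagged, r, cook, fit.aic, aic_without)


def plot_fit(fit: SegmentedFit, ax=None, n_grid: int = 200):
    """Plot data, fitted piecewise mean with 95% CI ribbon, and
    inflection markers. Requires matplotlib (``plot`` extra)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(fit.x, fit.y, s=10 + 40 * fit.weights / fit.weights.max(),
               alpha=0.6, label="observed")
    xg = np.linspace(fit.x.min(), fit.x.max(), n_grid)
    pred, lo, hi = predict_with_ci(fit, xg)
    ax.plot(xg, pred, color="C1", label=f"K={fit.K} fit")
    ax.fill_between(xg, lo, hi, color="C1", alpha=0.2)
    for k in range(fit.K):
        ax.axvline(fit.psi[k], color="C3", ls="--", lw=0.8)
        ax.plot(fit.psi_ci[k], [ax.get_ylim()[0]] * 2, color="C3", lw=2)
    ax.set_xlabel("% of maximum lifespan")
    ax.set_ylabel("instantaneous mortality (ln scale)")
    ax.legend()
    return ax


def grid_search_rss(
    x, y, weights=None, K: int = 1, refine: bool = True,
    min_segment_frac: float = MIN_SEGMENT_FRAC,
) -> tuple[np.ndarray, float]:
    """Exhaustive search over breakpoint candidates at data midpoints.

    Brute-force global reference for small problems: enumerates every
    combination of inter-point intervals (represented by the midpoints
    between adjacent sorted unique x values) that satisfies the same
    trim rule as the iterative fitter and, with ``refine``, polishes
    the breakpoints inside each interval combination by bounded
    quasi-Newton search on the continuous-model weighted RSS. Returns
    (best psi, weighted RSS).
    """
    from scipy import optimize

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    xs = np.unique(x)
    mids = (xs[:-1] + xs[1:]) / 2.0
    minseg = _min_segment_points(len(x), min_segment_frac)

    def rss_at(psi):
        X = _design(x, np.sort(psi), with_gap=False)
        _, rss, _, rank = _wls(X, y, w)
        return rss if rank == X.shape[1] else np.inf

    best_rss = np.inf
    best_psi = None
    for idx in itertools.combinations(range(len(mids)), K):
        psi0 = mids[list(idx)]
        if not _segments_valid(x, psi0, minseg):
            continue
        rss0 = rss_at(psi0)
        if not np.isfinite(rss0):
            continue
        if refine:
            eps = 1e-9 * (xs[-1] - xs[0])
            los = xs[list(idx)] + eps
            his = xs[[i + 1 for i in idx]] - eps

            res = optimize.minimize(
                rss_at, psi0, method="L-BFGS-B",
                bounds=list(zip(los, his)),
                options={"ftol": 1e-16, "gtol": 1e-12, "maxiter": 200})
            if res.fun < rss0:
                psi0, rss0 = np.clip(res.x, los, his), res.fun
        if rss0 < best_rss:
            best_rss = rss0
            best_psi = np.sort(np.asarray(psi0))
    return best_psi, best_rss
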
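"""Cohort life tables, age-specific and instantaneous mortality, lifespan
normalisation, and Kaplan-Meier curves with difference bands.

Mortality follows the classical cohort demography estimators: at each
observation day x with at least one death, the proportion surviving l_x
is recorded, age-specific mortality is

    q_x = (l_x - l_{x+dx}) / (l_x * dx)

over the gap dx to the next observation day, and instantaneous mortality
is mu_x = -ln(1 - q_x). mu_x over age (optionally normalised to percent
of the group's maximum lifespan) is the response for the segmented
mortality-trajectory regressions, weighted by the survivor count
entering each day.

Censoring note: l_x here is the cohort survivorship (deaths over the
initial cohort size; censored flies never count as deaths), matching the
printed estimator; censored individuals do leave the risk set for the
``n_alive`` survivor counts used as regression weights. A KM-based l_x
mode is available where censoring is heavy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

LIFETABLE_COLUMNS = ["x", "x_pct", "l_x", "delta_x", "q_x", "mu_x", "n_alive"]


def build_life_table(
    records: pd.DataFrame,
    mode: str = "cohort",
) -> pd.DataFrame:
    """Life table for one group of event records.

    Rows appear only at days with >= 1 observed death, plus a day-0
    anchor (l=1) used for reconstruction; the anchor and any terminal row
    with q_x = 1 (mu_x undefined, NaN) are flagged ``exclude`` for the
    downstream regression. ``mode='km'`` replaces cohort survivorship
    with the product-limit estimate.
    """
    if len(records) == 0:
        raise ValueError("empty group: cannot build a life table")
    day = np.asarray(records["day"], dtype=float)
    dead = np.asarray(records["status"], dtype=int) == 1
    if not dead.any():
        raise ValueError("group has no observed deaths")

    n0 = len(day)
    death_days = np.unique(day[dead])
    deaths_at = pd.Series(day[dead]).value_counts().sort_index()
    censored_at = pd.Series(day[~dead]).value_counts().sort_index()

    if mode == "km":
        km = km_estimate(records)
        surv_after = {t: s for t, s in zip(km.times, km.survival)}

    xs = np.concatenate([[0.0], death_days])
    l = np.empty(len(xs))
    n_alive = np.empty(len(xs), dtype=float)
    l[0] = 1.0
    n_alive[0] = n0
    cum_dead = 0.0
    km_l = 1.0
    for i, x in enumerate(death_days, start=1):
        removed = deaths_at[deaths_at.index < x].sum() + censored_at[censored_at.index < x].sum()
        n_alive[i] = n0 - removed
        if mode == "km":
            l[i] = km_l  # survival entering x = value after previous death day
            km_l = surv_after[x]
        else:
            cum_dead = deaths_at[deaths_at.index < x].sum()
            l[i] = (n0 - cum_dead) / n0

    # survivorship after the final death day (end of the last interval)
    if mode == "km":
        l_end = km_l
    else:
        l_end = (n0 - deaths_at.sum()) / n0
    l_next = np.concatenate([l[1:], [l_end]])

    dx = np.diff(np.concatenate([xs, [np.nan]]))
    if len(death_days) >= 2:
        dx[-1] = xs[-1] - xs[-2]  # last interval reuses the final gap
    else:
        dx[-1] = 1.0  # single observation day: unit interval (degenerate)
    if np.any(dx <= 0):
        raise ValueError("non-positive day gap; pre-aggregate duplicate days")

    with np.errstate(divide="ignore", invalid="ignore"):
        q = (l - l_next) / (l * dx)
        q = np.clip(q, 0.0, 1.0)
        mu = np.where(q < 1.0, -np.log1p(-np.where(q < 1.0, q, 0.0)), np.nan)

    table = pd.DataFrame({
        "x": xs,
        "x_pct": np.nan,
        "l_x": l,
        "delta_x": dx,
        "q_x": q,
        "mu_x": mu,
        "n_alive": n_alive,
    })
    table["exclude"] = (table["x"] == 0.0) | ~np.isfinite(table["mu_x"])
    return table


def build_life_tables(
    records: pd.DataFrame,
    grouping: list[str] | tuple[str, ...] = ("mito", "nuclear", "treatment"),
    mode: str = "cohort",
    normalise: bool = True,
) -> dict[tuple, pd.DataFrame]:
    """Life table per factor group (replicate populations pooled unless
    ``replicate``/``population`` is in the grouping)."""
    out: dict[tuple, pd.DataFrame] = {}
    for key, grp in records.groupby(list(grouping), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        table = build_life_table(grp, mode=mode)
        if normalise:
            table = normalise_time(table, max_lifespan=float(grp["day"].max()))
        out[key] = table
    return out


def normalise_time(table: pd.DataFrame, max_lifespan: float | None = None) -> pd.DataFrame:
    """Express observation days as percent of the group's maximum lifespan
    (age of the longest-lived individual), so groups with different
    maxima are comparable on one axis. The last observed day maps to 100
    when the longest-lived fly died on it."""
    if max_lifespan is None:
        max_lifespan = float(table["x"].max())
    if max_lifespan <= 0:
        raise ValueError("maximum lifespan must be positive")
    out = table.copy()
    out["x_pct"] = 100.0 * out["x"] / max_lifespan
    return out


@dataclass
class KMCurve:
    """Product-limit survival estimate with Greenwood variance and
    log-minus-log pointwise 95% CI."""

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def at(self, t: np.ndarray) -> np.ndarray:
        """Step-function evaluation S(t) (right-continuous)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        s = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return s

    def variance_at(self, t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        return np.where(idx >= 0, self.variance[np.clip(idx, 0, None)], 0.0)


def km_estimate(records: pd.DataFrame, alpha: float = 0.05) -> KMCurve:
    """Kaplan-Meier curve for one group of event records."""
    if len(records) == 0:
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(records["day"], event_observed=records["status"])
    tab = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    times = tab.index.to_numpy(dtype=float)
    d = tab["observed"].to_numpy(dtype=float)
    n = tab["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.cumprod(np.where(n > 0, 1.0 - d / n, 1.0))
        # Greenwood: Var(S) = S^2 * sum d / (n (n - d))
        inc = np.where((n > 0) & (n > d), d / (n * (n - d)), 0.0)
        var = s**2 * np.cumsum(inc)
        z = stats.norm.ppf(1 - alpha / 2)
        # log(-log S) scale keeps the band inside [0, 1]
        ok = (s > 0) & (s < 1)
        se_cll = np.zeros_like(s)
        se_cll[ok] = np.sqrt(var[ok]) / np.abs(s[ok] * np.log(s[ok]))
        lo = np.where(ok, s ** np.exp(z * se_cll), s)
        hi = np.where(ok, s ** np.exp(-z * se_cll), s)
    return KMCurve(times, s, var, lo, hi)


@dataclass
class KMDifference:
    """Treated-minus-control survival difference on the union event grid,
    with a normal-approximation band from summed Greenwood variances.
    The control arm is the implicit zero line."""

    times: np.ndarray
    difference: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray


def km_difference(treated: KMCurve, control: KMCurve, alpha: float = 0.05) -> KMDifference:
    """Difference between two KM curves (treated - control)."""
    lo = max(treated.times.min(), control.times.min())
    hi = min(treated.times.max(), control.times.max())
    if lo > hi:
        raise ValueError("curves have disjoint time supports")
    grid = np.union1d(treated.times, control.times)
    grid = grid[(grid >= lo) & (grid <= hi)]
    diff = treated.at(grid) - control.at(grid)
    var = treated.variance_at(grid) + control.variance_at(grid)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return KMDifference(grid, diff, diff - half, diff + half)


def write_life_tables(tables: dict[tuple, pd.DataFrame], path) -> None:
    frames = []
    for key, tab in tables.items():
        t = tab.copy()
        t.insert(0, "group", "/".join(str(k) for k in key))
        frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_life_tables(path) -> dict[tuple, pd.DataFrame]:
    df = pd.read_csv(path)
    out = {}
    for g, grp in df.groupby("group", sort=False):
        out[tuple(str(g).split("/"))] = grp.drop(columns="group").reset_index(drop=True)
    return out
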
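"""End-to-end orchestration: simulate (or load) a cohort, build life
tables, fit the factorial survival model, segmented mortality
trajectories, and the fecundity GLM, and write an auditable report
bundle of CSV/JSON outputs.

Every model-selection decision (distribution AIC table, breakpoint
count per condition, deleted terms, flagged outliers) is logged and
written to the bundle so the analysis is reproducible and auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aft, demography, fecundity, segmented, simulate
from .design import GENOTYPES

logger = logging.getLogger(__name__)


def backcross_purge_fraction(generations: int) -> float:
    """Percent of residual donor nuclear differences removed by repeated
    backcrossing, each generation halving what remains: 100*(1 - 2^-g).
    Five generations gives 96.875, i.e. ~97% of drift-derived nuclear
    variation purged."""
    if generations < 0:
        raise ValueError("generations must be >= 0")
    return 100.0 * (1.0 - 2.0 ** (-generations))


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run."""

    truth: simulate.SimTruth | None = None
    events_csv: str | None = None
    eggs_csv: str | None = None
    out_dir: str = "mitolife_out"
    seed: int = 0
    distributions: tuple[str, ...] | None = None  # None = all six
    K_max: int = 3
    query_percentiles: tuple[float, ...] = (30.0, 50.0, 70.0)
    exclude_outliers: bool = False
    fecundity_response: str = "per_female"
    lifetable_mode: str = "cohort"

    def __post_init__(self):
        if not all(0 < q < 100 for q in self.query_percentiles):
            raise ValueError("query percentiles must lie in (0, 100)")
        if self.K_max > 3:
            raise ValueError("K_max above 3 is not supported")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        if "truth" in cfg and cfg["truth"] is not None:
            cfg["truth"] = simulate.SimTruth(**cfg["truth"])
        for key in ("distributions", "query_percentiles"):
            if key in cfg and cfg[key] is not None:
                cfg[key] = tuple(cfg[key])
        return cls(**cfg)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the report dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    # --- inputs -----------------------------------------------------------
    try:
        if config.events_csv is not None:
            events = simulate.read_events(config.events_csv)
        else:
            truth = config.truth or simulate.SimTruth(seed=config.seed)
            truth = dataclasses.replace(truth, seed=config.seed)
            events = simulate.simulate_survival(truth)
            simulate.write_events(events, out / "events.csv")
        if config.eggs_csv is not None:
            eggs = simulate.read_eggs(config.eggs_csv)
        else:
            truth = config.truth or simulate.SimTruth(seed=config.seed)
            truth = dataclasses.replace(truth, seed=config.seed)
            eggs = simulate.simulate_eggs(truth)
            simulate.write_eggs(eggs, out / "eggs.csv")
    except Exception as exc:
        raise RuntimeError(f"[simulate] stage failed: {exc}") from exc

    # --- survival model ---------------------------------------------------
    try:
        if config.distributions is None or len(config.distributions) > 1:
            best, aic_table = aft.select_distribution(events)
        else:
            best = aft.fit_aft(events, distribution=config.distributions[0])
            aic_table = pd.DataFrame(
                {"distribution": [best.distribution], "aic": [best.aic],
                 "loglik": [best.loglik]})
        aic_table.to_csv(out / "survival_aic_by_distribution.csv", index=False)
        anova = aft.type3_anova(best)
        anova.to_csv(out / "survival_type3_anova.csv", index=False)
        reduced, trace = aft.fast_backward(events, best)
        trace.to_csv(out / "survival_fastbw_trace.csv", index=False)
        emm, contrasts = aft.emmeans_and_contrasts(best)
        emm.to_csv(out / "survival_emmeans.csv", index=False)
        contrasts.to_csv(out / "survival_rapamycin_contrasts.csv", index=False)
        per_pop = aft.per_population_tests(events)
        per_pop.to_csv(out / "survival_per_population.csv", index=False)
        report["stages"]["survival"] = {
            "distribution": best.distribution,
            "aic": best.aic,
            "retained_terms": list(reduced.terms),
            "dropped_terms": list(trace["dropped"]),
            "anova": anova.to_dict("records"),
        }
        logger.info("survival: %s selected (AIC %.2f); dropped %s",
                    best.distribution, best.aic, list(trace["dropped"]))
    except Exception as exc:
        raise RuntimeError(f"[survival] stage failed: {exc}") from exc

    # --- demography + segmented mortality ---------------------------------
    try:
        tables = demography.build_life_tables(events, mode=config.lifetable_mode)
        demography.write_life_tables(tables, out / "life_tables.csv")
        km_diffs = {}
        for g in GENOTYPES:
            sub = events[(events["mito"] == g[0]) & (events["nuclear"] == g[1])]
            treated = demography.km_estimate(sub[sub["treatment"] == "rapamycin"])
            control = demography.km_estimate(sub[sub["treatment"] == "control"])
            d = demography.km_difference(treated, control)
            km_diffs[g] = pd.DataFrame({
                "time": d.times, "difference": d.difference,
                "ci_lower": d.ci_lower, "ci_upper": d.ci_upper})
        pd.concat(km_diffs, names=["genotype", None]).to_csv(out / "km_differences.csv")

        seg_fits: dict[tuple, segmented.SegmentedFit] = {}
        seg_rows = []
        outlier_rows = []
        for key, tab in tables.items():
            usable = tab[~tab["exclude"]]
            fit = segmented.select_by_aic(
                usable["x_pct"], usable["mu_x"], usable["n_alive"],
                K_max=config.K_max, seed=config.seed)
            rep = segmented.detect_outliers(fit)
            for i in rep.flagged:
                outlier_rows.append({
                    "group": "/".join(map(str, key)), "index": int(i),
                    "x_pct": float(fit.x[i]),
                    "aic_with": rep.aic_with,
                    "aic_without": rep.aic_without[int(i)]})
            if config.exclude_outliers and len(rep.flagged):
                keep = np.ones(fit.n, dtype=bool)
                keep[rep.flagged] = False
                fit = segmented.select_by_aic(
                    fit.x[keep], fit.y[keep], fit.weights[keep],
                    K_max=config.K_max, seed=config.seed)
            seg_fits[key] = fit
            for k in range(fit.K):
                seg_rows.append({
                    "group": "/".join(map(str, key)), "K": fit.K,
                    "psi": fit.psi[k], "psi_lo": fit.psi_ci[k, 0],
                    "psi_hi": fit.psi_ci[k, 1], "aic": fit.aic, "r2": fit.r2})
            if fit.K == 0:
                seg_rows.append({"group": "/".join(map(str, key)), "K": 0,
                                 "psi": np.nan, "psi_lo": np.nan,
                                 "psi_hi": np.nan, "aic": fit.aic, "r2": fit.r2})
        pd.DataFrame(seg_rows).to_csv(out / "mortality_inflections.csv", index=False)
        pd.DataFrame(outlier_rows).to_csv(out / "mortality_outliers.csv", index=False)

        comp_rows = []
        for g in GENOTYPES:
            key_r = (g[0], g[1], "rapamycin")
            key_c = (g[0], g[1], "control")
            fit_r, fit_c = seg_fits[key_r], seg_fits[key_c]
            qs = _validated_percentiles(config.query_percentiles, fit_r, fit_c)
            lo = max(fit_r.x.min(), fit_c.x.min())
            hi = min(fit_r.x.max(), fit_c.x.max())
            inside = [q for q in qs if lo <= q <= hi]
            outside = [q for q in qs if not lo <= q <= hi]
            for q in outside:
                logger.warning("percentile %.0f%% outside the observed mortality "
                               "range [%.1f, %.1f] for %s; not evaluable", q, lo, hi, g)
                comp_rows.append({
                    "genotype": g, "pct_lifespan": q,
                    "mu_rapamycin": np.nan, "mu_rapa_lo": np.nan,
                    "mu_rapa_hi": np.nan, "mu_control": np.nan,
                    "mu_ctrl_lo": np.nan, "mu_ctrl_hi": np.nan, "differs": None})
            if inside:
                comp = segmented.compare_at_percentiles(fit_r, fit_c, inside)
                for j, q in enumerate(comp.percentiles):
                    comp_rows.append({
                        "genotype": g, "pct_lifespan": q,
                        "mu_rapamycin": comp.pred_a[j],
                        "mu_rapa_lo": comp.ci_a[j, 0], "mu_rapa_hi": comp.ci_a[j, 1],
                        "mu_control": comp.pred_b[j],
                        "mu_ctrl_lo": comp.ci_b[j, 0], "mu_ctrl_hi": comp.ci_b[j, 1],
                        "differs": bool(comp.differs[j])})
        comp_df = pd.DataFrame(comp_rows)
        comp_df.to_csv(out / "mortality_comparisons.csv", index=False)
        report["stages"]["mortality"] = {
            "K_by_group": {"/".join(map(str, k)): int(f.K) for k, f in seg_fits.items()},
            "r2_by_group": {"/".join(map(str, k)): float(f.r2) for k, f in seg_fits.items()},
            "comparisons": comp_df.to_dict("records"),
            "n_outliers_flagged": len(outlier_rows),
        }
    except Exception as exc:
        raise RuntimeError(f"[mortality] stage failed: {exc}") from exc

    # --- fecundity --------------------------------------------------------
    try:
        nb = fecundity.fit_negbin(eggs, response=config.fecundity_response)
        nb_anova = fecundity.type3_anova_nb(nb)
        nb_anova.to_csv(out / "fecundity_type3_anova.csv", index=False)
        pd.DataFrame({"term": ["intercept", *nb.terms], "coef": nb.coef}).to_csv(
            out / "fecundity_coefficients.csv", index=False)
        report["stages"]["fecundity"] = {
            "theta": nb.theta, "aic": nb.aic,
            "anova": nb_anova.to_dict("records"),
        }
    except Exception as exc:
        raise RuntimeError(f"[fecundity] stage failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report


def _validated_percentiles(percentiles, *fits):
    """Warn when a query percentile falls inside an inflection CI — the
    comparison points are meant to sit between inflections, not on them."""
    qs = tuple(percentiles)
    for fit in fits:
        for k in range(fit.K):
            lo, hi = fit.psi_ci[k]
            for q in qs:
                if lo <= q <= hi:
                    logger.warning(
                        "query percentile %.0f%% falls inside an inflection CI "
                        "[%.1f, %.1f]; interpret the comparison there with care",
                        q, lo, hi)
    return qs


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
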
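"""Synthetic cohorts with the factorial design and observation scheme of a
mito-nuclear x rapamycin lifespan study.

The generator emulates the study layout: 2 mitochondrial x 2 nuclear
backgrounds x 2 diets, 3 replicate populations per mitonucleogenotype,
10 vials of 15 females per condition, drug from day 3 of adulthood,
deaths scored at three visits per week. Latent death times come from a
location-scale survival family with a sum-to-zero factorial linear
predictor; observed death days are rounded up to the next scoring visit.
Egg counts per vial are negative binomial.

Ground-truth parameters live in :class:`SimTruth`, the target of the
parameter-recovery tests downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .design import FACTOR_LEVELS, FULL_TERMS, GENOTYPES, TREATMENTS, cell_row
from .families import get_family

EVENT_COLUMNS = [
    "fly_id", "population", "mito", "nuclear", "replicate", "treatment", "day", "status",
]
EGG_COLUMNS = [
    "vial_id", "mito", "nuclear", "replicate", "treatment", "n_females", "n_eggs",
]


def _default_egg_mu() -> dict[str, float]:
    # eggs per female per 24 h; rapamycin suppresses laying in every background
    mu = {}
    for g in GENOTYPES:
        mu[f"{g}:control"] = 4.0
        mu[f"{g}:rapamycin"] = 2.5
    return mu


@dataclass
class SimTruth:
    """Generating parameters for one synthetic study.

    ``beta`` maps sum-to-zero model terms (``intercept``, ``mito``, ...,
    ``mito:nuclear:treatment``) to location effects, in days for the
    raw-scale families (logistic, gaussian) and log-days for the log-scale
    families (weibull, exponential, lognormal, loglogistic). ``egg_mu``
    maps ``"<genotype>:<treatment>"`` cells to mean eggs per female.
    """

    distribution: str = "logistic"
    beta: dict[str, float] = field(
        default_factory=lambda: {"intercept": 60.0, "treatment": -3.0,
                                 "mito:nuclear:treatment": 1.5}
    )
    scale: float = 6.0
    n_per_vial: int = 15
    n_vials: int = 10
    n_replicates: int = 3
    scoring_interval_days: float = 7.0 / 3.0
    treatment_start_day: float = 3.0
    egg_mu: dict[str, float] = field(default_factory=_default_egg_mu)
    egg_theta: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        get_family(self.distribution)  # raises on unknown label
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.egg_theta <= 0:
            raise ValueError("egg_theta must be positive")
        for name in ("n_per_vial", "n_vials", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        allowed = set(FULL_TERMS) | {"intercept"}
        unknown = set(self.beta) - allowed
        if unknown:
            raise ValueError(f"unknown beta terms: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "SimTruth":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**cfg)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def visit_days(n_weeks: int, start_day: float = 3.0) -> np.ndarray:
    """Scoring-visit days: three visits per week on a Mon/Wed/Fri-like grid.

    Weekly blocks of offsets {0, 2, 4} days from ``start_day``, repeating
    every 7 days: 3, 5, 7, 10, 12, 14, 17, ...
    """
    weeks = np.arange(n_weeks)[:, None] * 7.0
    return (start_day + weeks + np.array([0.0, 2.0, 4.0])).ravel()


def _observed_day(latent: np.ndarray, start_day: float) -> np.ndarray:
    """Round latent death times UP to the next scoring visit."""
    horizon = int(np.ceil(latent.max() / 7.0)) + 2
    grid = visit_days(horizon, start_day)
    idx = np.searchsorted(grid, latent, side="left")
    return grid[idx]


def _linear_predictor(truth: SimTruth, mito: str, nuclear: str, treatment: str) -> float:
    terms = [t for t in FULL_TERMS if t in truth.beta]
    row = cell_row(terms, mito, nuclear, treatment)
    coefs = np.array([truth.beta.get("intercept", 0.0)] + [truth.beta[t] for t in terms])
    return float(row @ coefs)


def simulate_survival(truth: SimTruth) -> pd.DataFrame:
    """One event record per fly for the full factorial design.

    Returns a frame with columns ``fly_id, population, mito, nuclear,
    replicate, treatment, day, status`` (status 1 = death; the simulator
    itself censors nothing). Deterministic given ``truth.seed``; each
    replicate population draws from its own spawned random substream, so
    any single population is reproducible in isolation.
    """
    fam = get_family(truth.distribution)
    scale = fam.fixed_scale if fam.fixed_scale is not None else truth.scale
    n_per_arm = truth.n_vials * truth.n_per_vial
    pop_seeds = np.random.SeedSequence(truth.seed).spawn(
        len(GENOTYPES) * truth.n_replicates
    )

    frames = []
    fly0 = 0
    pop_i = 0
    for geno in GENOTYPES:
        mito, nuclear = geno[0], geno[1]
        for rep in range(1, truth.n_replicates + 1):
            rng = np.random.default_rng(pop_seeds[pop_i])
            pop_i += 1
            population = f"{geno}{rep}"
            for treatment in TREATMENTS:
                mu = _linear_predictor(truth, mito, nuclear, treatment)
                latent = _draw_latent(
                    fam, mu, scale, n_per_arm, truth.treatment_start_day, rng
                )
                day = _observed_day(latent, truth.treatment_start_day)
                frames.append(pd.DataFrame({
                    "fly_id": np.arange(fly0, fly0 + n_per_arm),
                    "population": population,
                    "mito": mito,
                    "nuclear": nuclear,
                    "replicate": rep,
                    "treatment": treatment,
                    "day": day,
                    "status": 1,
                }))
                fly0 += n_per_arm
    return pd.concat(frames, ignore_index=True)[EVENT_COLUMNS]


def _draw_latent(fam, mu, scale, n, start_day, rng, max_tries=1000):
    """Latent death times, redrawing any below the enrolment day.

    The assay enrols 3-day-old adults, so earlier latent deaths are
    truncated by redraw, keeping the factorial linear predictor
    interpretable as the untruncated location.
    """
    out = np.empty(n)
    need = np.ones(n, dtype=bool)
    for _ in range(max_tries):
        k = int(need.sum())
        if k == 0:
            return out
        w = fam.rvs(k, rng)
        y = mu + scale * w
        t = np.exp(y) if fam.log_scale else y
        out[need] = t
        need = out < start_day
    raise RuntimeError(
        "could not draw latent death times past the enrolment day; "
        "location is far below treatment_start_day"
    )


def simulate_eggs(truth: SimTruth) -> pd.DataFrame:
    """One negative-binomial egg count per vial per condition.

    Vial mean = ``n_per_vial * egg_mu[cell]``; dispersion ``egg_theta``
    (variance mu + mu^2/theta). Deterministic given ``truth.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(truth.seed).spawn(1)[0].spawn(1)[0])
    rows = []
    vial0 = 0
    for geno in GENOTYPES:
        for rep in range(1, truth.n_replicates + 1):
            for treatment in TREATMENTS:
                key = f"{geno}:{treatment}"
                if key not in truth.egg_mu:
                    raise KeyError(f"egg_mu has no entry for cell {key!r}")
                mu = truth.n_per_vial * truth.egg_mu[key]
                # NB as gamma-Poisson mixture: shape theta, mean mu
                lam = rng.gamma(truth.egg_theta, mu / truth.egg_theta, truth.n_vials)
                eggs = rng.poisson(lam)
                for v in range(truth.n_vials):
                    rows.append({
                        "vial_id": vial0 + v,
                        "mito": geno[0],
                        "nuclear": geno[1],
                        "replicate": rep,
                        "treatment": treatment,
                        "n_females": truth.n_per_vial,
                        "n_eggs": int(eggs[v]),
                    })
                vial0 += truth.n_vials
    return pd.DataFrame(rows)[EGG_COLUMNS]


def write_events(df: pd.DataFrame, path) -> None:
    df[EVENT_COLUMNS].to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event CSV missing columns: {sorted(missing)}")
    for factor in ("mito", "nuclear", "treatment"):
        bad = set(df[factor].astype(str)) - set(FACTOR_LEVELS[factor])
        if bad:
            raise ValueError(f"unknown {factor} level(s): {sorted(bad)}")
    if (df["day"] <= 0).any():
        raise ValueError("event days must be positive")
    return df


def write_eggs(df: pd.DataFrame, path) -> None:
    df[EGG_COLUMNS].to_csv(path, index=False)


def read_eggs(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EGG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"egg CSV missing columns: {sorted(missing)}")
    if (df["n_females"] < 1).any():
        raise ValueError("n_females must be >= 1")
    return df
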
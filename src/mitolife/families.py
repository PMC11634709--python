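"""Location-scale survival families shared by the simulator and the fitter.

A family is defined by a standard variate W and a flag saying whether the
linear predictor acts on time (``log_scale=False``: logistic, gaussian) or
on log time (``log_scale=True``: weibull, exponential, lognormal,
loglogistic), i.e. y = x'beta + sigma*W with y = t or y = ln t. The
exponential family is Weibull with sigma fixed at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import special, stats


@dataclass(frozen=True)
class Family:
    name: str
    log_scale: bool
    logpdf: Callable[[np.ndarray], np.ndarray]   # of the standard variate
    logsf: Callable[[np.ndarray], np.ndarray]
    dlogpdf: Callable[[np.ndarray], np.ndarray]  # d/dw ln f(w)
    dlogsf: Callable[[np.ndarray], np.ndarray]   # d/dw ln S(w) = -hazard
    rvs: Callable  # (size, rng) -> standard variates
    sd: float      # standard deviation of W, for scale initialisation
    fixed_scale: float | None = None


def _logis_dlogpdf(w):
    return 1.0 - 2.0 * special.expit(w)


def _logis_dlogsf(w):
    return -special.expit(w)


def _norm_dlogpdf(w):
    return -w


def _norm_dlogsf(w):
    # -phi(w)/Phi(-w), computed on the log scale for tail stability
    return -np.exp(stats.norm.logpdf(w) - stats.norm.logsf(w))


def _gumbel_min_logpdf(w):
    return w - np.exp(w)


def _gumbel_min_logsf(w):
    return -np.exp(w)


def _gumbel_min_dlogpdf(w):
    return 1.0 - np.exp(w)


def _gumbel_min_dlogsf(w):
    return -np.exp(w)


def _gumbel_min_rvs(size, rng):
    # W = ln E, E ~ Exp(1): P(W > w) = exp(-e^w)
    return np.log(rng.exponential(size=size))


FAMILIES: dict[str, Family] = {
    "logistic": Family(
        "logistic", False, stats.logistic.logpdf, stats.logistic.logsf,
        _logis_dlogpdf, _logis_dlogsf,
        lambda size, rng: rng.logistic(size=size), sd=np.pi / np.sqrt(3.0),
    ),
    "gaussian": Family(
        "gaussian", False, stats.norm.logpdf, stats.norm.logsf,
        _norm_dlogpdf, _norm_dlogsf,
        lambda size, rng: rng.standard_normal(size=size), sd=1.0,
    ),
    "weibull": Family(
        "weibull", True, _gumbel_min_logpdf, _gumbel_min_logsf,
        _gumbel_min_dlogpdf, _gumbel_min_dlogsf,
        _gumbel_min_rvs, sd=np.pi / np.sqrt(6.0),
    ),
    "exponential": Family(
        "exponential", True, _gumbel_min_logpdf, _gumbel_min_logsf,
        _gumbel_min_dlogpdf, _gumbel_min_dlogsf,
        _gumbel_min_rvs, sd=np.pi / np.sqrt(6.0), fixed_scale=1.0,
    ),
    "lognormal": Family(
        "lognormal", True, stats.norm.logpdf, stats.norm.logsf,
        _norm_dlogpdf, _norm_dlogsf,
        lambda size, rng: rng.standard_normal(size=size), sd=1.0,
    ),
    "loglogistic": Family(
        "loglogistic", True, stats.logistic.logpdf, stats.logistic.logsf,
        _logis_dlogpdf, _logis_dlogsf,
        lambda size, rng: rng.logistic(size=size), sd=np.pi / np.sqrt(3.0),
    ),
}


def get_family(name: str) -> Family:
    try:
        return FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown distribution {name!r}; choose from {sorted(FAMILIES)}"
        ) from None
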
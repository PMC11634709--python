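import logging

import numpy as np
import pandas as pd
import pytest

from mitolife import SimTruth, simulate_survival

logging.getLogger("mitolife").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_truth():
    return SimTruth(seed=11)


@pytest.fixture(scope="session")
def default_events(default_truth):
    return simulate_survival(default_truth)


def make_events(days, status=None, **factors):
    """Minimal event frame for hand-computed demography examples."""
    days = np.asarray(days, dtype=float)
    n = len(days)
    status = np.ones(n, dtype=int) if status is None else np.asarray(status, int)
    base = {
        "fly_id": np.arange(n), "population": "AA1", "mito": "A",
        "nuclear": "A", "replicate": 1, "treatment": "control",
        "day": days, "status": status,
    }
    base.update(factors)
    return pd.DataFrame(base)


def two_segment_data(rng, n=60, psi=50.0, b0=-3.0, s1=-0.02, s2=0.06, sigma=0.05):
    """Noisy draw from a fixed one-kink piecewise-linear truth."""
    x = np.sort(rng.uniform(0.0, 100.0, n))
    y = b0 + s1 * x + (s2 - s1) * np.maximum(x - psi, 0.0)
    return x, y + rng.normal(0.0, sigma, n)
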
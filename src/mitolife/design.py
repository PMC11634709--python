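"""Sum-to-zero coding for the 2x2x2 mito x nuclear x treatment factorial.

Every model in the package (parametric survival, negative binomial) uses
the same contrast convention: each two-level factor is coded +1 for its
alphabetically first level and -1 for the second (``contr.sum`` with
alphabetical level order), so coefficient signs are reproducible across
runs and software. Interaction columns are elementwise products of the
main-effect codes.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: factor -> ordered levels; first level is coded +1, second -1
FACTOR_LEVELS: dict[str, tuple[str, str]] = {
    "mito": ("A", "B"),
    "nuclear": ("A", "B"),
    "treatment": ("control", "rapamycin"),
}

#: model terms of the full factorial, in display order
FULL_TERMS: tuple[str, ...] = (
    "mito",
    "nuclear",
    "treatment",
    "mito:nuclear",
    "mito:treatment",
    "nuclear:treatment",
    "mito:nuclear:treatment",
)

TREATMENTS = FACTOR_LEVELS["treatment"]
GENOTYPES = ("AA", "AB", "BA", "BB")  # mito then nuclear letter


def factor_code(values: Iterable[str], factor: str) -> np.ndarray:
    """Sum-to-zero codes (+1/-1) for one factor column."""
    first, second = FACTOR_LEVELS[factor]
    values = np.asarray(list(values), dtype=object)
    codes = np.where(values == first, 1.0, np.where(values == second, -1.0, np.nan))
    if np.isnan(codes).any():
        bad = sorted(set(values) - set(FACTOR_LEVELS[factor]))
        raise ValueError(f"unknown level(s) {bad!r} for factor {factor!r}")
    return codes


def term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    """Design column for a (possibly interaction) term, e.g. ``mito:treatment``."""
    col = np.ones(len(df))
    for factor in term.split(":"):
        col = col * factor_code(df[factor], factor)
    return col


def design_matrix(df: pd.DataFrame, terms: Sequence[str] = FULL_TERMS) -> pd.DataFrame:
    """Design matrix with intercept plus the requested sum-to-zero terms."""
    out = {"intercept": np.ones(len(df))}
    for term in terms:
        out[term] = term_column(df, term)
    return pd.DataFrame(out, index=df.index)


def cell_row(terms: Sequence[str], mito: str, nuclear: str, treatment: str) -> np.ndarray:
    """A single design row (intercept first) for one factor cell."""
    cell = pd.DataFrame({"mito": [mito], "nuclear": [nuclear], "treatment": [treatment]})
    return design_matrix(cell, terms).to_numpy()[0]


def reference_grid() -> pd.DataFrame:
    """All 8 factor cells, ordered by genotype then treatment."""
    rows = [
        {"mito": g[0], "nuclear": g[1], "treatment": t}
        for g in GENOTYPES
        for t in TREATMENTS
    ]
    return pd.DataFrame(rows)
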
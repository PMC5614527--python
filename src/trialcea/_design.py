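"""Design-matrix assembly shared by the imputation and analysis modules.

Categorical columns (pandas ``object``/``category`` dtype or the known
categorical trial fields) expand to treatment-coded dummies with the first
category, in sorted order, as reference — fixed ordering keeps every fit
reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def term_columns(df: pd.DataFrame, term: str) -> tuple[np.ndarray, list[str]]:
    """Columns and names contributed by one model term."""
    s = df[term]
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
        cats = sorted(pd.unique(s.astype(str)))
        cols = [(s.astype(str) == c).to_numpy(dtype=float) for c in cats[1:]]
        names = [f"{term}[{c}]" for c in cats[1:]]
        if not cols:  # constant categorical: contributes nothing
            return np.empty((len(s), 0)), []
        return np.column_stack(cols), names
    return s.to_numpy(dtype=float)[:, None], [term]


def design_matrix(
    df: pd.DataFrame, terms: list[str]
) -> tuple[np.ndarray, list[str], dict[str, slice]]:
    """Intercept + term columns; returns (X, column names, term -> slice)."""
    blocks = [np.ones((len(df), 1))]
    names = ["const"]
    slices: dict[str, slice] = {}
    pos = 1
    for t in terms:
        cols, cnames = term_columns(df, t)
        blocks.append(cols)
        names.extend(cnames)
        slices[t] = slice(pos, pos + cols.shape[1])
        pos += cols.shape[1]
    return np.hstack(blocks), names, slices
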
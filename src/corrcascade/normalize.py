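"""Quantile normalization across samples.

Every column is forced onto a common reference distribution: the per-rank
mean (or median) of the column-sorted values.  Ties within a column receive
the average of the reference values over the tied rank span, so tied inputs
stay tied and within-column rank order is preserved exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["quantile_normalize"]


def quantile_normalize(expr: pd.DataFrame, reference: str = "mean") -> pd.DataFrame:
    """Quantile-normalize an expression matrix (rows=genes, columns=samples).

    Parameters
    ----------
    expr
        Numeric matrix with at least one column.
    reference
        ``"mean"`` (default) or ``"median"`` of the column-sorted values at
        each rank.

    Returns
    -------
    DataFrame of the same shape whose columns all share one value multiset
    (up to tie-averaging).
    """
    if reference not in ("mean", "median"):
        raise ValueError(f"reference must be 'mean' or 'median', got {reference!r}")
    X = expr.to_numpy(dtype=float)
    if X.size == 0:
        raise ValueError("cannot normalize an empty matrix")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; drop or impute first")
    sorted_cols = np.sort(X, axis=0)
    ref = sorted_cols.mean(axis=1) if reference == "mean" else np.median(sorted_cols, axis=1)
    n = X.shape[0]
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = ref
        # ties get the mean reference value over their whole rank span
        _, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if (counts > 1).any():
            sums = np.bincount(inv, weights=assigned)
            assigned = (sums / counts)[inv]
        out[:, j] = assigned
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)
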
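"""Anchor-gene correlation screening and the transcription-factor cascade.

The screening logic works in three layers:

1. *Anchor screen* — correlate every candidate gene with a fixed anchor
   (e.g. a growth-factor receptor) separately in tumor and normal samples and
   classify each coefficient against empirical-null thresholds, flagging
   genes whose association is tumor-specific.
2. *Multi-anchor counting* — for a set of anchors (e.g. the seven mevalonate
   pathway genes), count per gene how many anchors it is significantly
   correlated with in a given direction, and keep genes reaching a minimum
   count.
3. *Cascade* — starting from transcription-factor subunit genes (NFYA/B/C by
   default), select genes positively correlated with at least one subunit,
   then keep those whose count of positive correlations with the
   anchor-associated gene set reaches a data-derived count threshold (the top
   2.5th percentile of that count over all genes in the matrix).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .empirical_null import (
    NEGATIVE,
    NONSIGNIFICANT,
    POSITIVE,
    NullThresholds,
    classify_correlation,
    standardize_rows,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MEVALONATE_GENES",
    "FATTY_ACID_GENES",
    "NFY_SUBUNITS",
    "AnchorScreenResult",
    "CountThreshold",
    "CascadeResult",
    "pearson_matrix",
    "screen_against_anchor",
    "count_anchor_associations",
    "derive_count_threshold",
    "nfy_cascade",
]

#: mevalonate / early sterol biosynthesis enzymes used as anchors
MEVALONATE_GENES: tuple[str, ...] = (
    "FDFT1", "FDPS", "HMGCS1", "IDI1", "LSS", "EBP", "MVK",
)
#: fatty-acid synthesis genes used as the secondary anchor set
FATTY_ACID_GENES: tuple[str, ...] = (
    "FADS1", "FADS2", "FASN", "SCD", "ELOVL2", "PGS1", "FA2H",
)
#: CCAAT-binding factor NF-Y subunit genes
NFY_SUBUNITS: tuple[str, ...] = ("NFYA", "NFYB", "NFYC")


def _check_ids(expr: pd.DataFrame, ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    missing = [g for g in ids if g not in expr.index]
    if missing:
        raise KeyError(f"{what} not in matrix: {missing[:10]}")
    return ids


def pearson_matrix(
    expr: pd.DataFrame,
    rows_a: Sequence[str],
    rows_b: Sequence[str],
) -> pd.DataFrame:
    """Pearson coefficients between two row sets across all columns.

    Constant rows yield NaN entries with a warning.
    """
    rows_a = _check_ids(expr, rows_a, "rows_a")
    rows_b = _check_ids(expr, rows_b, "rows_b")
    if expr.shape[1] < 3:
        raise ValueError("need >=3 samples to correlate")
    Z, ok = standardize_rows(expr.to_numpy(dtype=float))
    ok_s = pd.Series(ok, index=expr.index)
    ia = expr.index.get_indexer(rows_a)
    ib = expr.index.get_indexer(rows_b)
    R = Z[ia] @ Z[ib].T
    bad_a, bad_b = ~ok_s[rows_a].to_numpy(), ~ok_s[rows_b].to_numpy()
    if bad_a.any() or bad_b.any():
        warnings.warn("constant rows produce NaN correlations", stacklevel=2)
        R[bad_a, :] = np.nan
        R[:, bad_b] = np.nan
    return pd.DataFrame(R, index=pd.Index(rows_a), columns=pd.Index(rows_b))


@dataclass
class AnchorScreenResult:
    """Per-candidate correlations against one anchor in both sample groups."""

    anchor: str
    table: pd.DataFrame  # gene, r_tumor, r_normal, class_tumor, class_normal, cancer_specific
    thresholds: NullThresholds

    def hits(self, direction: str) -> pd.DataFrame:
        """Candidates significant in ``direction`` in the tumor group."""
        if direction not in (NEGATIVE, POSITIVE):
            raise ValueError(f"direction must be negative/positive, got {direction!r}")
        return self.table[self.table["class_tumor"] == direction]


def screen_against_anchor(
    expr_tumor: pd.DataFrame,
    expr_normal: pd.DataFrame,
    anchor: str,
    candidates: Sequence[str],
    thr: NullThresholds,
    direction: str | None = None,
) -> AnchorScreenResult:
    """Correlate candidates with an anchor gene in tumor and normal samples.

    Returns one row per candidate with coefficients and significance classes
    in both groups, plus a ``cancer_specific`` flag (significant in tumor,
    nonsignificant in normal).  ``direction``, if given, pre-filters the
    stored table's convenience view but never the table itself.
    """
    candidates = [c for c in candidates if c != anchor]
    if not candidates:
        table = pd.DataFrame(columns=["gene", "r_tumor", "r_normal", "class_tumor",
                                      "class_normal", "cancer_specific"])
        return AnchorScreenResult(anchor, table, thr)
    for name, mat in (("tumor", expr_tumor), ("normal", expr_normal)):
        _check_ids(mat, [anchor], "anchor")
        if mat.loc[anchor].nunique() <= 1:
            raise ValueError(f"anchor {anchor!r} is constant in the {name} group")
    r_t = pearson_matrix(expr_tumor, candidates, [anchor]).iloc[:, 0]
    r_n = pearson_matrix(expr_normal, candidates, [anchor]).iloc[:, 0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cls_t = classify_correlation(r_t.to_numpy(), thr)
        cls_n = classify_correlation(r_n.to_numpy(), thr)
    table = pd.DataFrame({
        "gene": candidates,
        "r_tumor": r_t.to_numpy(),
        "r_normal": r_n.to_numpy(),
        "class_tumor": cls_t,
        "class_normal": cls_n,
    })
    table["cancer_specific"] = (
        (table["class_tumor"] != NONSIGNIFICANT)
        & (table["class_normal"] == NONSIGNIFICANT)
    )
    result = AnchorScreenResult(anchor, table, thr)
    if direction is not None:
        result.table.attrs["direction"] = direction
    return result


def _significance_counts(
    expr: pd.DataFrame,
    reference: Sequence[str],
    thr: NullThresholds,
    direction: str,
) -> pd.Series:
    """Per-gene count of significant correlations with a reference gene set.

    Self-correlations (a gene with itself when it belongs to the reference
    set) are excluded from its own count.
    """
    if direction not in (NEGATIVE, POSITIVE):
        raise ValueError(f"direction must be negative/positive, got {direction!r}")
    reference = _check_ids(expr, list(dict.fromkeys(reference)), "reference genes")
    Z, ok = standardize_rows(expr.to_numpy(dtype=float))
    iref = expr.index.get_indexer(reference)
    R = Z @ Z[iref].T  # n_genes x n_ref
    R[~ok, :] = np.nan
    R[:, ~ok[iref]] = np.nan
    if thr.strict:
        sig = (R < thr.lower) if direction == NEGATIVE else (R > thr.upper)
    else:
        sig = (R <= thr.lower) if direction == NEGATIVE else (R >= thr.upper)
    sig = np.where(np.isnan(R), False, sig)
    # zero the diagonal entries where gene == reference member
    pos = {g: k for k, g in enumerate(reference)}
    for g, k in pos.items():
        sig[expr.index.get_loc(g), k] = False
    return pd.Series(sig.sum(axis=1), index=expr.index, name="count")


def count_anchor_associations(
    expr: pd.DataFrame,
    anchors: Sequence[str],
    thr: NullThresholds,
    direction: str,
    min_count: int = 3,
) -> tuple[pd.Series, set[str]]:
    """Count per gene its significant associations with the anchor set.

    Returns the full count table and the set of genes whose count reaches
    ``min_count``.  Anchors never count themselves.
    """
    anchors = list(dict.fromkeys(anchors))
    if not anchors:
        raise ValueError("anchor set is empty")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = _significance_counts(expr, anchors, thr, direction)
    if min_count > len(anchors):
        warnings.warn(
            f"min_count={min_count} exceeds the {len(anchors)} anchors; "
            "no gene can qualify", stacklevel=2,
        )
        return counts, set()
    selected = set(counts.index[counts >= min_count])
    return counts, selected


@dataclass(frozen=True)
class CountThreshold:
    """Integer cutoff on multi-reference association counts."""

    value: int
    percentile: float = 97.5
    universe_size: int = 0
    counts: pd.Series | None = field(default=None, repr=False, compare=False)


def derive_count_threshold(
    expr: pd.DataFrame,
    reference_set: Sequence[str],
    thr: NullThresholds,
    percentile: float = 97.5,
    *,
    rounding: str = "ceil",
) -> CountThreshold:
    """Data-derived count cutoff: the top tail of the per-gene count of
    positive-significant correlations with ``reference_set`` over every gene
    in the matrix, integerized with ceiling by default (a count threshold
    must be attainable).
    """
    reference_set = list(dict.fromkeys(reference_set))
    if not reference_set:
        raise ValueError("reference set is empty")
    counts = _significance_counts(expr, reference_set, thr, POSITIVE)
    raw = float(np.percentile(counts.to_numpy(), percentile))
    if rounding == "ceil":
        value = math.ceil(raw)
    elif rounding == "round":
        value = int(round(raw))
    elif rounding == "floor":
        value = math.floor(raw)
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    value = min(value, int(counts.max()))
    return CountThreshold(int(value), percentile, len(counts), counts)


@dataclass
class CascadeResult:
    """All layers of the subunit-to-target cascade."""

    per_subunit: dict[str, set[str]]
    union: set[str]
    final: set[str]
    counts: pd.Series  # counts of union genes against the associated set
    count_threshold: CountThreshold

    @property
    def per_subunit_sizes(self) -> dict[str, int]:
        return {s: len(g) for s, g in self.per_subunit.items()}


def nfy_cascade(
    expr: pd.DataFrame,
    subunit_genes: Sequence[str],
    mev_assoc: Iterable[str],
    thr: NullThresholds,
    count_thr: CountThreshold,
) -> CascadeResult:
    """Two-stage cascade from transcription-factor subunits to targets.

    Stage 1 keeps genes positively significant with at least one subunit;
    stage 2 keeps stage-1 genes whose count of positive-significant
    correlations with the ``mev_assoc`` set reaches ``count_thr.value``.
    """
    subunit_genes = list(dict.fromkeys(subunit_genes))
    missing = [s for s in subunit_genes if s not in expr.index]
    if missing:
        raise KeyError(f"subunit gene(s) missing from matrix: {missing}")
    mev_assoc = [g for g in dict.fromkeys(mev_assoc) if g in expr.index]

    per_subunit: dict[str, set[str]] = {}
    R = pearson_matrix(expr, list(expr.index), subunit_genes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in subunit_genes:
            cls = classify_correlation(R[s].to_numpy(), thr)
            genes = set(R.index[(cls == POSITIVE)]) - {s}
            per_subunit[s] = genes
    union: set[str] = set().union(*per_subunit.values()) if per_subunit else set()

    if union and mev_assoc:
        sub_expr = expr.loc[sorted(union | set(mev_assoc))]
        counts_all = _significance_counts(sub_expr, mev_assoc, thr, POSITIVE)
        counts = counts_all.loc[sorted(union)]
    else:
        counts = pd.Series(dtype=int)
    final = set(counts.index[counts >= count_thr.value]) if len(counts) else set()
    return CascadeResult(per_subunit, union, final, counts, count_thr)
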
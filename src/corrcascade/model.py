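"""Model/Results interface over the correlation-cascade analysis.

:class:`CorrelationCascadeModel` bundles an expression matrix, sample group
labels and the screening configuration; :meth:`fit` runs quantile
normalization, the empirical correlation null, multi-anchor association
counting and the subunit cascade, returning a :class:`CascadeResults` object
that carries every intermediate product, offers Table-style views, enrichment
and hub analyses, and prints a summary.

Example
-------
>>> from corrcascade import CorrelationCascadeModel, synthetic
>>> expr, groups, truth = synthetic.generate_expression(
...     synthetic.SyntheticConfig(seed=0))
>>> res = CorrelationCascadeModel(expr, groups, seed=0).fit()
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import cascade as _cascade
from .cascade import (
    MEVALONATE_GENES,
    NFY_SUBUNITS,
    AnchorScreenResult,
    CascadeResult,
    CountThreshold,
)
from .empirical_null import (
    NEGATIVE,
    POSITIVE,
    NullConfig,
    NullThresholds,
    build_null_thresholds,
)
from .expr_io import subset_samples, validate_expression
from .normalize import quantile_normalize

__all__ = ["CorrelationCascadeModel", "CascadeResults"]


class CorrelationCascadeModel:
    """Correlation-cascade screen of a two-group expression matrix.

    Parameters
    ----------
    expr
        genes x samples matrix (log2 scale assumed).
    groups
        sample id -> group label; both groups must be non-empty.
    anchors
        anchor gene set for association counting (default: the seven
        mevalonate-pathway genes).
    subunits
        transcription-factor subunit genes seeding the cascade (default:
        NFYA/NFYB/NFYC).
    tumor_label, normal_label
        which group labels play the tumor/normal roles.
    null_config
        empirical-null settings (pair count, percentiles).
    normalize
        quantile-normalize across all samples before analysis (default True).
    min_anchor_count
        anchors a gene must associate with to enter the associated set.
    count_percentile
        percentile of the per-gene count distribution defining the cascade's
        stage-2 cutoff.
    """

    def __init__(
        self,
        expr: pd.DataFrame,
        groups: Mapping[str, str] | pd.Series,
        *,
        anchors: Sequence[str] = MEVALONATE_GENES,
        subunits: Sequence[str] = NFY_SUBUNITS,
        tumor_label: str = "tumor",
        normal_label: str = "normal",
        null_config: NullConfig | None = None,
        normalize: bool = True,
        min_anchor_count: int = 3,
        count_percentile: float = 97.5,
        seed: int | None = None,
    ) -> None:
        self.expr = validate_expression(pd.DataFrame(expr))
        self.groups = pd.Series(groups)
        missing = [s for s in self.expr.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing[:5]}")
        for label in (tumor_label, normal_label):
            if label not in set(self.groups.values):
                raise ValueError(f"group {label!r} absent from the labels")
        self.anchors = [a for a in anchors if a in self.expr.index]
        if not self.anchors:
            raise ValueError("no anchor gene present in the matrix")
        self.subunits = list(subunits)
        self.tumor_label = tumor_label
        self.normal_label = normal_label
        self.null_config = null_config or NullConfig(
            seed=seed, sample_group=tumor_label
        )
        if seed is not None and self.null_config.seed is None:
            self.null_config = NullConfig(
                self.null_config.n_pairs, self.null_config.lower_pct,
                self.null_config.upper_pct, seed, tumor_label,
            )
        self.normalize = normalize
        self.min_anchor_count = min_anchor_count
        self.count_percentile = count_percentile

    @classmethod
    def from_dataframe(
        cls,
        expr: pd.DataFrame,
        groups: Mapping[str, str] | pd.Series,
        **kwargs,
    ) -> "CorrelationCascadeModel":
        return cls(expr, groups, **kwargs)

    def fit(self) -> "CascadeResults":
        """Run normalization, the empirical null and the full cascade."""
        expr = quantile_normalize(self.expr) if self.normalize else self.expr
        tumor = subset_samples(expr, self.groups, self.tumor_label)
        normal = subset_samples(expr, self.groups, self.normal_label)
        thresholds = build_null_thresholds(tumor, self.null_config)
        pos_counts, mev_assoc_pos = _cascade.count_anchor_associations(
            tumor, self.anchors, thresholds, POSITIVE, self.min_anchor_count
        )
        neg_counts, mev_assoc_neg = _cascade.count_anchor_associations(
            tumor, self.anchors, thresholds, NEGATIVE, self.min_anchor_count
        )
        if mev_assoc_pos:
            count_thr = _cascade.derive_count_threshold(
                tumor, sorted(mev_assoc_pos), thresholds, self.count_percentile
            )
        else:  # degenerate screen: no gene qualified against the anchors
            count_thr = CountThreshold(0, self.count_percentile, len(tumor))
        present_subunits = [s for s in self.subunits if s in tumor.index]
        cascade_result = None
        if present_subunits:
            cascade_result = _cascade.nfy_cascade(
                tumor, present_subunits, sorted(mev_assoc_pos), thresholds,
                count_thr,
            )
        return CascadeResults(
            model=self,
            normalized=expr,
            tumor=tumor,
            normal=normal,
            thresholds=thresholds,
            anchor_counts_positive=pos_counts,
            anchor_counts_negative=neg_counts,
            associated_positive=mev_assoc_pos,
            associated_negative=mev_assoc_neg,
            count_threshold=count_thr,
            cascade=cascade_result,
        )


@dataclass
class CascadeResults:
    """Fitted correlation-cascade results.

    Attributes mirror the analysis stages: empirical-null ``thresholds``,
    per-gene anchor-association counts in both directions, the associated
    gene sets, the stage-2 ``count_threshold`` and the ``cascade`` layers
    (per-subunit sets, their union, and the final set).
    """

    model: CorrelationCascadeModel = field(repr=False)
    normalized: pd.DataFrame = field(repr=False)
    tumor: pd.DataFrame = field(repr=False)
    normal: pd.DataFrame = field(repr=False)
    thresholds: NullThresholds
    anchor_counts_positive: pd.Series = field(repr=False)
    anchor_counts_negative: pd.Series = field(repr=False)
    associated_positive: set[str]
    associated_negative: set[str]
    count_threshold: CountThreshold
    cascade: CascadeResult | None

    # ---- convenience analyses -------------------------------------------

    def screen(
        self,
        anchor: str,
        candidates: Sequence[str] | None = None,
        direction: str | None = None,
    ) -> AnchorScreenResult:
        """Tumor-vs-normal anchor screen at the fitted thresholds."""
        if candidates is None:
            candidates = [g for g in self.tumor.index if g != anchor]
        return _cascade.screen_against_anchor(
            self.tumor, self.normal, anchor, list(candidates),
            self.thresholds, direction,
        )

    def anchor_count_table(self) -> pd.DataFrame:
        """Per-anchor counts of significantly correlated genes (both signs)."""
        rows = []
        for a in self.model.anchors:
            counts_p = _cascade._significance_counts(
                self.tumor, [a], self.thresholds, POSITIVE)
            counts_n = _cascade._significance_counts(
                self.tumor, [a], self.thresholds, NEGATIVE)
            rows.append((a, int((counts_p > 0).sum()), int((counts_n > 0).sum())))
        return pd.DataFrame(rows, columns=["anchor", "positive", "negative"])

    def enrich(self, collection, query: Iterable[str] | None = None,
               alpha: float = 0.025, **kw) -> pd.DataFrame:
        """Over-representation of a result set (default: the final cascade
        set) against a GMT collection, background = all matrix genes."""
        from .enrichment import enrich as _enrich
        if query is None:
            if self.cascade is None:
                raise ValueError("no cascade result; pass a query explicitly")
            query = self.cascade.final
        return _enrich(query, set(self.normalized.index), collection,
                       alpha, **kw)

    def hub_analysis(self, graph, *, max_path: int = 2, **kw):
        """Seed-set subnetwork plus hub classification, seeded by the
        subunits (set A) and the final cascade set (set B)."""
        from .ppi import build_subnetwork, find_hubs
        if self.cascade is None:
            raise ValueError("no cascade result to seed the network with")
        seeds_a = [s for s in self.model.subunits]
        seeds_b = sorted(self.cascade.final)
        sub = build_subnetwork(graph, seeds_a, seeds_b, max_path=max_path)
        return find_hubs(sub, seeds_b, seeds_a=seeds_a, **kw)

    # ---- reporting -------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Correlation cascade results",
            "=" * 45,
            f"genes x samples        {self.normalized.shape[0]} x {self.normalized.shape[1]}"
            f" ({self.tumor.shape[1]} {self.model.tumor_label}, "
            f"{self.normal.shape[1]} {self.model.normal_label})",
            f"null pairs             {len(self.thresholds.null_sample)}",
            f"null thresholds        [{self.thresholds.lower:+.3f}, "
            f"{self.thresholds.upper:+.3f}]",
            f"anchors                {', '.join(self.model.anchors)}",
            f"assoc >= {self.model.min_anchor_count} anchors     "
            f"{len(self.associated_positive)} positive, "
            f"{len(self.associated_negative)} negative",
            f"count threshold        >= {self.count_threshold.value} "
            f"(top {100 - self.count_threshold.percentile:g}% of "
            f"{self.count_threshold.universe_size} genes)",
        ]
        if self.cascade is not None:
            sizes = ", ".join(f"{s}:{n}" for s, n in
                              self.cascade.per_subunit_sizes.items())
            lines += [
                f"per-subunit hits       {sizes}",
                f"subunit union          {len(self.cascade.union)}",
                f"final cascade set      {len(self.cascade.final)}",
            ]
        return "\n".join(lines)

    def plot_null(self, ax=None):
        """Histogram of the resampled correlation null with threshold lines."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.thresholds.null_sample, bins=80, color="0.7",
                density=True)
        for x, lab in ((self.thresholds.lower, "lower"),
                       (self.thresholds.upper, "upper")):
            ax.axvline(x, color="crimson", linestyle="--", label=f"{lab} {x:+.3f}")
        ax.set_xlabel("Pearson r (random gene pairs)")
        ax.set_ylabel("density")
        ax.legend()
        return ax
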
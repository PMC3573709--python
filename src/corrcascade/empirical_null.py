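"""Resampling-based null distribution for Pearson correlations.

Significance cutoffs for co-expression are taken from the empirical
distribution of Pearson coefficients over random pairs of distinct genes
drawn from the same matrix: the lower/upper tail percentiles (2.5th/97.5th by
default, from 100,000 pairs) become the thresholds for calling a correlation
significantly negative or positive.  This sidesteps distributional
assumptions about array data at the cost of dataset-specific cutoffs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NullConfig",
    "NullThresholds",
    "sample_pair_null",
    "derive_thresholds",
    "build_null_thresholds",
    "classify_correlation",
    "NEGATIVE",
    "NONSIGNIFICANT",
    "POSITIVE",
]

NEGATIVE = "negative"
NONSIGNIFICANT = "nonsignificant"
POSITIVE = "positive"


@dataclass(frozen=True)
class NullConfig:
    """Settings for the resampled correlation null."""

    n_pairs: int = 100_000
    lower_pct: float = 2.5
    upper_pct: float = 97.5
    seed: int | None = None
    sample_group: str | None = "tumor"

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower_pct < self.upper_pct <= 100.0):
            raise ValueError("need 0 <= lower_pct < upper_pct <= 100")
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be non-negative")


@dataclass
class NullThresholds:
    """Significance cutoffs derived from a resampled correlation null."""

    lower: float
    upper: float
    null_sample: np.ndarray = field(repr=False)
    config: NullConfig = field(default_factory=NullConfig)
    strict: bool = False  # if True, require strict inequality at the cutoff

    def __post_init__(self) -> None:
        if not (self.lower < self.upper):
            raise ValueError(
                f"degenerate thresholds: lower={self.lower} >= upper={self.upper}"
            )
        if abs(self.lower) > 1 or abs(self.upper) > 1:
            raise ValueError("thresholds must lie in [-1, 1]")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "lower": self.lower,
            "upper": self.upper,
            "n_pairs": int(len(self.null_sample)),
            "lower_pct": self.config.lower_pct,
            "upper_pct": self.config.upper_pct,
            "seed": self.config.seed,
            "group": self.config.sample_group,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit norm; returns (Z, nonconstant mask).

    With Z rows unit-norm, the Pearson coefficient of rows i and j is the dot
    product Z[i] @ Z[j].
    """
    X = np.asarray(X, dtype=float)
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    # a row is constant iff its range is exactly zero; centering alone can
    # leave ~1e-16 residuals that would masquerade as variance
    ok = (norms > 0) & (X.max(axis=1) > X.min(axis=1))
    Z = np.zeros_like(centered)
    Z[ok] = centered[ok] / norms[ok, None]
    return Z, ok


def sample_pair_null(
    expr: pd.DataFrame,
    config: NullConfig | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Pearson coefficients for ``n_pairs`` random pairs of distinct rows.

    Pairs are drawn uniformly with replacement across draws; self-pairs and
    pairs involving constant rows are redrawn (redraw count is logged).  The
    matrix should already be restricted to the sample group of interest.
    """
    config = config or NullConfig()
    if config.n_pairs == 0:
        return np.empty(0)
    X = expr.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_genes < 2 or n_samples < 3:
        raise ValueError("need >=2 rows and >=3 samples for a correlation null")
    Z, ok = standardize_rows(X)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 non-constant rows")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n = config.n_pairs
    i = rng.integers(0, n_genes, size=n)
    j = rng.integers(0, n_genes, size=n)
    n_redrawn = 0
    bad = (i == j) | ~ok[i] | ~ok[j]
    while bad.any():
        n_redrawn += int(bad.sum())
        i[bad] = rng.integers(0, n_genes, size=int(bad.sum()))
        j[bad] = rng.integers(0, n_genes, size=int(bad.sum()))
        bad = (i == j) | ~ok[i] | ~ok[j]
    if n_redrawn:
        logger.info("redrew %d invalid pairs (self-pairs or constant rows)", n_redrawn)
    return np.einsum("ij,ij->i", Z[i], Z[j])


def derive_thresholds(
    null_sample: np.ndarray,
    config: NullConfig | None = None,
    *,
    strict: bool = False,
) -> NullThresholds:
    """Percentile cutoffs (linear-interpolation convention) from a null sample."""
    config = config or NullConfig()
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size == 0:
        raise ValueError("empty null sample")
    lower, upper = np.percentile(null_sample, [config.lower_pct, config.upper_pct])
    return NullThresholds(float(lower), float(upper), null_sample, config, strict)


def build_null_thresholds(
    expr: pd.DataFrame,
    config: NullConfig | None = None,
    *,
    rng: np.random.Generator | None = None,
    strict: bool = False,
) -> NullThresholds:
    """Convenience wrapper: sample the pair null and derive its thresholds."""
    config = config or NullConfig()
    return derive_thresholds(sample_pair_null(expr, config, rng=rng), config,
                             strict=strict)


def classify_correlation(r, thr: NullThresholds):
    """Classify coefficients as negative / nonsignificant / positive.

    Cutoffs are inclusive by default (r <= lower is negative, r >= upper is
    positive); ``thr.strict`` switches to strict inequalities.  NaN values
    classify as nonsignificant with a warning.
    """
    arr = np.asarray(r, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    nan = np.isnan(arr)
    if nan.any():
        warnings.warn(f"{int(nan.sum())} NaN correlation(s) classified as "
                      "nonsignificant", stacklevel=2)
    if np.nanmax(np.abs(arr), initial=0.0) > 1 + 1e-12:
        raise ValueError("correlation outside [-1, 1]")
    out = np.full(arr.shape, NONSIGNIFICANT, dtype=object)
    if thr.strict:
        out[(arr < thr.lower) & ~nan] = NEGATIVE
        out[(arr > thr.upper) & ~nan] = POSITIVE
    else:
        out[(arr <= thr.lower) & ~nan] = NEGATIVE
        out[(arr >= thr.upper) & ~nan] = POSITIVE
    return out[0] if scalar else out
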
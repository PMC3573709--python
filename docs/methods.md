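# Methods

## Analysis model

The package treats co-expression screening as a fixed sequence of decisions
applied to a genes × samples log2 expression matrix with a binary sample
grouping (tumor/normal by default):

1. **Quantile normalization** across all samples jointly. Every column is
   mapped onto the reference distribution formed by the per-rank mean
   (optionally median) of the column-sorted values. Ties within a column
   receive the mean of the reference values across the tied rank span, so
   tied inputs remain tied and within-column rank order is preserved exactly.
   With the span-averaging tie rule, exact idempotence holds only for
   tie-free matrices: re-normalizing a matrix with ties perturbs the
   reference by the tie averages. We normalize jointly over all arrays (not
   per group) because a single dataset-wide normalization is the standard
   workflow for one-batch array studies.
2. **Empirical correlation null.** Pearson coefficients of 100,000 uniformly
   drawn pairs of distinct rows of the group-restricted matrix; self-pairs
   and pairs touching constant rows are redrawn (counted and logged).
   Thresholds are the 2.5th/97.5th percentiles under the linear-interpolation
   convention. Boundary values classify as significant (inclusive ≤/≥); a
   strict mode exists. The null is computed on the tumor columns by default —
   the same group the downstream screens use — because a null from the group
   under test is the conservative, self-consistent choice; callers can pass
   any group or the whole matrix.
3. **Anchor screens and counting.** Correlations are computed from
   row-standardized matrices (centered, unit norm), so r is a dot product;
   this agrees with the textbook formula to 1e-12 and is exercised against
   a direct-formula oracle in the tests. Anchors never count themselves.
   A gene enters the "associated set" when significant with ≥ 3 of the 7
   anchors (both the anchor list and the minimum are configurable).
4. **Count threshold and cascade.** The stage-2 cutoff is
   ceil(P97.5 of {per-gene count of positive associations with the associated
   set, over all genes in the matrix}), capped at the maximum observed count.
   Ceiling is used because a count threshold must be attainable; floor and
   round are available. Stage 1 = genes positively significant with ≥ 1
   transcription-factor subunit (self excluded); stage 2 = stage-1 genes
   whose count reaches the cutoff. All layers (per-subunit sets, union,
   final set, counts) are returned for reporting.
5. **Over-representation.** Upper-tail hypergeometric survival probability
   of the query/term overlap in the matrix-wide universe, BH-adjusted,
   significant below 0.025. The EASE variant (overlap reduced by one)
   reproduces the more conservative convention of legacy annotation servers;
   term-level agreement with any specific annotation release is out of scope
   because term memberships are version-dependent.
6. **Interaction subnetwork and hubs.** The subnetwork induced by two seed
   sets plus every non-seed node lying on a simple path of length ≤
   `max_path` (default 2, i.e. direct bridges) between a member of one set
   and a member of the other. Paths may pass through other seeds; the literal
   reading is used and verified against exhaustive path enumeration. Primary
   hubs: non-seed nodes with ≥ 3 edges to the target seed set; secondary:
   remaining non-seed nodes with ≥ 2 seed edges and ≥ 2 primary-hub edges.
   These cutoffs codify a verbal convention, so they are parameters, not
   constants. The hub-vs-background expression test is a two-sample t-test
   (pooled variance by default, Welch optional) on per-gene correlations with
   a reference gene; the background deliberately includes the group, matching
   the "group vs all genes" convention.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n_pairs` | 100,000 | resampled pairs in the null; percentile s.e. ≈ 0.001 at this size |
| `lower_pct`, `upper_pct` | 2.5, 97.5 | null tail percentiles defining significance |
| `min_anchor_count` | 3 | anchors needed to enter the associated set |
| `count_percentile` | 97.5 | percentile of matrix-wide counts fixing the cascade cutoff |
| `alpha` | 0.025 | BH-adjusted significance level for enrichment |
| `max_path` | 2 | longest seed-to-seed path contributing intermediates |
| `primary_min` / `secondary_min_*` | 3 / 2,2 | hub degree rules |

## Synthetic data generator

The generator emulates the statistical architecture the pipeline is designed
to detect, at study scale: 58 tumor and 49 normal samples, 2,000 genes. Three
standard-normal latent factors are drawn per sample — *growth*, *mevalonate*
(the proliferation/metabolic program) and *nfy* (transcription-factor
activity). *growth* and *mevalonate* are correlated ρ_tumor = −0.6 in tumor
columns and ρ_normal = 0 in normal columns; *nfy* is independent. A gene is
baseline (7.0) + Σ loading×factor + N(0, 0.6²) noise; genes outside all
modules are pure noise. Default modules and loadings:

| module | size | loadings |
|---|---|---|
| growth_receptor (EGFR, MET, …) | 10 | growth 1.4 |
| adhesion | 20 | growth 0.8 |
| mevalonate (the 7 anchors) | 7 | mevalonate 1.0 |
| cell_cycle | 60 | mevalonate 0.25 |
| nfy_subunits (NFYA/B/C) | 3 | nfy 1.0 |
| nfy_targets | 40 | nfy 1.0, mevalonate 1.0 |

A two-factor model cannot express this design: if the subunits and the
cell-cycle module load the same factor, the cascade's count threshold — the
51st-highest of 2,000 counts at the 97.5th percentile — cannot sit both
above the subunits' counts and below the targets' counts, because the two
tiers collide. The third factor separates the NF-Y axis: subunits stay out of
the anchor-associated set (their counts are pinned near
P(detect) × |targets| ≈ 40), targets gain counts from both axes (≈ 85), and
the cell-cycle tier (≈ 30–45) anchors the threshold between them. Loadings
were fixed by a simulation-based power analysis of exactly these margins
before the recovery tests were frozen; the binding constraints are (a) the
threshold must clear the subunit tier, whose height is forced by the
requirement that targets be captured in stage 1, and (b) cell-cycle/target
coupling through the shared mevalonate factor makes those tiers co-move with
the realized factor variance, so the cell-cycle loading is kept low. The
growth-receptor loading (1.4) sharpens the tumor-specific anti-correlation
screen, whose per-replicate variability is dominated by the sampling spread
of the realized factor correlation (s.d. ≈ (1−ρ²)/√n ≈ 0.08 at n = 58) — an
irreducible property of the study's sample size, which is why module-level
detection is asserted on a 30-gene module rather than the 7 anchors.

The generator also writes GMT annotations (one term per planted module plus
decoy terms drawn from non-module genes, disjoint from modules by
construction) and a planted interaction network: primary hubs wired to ≥ 3
target genes and one subunit (so they lie on length-2 paths between the seed
sets and are recoverable at the default `max_path`), secondary hubs wired to
2 targets, 2 primary hubs and one subunit, plain intermediates bridging one
subunit and one target, plus Erdős–Rényi background edges (default density
0.002). Everything is byte-deterministic under a fixed seed.

**What the generator does not emulate** — probe-level noise models,
batch/array effects, non-Gaussian expression marginals, realistic annotation
term sizes, heavy-tailed count distributions over the associated set, and
correlated gene-gene structure beyond three factors. Passing recovery tests
therefore demonstrates that the pipeline's inference chain is correct under
its own statistical assumptions, not that those assumptions hold for any
particular real cohort; on real arrays the thresholds and set sizes are
dataset properties.

## Numerical choices and degenerate inputs

* Constant rows: detected by exact zero range (centering alone leaves ~1e-16
  residuals); they yield NaN correlations with a warning, are excluded from
  the pair null by redrawing, and classify as nonsignificant.
* Percentiles use numpy's linear-interpolation convention throughout.
* A degenerate null (constant resample vector) raises rather than emitting
  lower = upper thresholds.
* An empty anchor-associated set short-circuits the cascade with a zero
  count threshold instead of failing the fit.
* Probe→symbol collapse keeps the probe with the highest mean expression
  across all samples (`max_mean`), the common convention for 3'-array data;
  a value-preserving probe-level mode is kept for threshold-sensitive
  reproduction work. Rows with missing values are dropped, with a logged
  count, not imputed.
* Sample-group labels in Series Matrix files are extracted from the first
  characteristics line matching configurable tumor/normal regexes, because
  label encodings vary between depositions; a sidecar TSV always wins.

## Problem sizes in the test suite

The acceptance tests run the calibration check at the full published scale
(2,000 genes × 58 samples, 100,000 pairs), exhaustive hypergeometric
enumeration to N = 12, graph oracles on 100 random 60-node graphs, and 100
fresh study-scale replicates for parameter recovery; the whole suite
completes in well under a minute on one CPU. Recovery criteria are asserted
as means over the replicate stream.

## Known limitations

* The per-gene count distribution in stage 2 is treated as exchangeable when
  taking its percentile; on strongly structured real data the threshold is a
  mixture quantile and can land inside a correlated block of genes, making
  the final set sensitive to the realized correlation strength — visible in
  the generator's power analysis and presumably in any real cohort.
* The empirical null conflates "random gene pair" with "null gene pair";
  structured pairs fatten the tails slightly, so thresholds on real data are
  wider than the iid closed form.
* The subnetwork rule is path-based, not flow- or confidence-based; edge
  provenance and weights are ignored.
* Enrichment assumes the matrix universe is the correct background, which is
  right for arrays but conservative for pre-filtered matrices.
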
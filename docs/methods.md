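# Methods

## Data model

A replicate series is a `StageMatrix`: genes × ordered stages (days 2, 4, 6,
8, 10, 12, 14), with per-gene transcript lengths and, for raw counts, the
per-stage totals of mapped reads. RPKM is computed from the supplied mapped
totals, not from column sums, because mapped totals come from genome-wide
alignment and differ from the sum over annotated genes; a column-sum fallback
(`column_sum_totals`) exists for inputs without totals.

## Trimming

A gene is kept when (1) its day-14 RPKM is ≥ `day14_min` (inclusive; default
0.2) and (2) its RPKM summed over all stages is > `sum_min` (strict; default
0.2). By default criterion (1) is evaluated on replicate A and criterion (2)
on replicate B — the cross-comparison design under which both replicate
datasets share one trimmed gene universe. Either criterion can be pointed at
`"A"`, `"B"` or `"both"`; which replicate carries criterion (1) is genuinely
ambiguous in the source design, so it is a configuration choice, not an
inference.

## Normalization for clustering

Profiles are transformed as `x = log2(RPKM + 1)` and then centered by the
gene's mean over stages, so each row has mean 0 and clustering sees only
temporal shape, not expression level. "Normalize to the stage average" could
also be read as division in linear space before the log transform; that
variant is available (`mode="divide_linear_mean"`) but is not the default,
because subtraction after the log transform keeps the transform order
(log first, then normalization) explicit and makes the row-mean-zero contract
exactly testable. The stage dendrogram is computed on the *uncentered*
`log2(RPKM + 1)` columns (Euclidean distance, complete linkage; both
configurable), matching the usual convention for sample-level heatmaps.

## K-means

Lloyd's algorithm with uniform-random point initialization, `n_starts = 30`
restarts drawn from a single seeded RNG stream, `max_iter = 30000`; the
restart with the smallest within-cluster sum of squares wins, so the result
is deterministic given the seed and can only improve as `n_starts` grows.
Empty clusters are re-seeded with the point farthest from its current center,
keeping exactly K clusters. K = 4 is fixed by interpretability (the four
temporal archetypes), not selected by a criterion. On instances small enough
to enumerate every assignment (≤ 8 genes, K ≤ 3), the restarted search
attains the exhaustive within-SS minimum; tests enforce this.

Clusters are named by maximum-correlation bipartite matching between centroid
profiles and the archetype templates (optimal assignment, each name used
once). Flat profiles have undefined Pearson correlation, so degenerate pairs
fall back to a distance-based similarity `1/(1 + ‖c − t‖)`, which correctly
matches a flat centroid to the flat template.

## Cross-replicate consensus

K-means indices are arbitrary, so clusters are aligned before intersecting:
by archetype-label identity when both models are labelled (disagreements with
the distance-optimal assignment are logged), otherwise by the
minimum-total-distance bijection between centroid sets
(`scipy.optimize.linear_sum_assignment`). Consensus set c is the intersection
of A's cluster c with its matched B cluster; the "combined up" set intersects
the unions of the two rising clusters (late rise ∪ early rise) across
replicates. Genes trimmed from either replicate never enter any intersection.

## Differential expression

Counts (never RPKM — the NB model is defined for counts, and the API refuses
RPKM input) are modelled per gene with a log-link negative-binomial GLM,
variance `μ + φμ²`, over the 14 observations (7 stages × 2 replicates), with
log mapped totals as offsets; gene length is constant within a gene and is
absorbed by the intercept. Full model `~ stage + replicate` (8 parameters),
reduced `~ replicate` (2); the LRT statistic `2(ℓ_full − ℓ_reduced)`, clipped
at 0, is referred to χ² with 6 degrees of freedom.

Fitting is iteratively reweighted least squares, vectorized across genes
(all genes share the design, so one IRLS step is a batch of 8×8 weighted
least-squares solves). Convergence: relative deviance change < 1e-8, at most
100 iterations; non-converged genes are excluded from testing (p set to NaN)
and counted, never silently dropped. φ = 0 degrades exactly to Poisson. The
reported log-likelihood is the exact NB/Poisson log pmf at the fitted means
(an identity tested against direct pmf summation and against statsmodels'
GLM).

**Dispersion.** For candidate φ the gene's coefficients are re-fitted and the
Cox–Reid adjusted profile log-likelihood `APL(φ) = ℓ(β̂(φ); φ) − ½ log det
(XᵀWX)` is evaluated; the CR term compensates for the 8 estimated mean
parameters, without which φ would be biased low and the LRT anti-conservative.
Modes:

* `genewise` — per-gene APL maximum (vectorized golden-section search on
  log φ over [1e-6, 10]; boundary solutions snap to 0). Unmoderated genewise
  values are noisy at 6 residual df and make the LRT anti-conservative; this
  mode exists mainly for diagnostics.
* `common` — one value maximizing the average APL over genes (Brent).
* `shrunk` (default) — per-gene maximum of `APL_g(φ) + w · meanAPL(φ)`,
  where meanAPL is the common curve (interpolated from a 43-point log grid)
  and `w` (`prior_weight`, default 10, in units of genes) sets the shrinkage
  strength. This is a weighted-likelihood moderation in the edgeR spirit; at
  the default weight the null rejection rate of the LRT at α = 0.05 sits at
  ≈ 0.05 (tests require [0.03, 0.07] over 2,000 null genes with φ = 0.1).

All-zero genes get φ = 0 with a flag. A design with no residual degrees of
freedom (one observation per condition) raises an error rather than returning
a silent 0. FDR control is Benjamini–Hochberg; the significance default is
FDR ≤ 0.05.

## Enrichment

For query size n, category size K and background size N, the p-value is the
classical one-sided hypergeometric tail `P(X ≥ k)` (scipy's stable survival
function). DAVID's EASE variant (tail at k − 1) is available via
`ease=True` but is not the default — the classical tail is exactly specified
and oracle-testable by enumeration. The `benjamini` column is BH over exactly
the terms passing `min_category` (default 2), mirroring chart conventions;
records are sorted by p with a term-name tiebreak. The background defaults to
whatever universe the collection carries and is restricted to the trimmed
gene universe inside the pipeline.

## Synthetic data generator

The generator defines the study-like conditions under which everything is
tested:

* **Archetypes and proportions.** Four log2 templates over days 2–14 in
  fractions 0.040 / 0.141 / 0.684 / 0.135 (late rise / early rise / flat /
  early drop — the relative sizes of the four observed clusters,
  559/1,998/9,658/1,909 of 14,124). Default templates: late rise
  (0,0,0,0,2.7,2.85,3.0) — an 8-fold span concentrated after day 8, as
  receptor genes rising from near-undetectable levels do; early rise
  (0,0.4,0.75,1.15,1.4,1.7,2.0) — a 4-fold span with most of the rise before
  day 8; flat; early drop (0,0,−1.5,…) — a 2.8-fold drop between days 4 and 6
  then a plateau. These magnitudes were chosen together so that the stage
  columns carry the early/late two-branch structure *and* the four shapes
  remain separable at the default noise level: a synchronized 4-fold drop in
  13.5% of genes would make days 2–4 vs 6–14 the dominant column split, and a
  drop much under 2-fold is not separable from flat at dispersion 0.05.
* **Counts.** `μ_gj = e_gj · length_g · total_j / 10⁹` with
  `e_gj = base_mean · 2^(template + replicate offset)`, so a gene's expected
  RPKM equals `e_gj` by construction. Draws are negative binomial with
  variance `μ + φμ²` (Poisson at φ = 0). Defaults: `base_mean` 20 RPKM,
  φ = 0.05, lengths uniform on 500–5,000 bp, mapped totals 10⁷ per stage
  (sequencing depth is unstated in the source design; 10⁷ mapped reads per
  library is a typical bulk depth).
* **Replicates.** A per-gene, per-replicate Gaussian offset in log2 space
  (SD 0.1) — the simplest structure making the replicate covariate in the
  GLM non-trivial.
* **Planted category.** 40 genes sampled without replacement with odds 50:1
  in favour of late-rise genes, plus 20 random decoy categories (20–100
  genes), so enrichment ranking has something to beat.

What the generator does *not* emulate: cell-type mixtures, library-prep or
amplification biases, gene–gene correlation, transcript-level structure, or
any sequence content. Passing tests therefore demonstrate that the pipeline's
statistics behave correctly under the stated noise model — not that they are
robust to artefacts absent from that model.

## Pipeline and reproducibility

`run_pipeline` executes simulate/load → RPKM → trim → per-replicate K-means
and stage dendrograms → consensus → LRT → enrichment, persisting every
intermediate as TSV/JSON/GMT/Newick. One root seed expands to per-stage seeds
via `derive_seed(root, stage_name)` = first 8 hex digits of
SHA-256(`"<root>:<stage>"`) mod 2³¹. The manifest records the config hash,
derived seeds, and the gene-count funnel; identical configs produce
byte-identical manifests (no timestamps are written).

## Problem sizes and numerical choices

Tests and the acceptance script use 2,000-gene series for clustering and
calibration studies, 5,000 for dispersion recovery and FDR measurement, and
exhaustive oracles up to 8 genes (K-means) / N = 30 (hypergeometric) — sizes
at which every check completes in seconds while Monte-Carlo error stays well
inside the asserted bands. IRLS means are floored at 1e-10 and linear
predictors clipped at ±40 to keep exp/log finite; dispersions below 1e-10 are
treated as exactly Poisson.

## Known limitations

* The LRT relies on χ² asymptotics at 14 observations; p-values are
  approximately, not exactly, uniform under the null (KS-checked at moderate
  counts).
* No quasi-likelihood F-tests, no empirical-Bayes moderation beyond the
  single shrinkage weight, and no pairwise stage contrasts — only the
  across-days ANOVA-like test.
* Hypergeometric enrichment assumes gene-level independence; no GO-graph
  propagation or term clustering.
* Consensus is limited to two replicates.
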
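# Methods

This note documents the statistical procedures implemented in `sctme`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Normalization and embedding

Counts are library-size normalized: `value(g,c) = log1p(count(g,c) /
total(c) × s)` with scale factor `s = 10,000` (`norm.scale_factor`). This
replaces regularized-NB variance stabilization deliberately: every
downstream statistic in the pipeline is rank-based (Wilcoxon), mean-based
(cluster means, module scores, communication scores) or count-based
(proportions), so the flavor of variance stabilization does not enter the
results, and log normalization keeps the pipeline exactly reproducible and
depth-invariant (a property the tests assert exactly).

Highly variable genes are ranked by dispersion (variance/mean of the
normalized values) z-scored within 20 equal-frequency mean bins; genes
whose variance is zero up to floating-point rounding are never selected
while any variable gene remains. PCA (deterministic full-SVD solver) is
computed on the centered, unit-scaled HVG submatrix with a fixed sign
convention (largest-magnitude loading positive) so reruns are
bit-identical. The default 60 components serve both graph construction
(first 50) and silhouette scoring (first 60) from a single embedding.

The SNN graph uses k = 20 Euclidean nearest neighbors on the first 50 PCs
(neighbor sets include the cell itself), Jaccard edge weights, and a prune
threshold of 1/15 — the de facto community defaults, exposed as
`graph.*` config keys.

## Clustering and resolution selection

Leiden with the resolution-parameterized RB-modularity objective is run at
resolutions 0.2–2.0 in steps of 0.1; each partition is scored by the mean
silhouette width (Euclidean, first 60 PCs; single-cluster partitions score
−1, all-identical geometries 0). The selected resolution is the strict
silhouette argmax with ties broken toward the lower resolution
(parsimony). The full sweep table is always written so a human can
override the choice via config. Cluster labels are relabeled 0..k−1 by
decreasing size for determinism.

Cluster stability across the sweep is summarized by membership flow: for
consecutive resolutions, each cluster's stability is the largest fraction
of its cells landing in a single cluster of the next partition,
cell-weighted-averaged per resolution. This is a decision-support
diagnostic, not part of the resolution choice.

Compartment reassignment takes, per cluster, the plurality sorted
compartment; ties break by the fixed priority immune > stromal > cancer
and are logged. The operation is idempotent.

## Differential abundance

For groups A and B the statistic per cluster is
`log2((p_A + ε_A)/(p_B + ε_B))` with pseudo-proportions
`ε_X = 0.5/n_X` so that empty clusters stay finite while antisymmetry
under group swap is exact. The null is built by permuting group labels
over cells (`n_perm = 1000` by default). Permuting labels and recounting
group A's clusters is *exactly* a multivariate-hypergeometric draw of the
cluster counts, and within-group bootstrap resampling of cells is exactly
multinomial on the counts; both identities are used for vectorization and
are equalities, not approximations. A sample-level permutation mode
(`unit="sample"`) is available for users who prefer sample
exchangeability.

The p-value uses the add-one estimator with mid-p tie handling:
`p = (1 + #{|Λ*| > |Λ|} + ½·#{|Λ*| = |Λ|}) / (n_perm + 1)`. The count
statistic is discrete — in a 2×1000-cell, 5-cluster null, an exact tie
with the observed value occurs in roughly 9% of permutations — so
full-weight tie counting is visibly conservative (measured type-I error
0.041 at α = 0.05, p-value KS distance from uniform 0.070), whereas the
mid-p convention restores calibration (type-I 0.046, KS 0.017). BH
adjustment is applied across clusters; bootstrap percentile CIs (2.5/97.5)
use `n_boot = 1000` by default. Enrichment calls gate on FDR < 0.05 and
the point-estimate |log2FD| against the presets 0.58 (1.5-fold), 1
(2-fold), or 5 (stringent); the bootstrap-mean log2FD is reported
alongside for users who prefer classifying on it.

## Differential expression and signatures

The Wilcoxon rank-sum test runs on normalized values; a gene is tested
only if detected in ≥ `min.pct` (default 0.1) of cells in at least one
group and its |log2FC| clears the threshold (default 0.1). log2FC is
computed on expm1-back-transformed means with a +1 pseudocount — the
convention presupposed by fold-change thresholds like 0.25 in this field.
Exact enumeration is used when n_A + n_B ≤ 20, otherwise a tie-corrected
normal approximation with continuity correction; the two agree within
|Δp| ≤ 0.01 at balanced n = 10+10 without ties (asserted).

The age signature is the directional intersection of two DE runs
(by default: within-target-cluster age comparison × global age
comparison): a gene enters the up (down) set iff it passes adjusted
p < 0.05 and |log2FC| ≥ 0.25 in both runs with the same sign in both. The
operation is symmetric in its inputs and an empty intersection is a
warning, not an error.

Module scores bin all genes into 24 equal-frequency bins by average
expression and, per signature gene, draw 10 control genes without
replacement from its bin (seeded); the score is the per-cell mean of
signature genes minus mean of pooled controls. A constant matrix scores
exactly 0. Note the well-known caveat, which one test works around
explicitly: if the signature genes are the *only* occupants of their
expression bins, they become their own controls and the score deflates.

Over-representation uses the upper-tail hypergeometric against a
configurable universe (default: all tested genes), BH across sets, and an
odds ratio with Haldane +0.5 correction when any 2×2 cell is zero. The
implementation agrees with brute-force enumeration to 1e-12 on universes
up to 30.

Classifier validation mirrors the balanced design used for human-CAF
cohorts: equal subsamples per age group (1,000 cells per group in the
benchmark), a 50/50 train/test split, feature scaling fit on train only,
a 500-tree random forest, held-out sensitivity/specificity, and per-gene
permutation importance. Importance vectors from two models are compared by
top-set overlap at increasing importance thresholds with a two-sided
Fisher exact test.

## Cell–cell communication

Cluster mean expression (normalized values, clusters with > 10 cells
only) feeds two channels per (sender, receiver, ligand, receptor):

- NATMI edge specificity: (ligand's share of sender-summed expression) ×
  (receptor's share of receiver-summed expression); sums to 1 over the
  sender×receiver grid per LR pair.
- SingleCellSignalR LRscore: `√(l·r)/(μ + √(l·r))` with μ the global mean
  of the normalized matrix; bounded in [0,1) and monotone in each mean.

The interaction score is their exact product. The consensus aggregated
rank converts each channel to normalized fractional ranks (lower =
stronger) and takes their geometric mean — a deliberate two-channel
simplification of multi-method rank aggregation that preserves the
"low = consensus-strong" semantics and is exactly testable. Autocrine
pairs are included. Between-group similarity is the Jaccard index of
interaction keys retained at aggregated-rank thresholds 0.05–1.0 (step
0.05), defined as 1 when both sets are empty. Ortholog translation drops
pairs with unmapped members and rejects one-to-many mappings.

## Synthetic data generator

The generator emulates FACS-sorted multi-sample captures: per-gene
baseline means are lognormal (meanlog log 0.3, sdlog 1); counts are
negative-binomial via a gamma–Poisson mixture with shared
inverse-dispersion θ = 2 (var = m + m²/θ); per-cell library factors are
lognormal (sdlog 0.25). Cell types (default three: cancer/immune/stromal,
25 markers each at +3 log2) are drawn per sample from group-specific
proportion vectors; a planted age program (default 40 genes at ±1 log2 in
the CAF type, on a +3 log2 baseline boost — collagens are among the most
abundant fibroblast transcripts) and planted directed ligand–receptor
channels (+3 log2 on ligand in sender, receptor in receiver) provide
ground truth; a configurable fraction of cells receives a wrong sorted
compartment while keeping its true type. All randomness flows from one
seed; equal seeds give byte-identical outputs.

The generator deliberately omits ambient RNA, doublets, batch effects and
cell-cycle structure. Passing benchmarks therefore demonstrate that the
estimators recover effects of the stated sizes under clean multi-sample NB
sampling — not robustness to those artifacts, which real data preparation
must handle upstream.

## Benchmark problem sizes

The planted-recovery benchmarks use: 800 cells / 3 types for clustering
and compartment recovery (10% mis-sorting); 2×1000 cells, 5 clusters,
2,000 replicates for permutation-null calibration; a 0.35 → 0.70 dominant
cluster (log2FD exactly +1, mirroring a dominant matrix-CAF population)
at 1,000 cells/group over 200 replicates for shift recovery — at this
size the sampling SE of log2FD is ≈ 0.07, so the ±0.15 recovery band is a
≈2σ statement; 500 cells/group with 40 planted genes for signature
recall; 1,000 cells/group with 20 planted genes for the classifier; five
types with four planted channels for communication.

## Known limitations

- Silhouette-argmax resolution selection inherits silhouette's bias
  toward compact, balanced clusters; the sweep table is written precisely
  so a human can override.
- Per-cluster (not per-cell) annotation: heterogeneous clusters get one
  label.
- Cell-level permutation treats cells as exchangeable; with strong
  sample-level structure use `unit="sample"`.
- The two-channel aggregated rank is not a full multi-method consensus;
  anyone comparing against a full LIANA-style aggregate should expect
  rank differences away from the extremes.
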
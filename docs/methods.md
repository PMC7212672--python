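# Methods

## The artifact model

The package targets a specific technical confounder of blood-derived
single-cell RNA-seq: time between sample draw and cryopreservation.
Empirically this manifests as (i) a broad, monotone downregulation touching
a large fraction of the transcriptome, (ii) a small up-regulated
cold-shock/stress module, and (iii) a decline in per-cell library size and
detected genes. Cells sampled more than 2 h after draw are treated as the
"affected" (time-biased) class throughout; that threshold is a convention
of the workflow, not a fitted quantity.

## Synthetic data generator

Counts are gamma-Poisson: gene g draws a base mean `m_g ~ Gamma(shape,
scale)` and cell c at time t observes `NB(mu_gc, size=dispersion)` with

    mu_gc = m_g · exp(slope_g · t) · exp(-libsize_decay · t)
            · donor_fx · batch_fx · marker_boost

`slope_g` is `-downreg_rate` for the affected block (default 30% of
genes), `+coldshock_rate` for the cold-shock block (default 10 genes), 0
otherwise. Donor and batch effects are gene-wise log-normal multipliers
(sd 0.1), independent across genes — enough structure for variance
attribution without modelling co-expression. Cell types are planted as
marker blocks (20 genes per type, e^1.5-fold elevation) drawn from the
null block so the time truth stays clean. All draws come from one
`numpy` Generator seeded by the config, so identical configs are
bit-identical.

Defaults follow what the workflow assumes about PBMC-like data: 4 sampling
times (0/2/8/24 h), overdispersed counts (NB size 2), sparse expression
(gamma shape 0.5 · scale 2 ⇒ mean ≈ 1 count). No quantitative decay rate
is established for the real artifact; the default 0.05/h (≈ 70% loss at
24 h on affected genes) is a calibration choice that produces clearly
separable but not degenerate conditions, and tests that depend on effect
size set it explicitly.

The HTO simulator draws a barcode's own hashtag from a foreground NB and
all others from a background NB; doublets draw foreground for two distinct
hashtags, negatives background everywhere.

What the generator does **not** emulate: ambient RNA, gene–gene
correlation beyond the planted blocks, cell-type-specific time responses,
batch effects on the HTO side, or read-level noise. Tests passing on this
generator therefore demonstrate the procedures' correctness and
calibration, not their performance on every pathology of real data.

## Demultiplexing

CLR per hashtag: `ln(x+1)` minus the row mean of `ln(x+1)` (pseudocount 1
so zeros are defined; the geometric mean is computed on pseudocounted
values). Barcodes are clustered with a PAM-style k-medoids (Euclidean
distance on joint CLR profiles, k-means++-style seeded initialization,
medoid update until convergence); k defaults to the number of pooled
conditions. For each hashtag, the background is every barcode outside the
cluster whose medoid is highest for that hashtag; the top 0.5% of
background values are trimmed as outliers.

The calling threshold is the 0.99 quantile of the trimmed background.
Two estimators are provided. The default fits a normal distribution to the
trimmed background and thresholds at `mean + z_0.99 · sd`: doublets that
carry hashtag i but cluster with their other hashtag leak into hashtag i's
background (≈ 1.7% of it at a 5% doublet rate and 4 hashtags), which
exceeds what a 0.5% trim plus a 1% empirical tail can absorb, so the
empirical quantile lands in the doublet tail and misses up to ~10% of true
singlets; a parametric fit is driven by the bulk of the background and is
robust to that contamination (this mirrors the parametric background fit
of the original cell-hashing protocol). The empirical
linear-interpolation sample quantile remains available as
`threshold_method="quantile"`. A barcode exceeding (strictly — ties do
not exceed) thresholds of ≥ 2 hashtags is a multiplet, of none a
negative, otherwise it is assigned its single positive hashtag.
Per-batch/per-donor demultiplexing is the caller's loop.

## QC and normalization

Cell filters are explicit numeric thresholds on total counts, detected
genes and mitochondrial fraction (genes identified by name prefix,
default `MT-`); a cell failing any rule is removed and the report counts
per-rule and unique removals. The full-length `smartseq2` preset is
75,000–1,000,000 counts, ≥ 435 genes, ≤ 20% mito, gene mean ≥ 1. Gene
filters drop genes detected in fewer than a configurable number of cells.

Size factors are relative library sizes scaled to mean 1
(`sf_c = total_c / mean(total)`), with values `ln(1 + x/sf)`. The
pooling-deconvolution estimator used by heavier pipelines is deliberately
not re-implemented: every downstream operation depends only on the
size-factor contract (positive, mean 1). One consequence worth knowing:
for genes with near-zero means, `log1p` cannot equalize count discreteness
across sequencing depths, so rank tests retain a small depth signal in
that regime; at moderate expression the normalization removes the depth
signal completely (verified by a uniformity test in the suite).

## Differential expression and the signature

Each gene is tested with the two-sample Wilcoxon–Mann–Whitney rank-sum
test, biased (t > 2 h) vs unbiased cells: exact null enumeration when
both groups have ≤ 8 tie-free observations, normal approximation with tie
correction otherwise. logFC is the natural log of pseudocounted de-logged
group means — `ln(mean(expm1(x))+1)` per group — matching the common
single-cell convention. Adjustment is Bonferroni by default
(Benjamini–Hochberg selectable). The signature keeps genes with |logFC| ≥
0.25, adjusted p < 0.001 and (optionally) a minimum expression in the
larger group mean.

Set enrichment is the upper-tail hypergeometric test of the 2×2 overlap
table on pre-propagated gene sets, with terms outside [3, 600) genes
excluded and results filtered at p < 0.05 and sample odds ratio > 2
(Haldane 0.5 correction when a margin cell is zero).

## Time score, classification, correction

The module score bins genes into 25 expression bins by row mean
(quantile bins on ranks), draws 100 control genes per signature gene from
the same bin (without replacement when possible; signature genes are
excluded from control pools) and reports mean signature minus mean pooled
control expression per cell. The classifier is an unregularized logistic
fit of the affected flag on the score; perfect separation yields capped
coefficients (|slope| bounded at 50/sd) plus a warning rather than a
failure. AUC is rank-based (U/(n₊n₋), ties half) and therefore identical
on scores and predicted probabilities.

Correction: within each cell type, each gene is regressed on the score
(OLS) and the score-explained component `slope · (score - mean)` is
subtracted; the group mean is left in place, and the reassembled matrix is
centered and scaled to unit variance per gene (variance at rounding-noise
scale maps to zeros). Removing only the within-type score component is
what lets the correction collapse the affected/unaffected separation while
preserving between-type structure; re-centering residuals within each type
separately would zero out cell-identity differences along with the
artifact. Fitting per cell type avoids the Simpson's-paradox failure mode
where a pooled slope mixes between-type and within-type relations.

The bootstrap silhouette procedure resamples 300 cells with replacement at
each affected fraction from 10% to 90% (step 10), embeds them in 10
principal components, and records the average silhouette width of the
affected/unaffected split before and after correcting the resample
(25 replicates per fraction; 225 rows).

## Mixing and variance attribution

kBET samples test cells and compares the batch-label counts among each
cell's k nearest Euclidean neighbors (cell included) against k times the
global frequencies with a Pearson χ² test, (L−1) df, asymptotic p, no
continuity correction; acceptance rate is the percentage of tested cells
with p > 0.05. The default k is max(10, ⌊0.25 · mean batch size⌋). The
pipeline evaluates kBET in 10-PC PCA space: deterministic, at the cost of
diverging from manifold embeddings some workflows use.

ρ_p(x, y) = 2·cov(x, y)/(var x + var y) on log-scale normalized
expression, population (1/n) moments; constant cells are reported as
missing rather than 0. Per-gene r² on a categorical covariate is the
one-way-ANOVA η² (between-group SS over total SS), and the PC-level
summary is Σ var(PC_i)·r²(PC_i ~ covariate)/Σ var(PC_i) over the top PCs —
a reconstruction whose outputs are not comparable to published
percentages computed by other means.

## Numerical and design notes

- One global seed per run; stages derive fixed offsets so any stage is
  reproducible in isolation. All randomness flows through
  `numpy.random.default_rng`.
- Quantiles are linear-interpolation sample quantiles; "exceeds" is
  strict everywhere a threshold is compared.
- k-medoids is O(n²) in barcodes (distance matrix held in memory); fine
  for per-batch demultiplexing scales (thousands of barcodes), not for
  hundreds of thousands.
- The run config is a flat YAML validated by field-name checking; stage
  artifacts are MTX-triplet + CSV so external tools can replace any stage.
- Problem sizes in the test suite and acceptance script (≈ 2,000 genes ×
  1,000 cells for effect-recovery runs, 2,000 barcodes for hashing,
  20 × 300-gene null replicates) are chosen so the full battery completes
  in minutes while keeping every statistic far from its small-sample
  regime.

## Known limitations

- The simulator's independence assumptions (genes, donors, batches) make
  variance attribution cleaner than in real data.
- The empirical-quantile threshold mode degrades when doublet rates are
  high relative to the trim fraction (see Demultiplexing).
- The logistic separation cap is a pragmatic device; confidence intervals
  for capped fits are not meaningful.
- Correction assumes the score captures the artifact linearly per gene
  within a cell type; strongly nonlinear responses would leave residual
  structure.
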
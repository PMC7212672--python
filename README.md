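# timedrift

Detection, quantification and correction of **sampling-time artifacts** in
single-cell RNA-seq.

When blood samples sit at ambient temperature between draw and
cryopreservation, cells accumulate a technical expression signature: a broad
downregulation of the transcriptome, an up-regulated cold-shock module
(*CIRBP*/*RBM3*-like), and decaying per-cell library size. Cells processed
more than ~2 h after extraction ("time-biased") separate from promptly
processed cells in embeddings and confound downstream comparisons — a
serious problem for retrospective cohorts and biobank material where
processing delay varies by sample. `timedrift` is aimed at analysts of such
cohorts: it provides the full workflow to simulate, detect, score and
regress out this artifact, and to verify that the correction improved
mixing without erasing cell-identity structure.

## What it does

- **`timedrift.sim`** — a gamma-Poisson (negative binomial) count simulator
  with planted time effects and full ground truth: affected genes' means
  decay as `exp(-r·t)`, a small cold-shock module grows as `exp(+r·t)`,
  library size decays with `t`, plus cell types with marker genes and
  multiplicative donor/batch effects. A matched hashtag-oligo (HTO)
  simulator produces singlets, doublets and negatives.
- **`timedrift.demux`** — cell-hashing demultiplexing: centered-log-ratio
  (CLR) normalization per hashtag, PAM-style k-medoids clustering of
  barcodes (k = number of pooled conditions), per-hashtag background
  distributions with 0.5% outlier trimming, 0.99-quantile thresholds, and
  singlet / multiplet / negative calls.
- **`timedrift.qc`** — explicit-threshold cell filters (library size,
  detected genes, mitochondrial fraction; a full-length `smartseq2` preset
  ships: 75,000–1,000,000 counts, ≥ 435 genes, ≤ 20% mito), gene detection
  filters, and relative-library-size factors (mean 1) with `ln(1 + x/sf)`
  normalization.
- **`timedrift.dea`** — per-gene Wilcoxon–Mann–Whitney rank-sum DEA between
  time-biased (t > 2 h) and unbiased cells; the sampling-time signature is
  the filtered table (|logFC| ≥ 0.25, adjusted p < 0.001); hypergeometric
  gene-set over-representation (term size in [3, 600), p < 0.05, odds
  ratio > 2) and cross-signature overlap with top-N harmonization.
- **`timedrift.score`** — per-cell time score (mean signature expression
  minus expression-matched control genes, 25 bins × 100 controls),
  logistic classification of biased cells with rank-based AUC, per-cell-type
  regression of each gene on the score (scaled/centered residuals), and a
  bootstrap silhouette procedure (300 cells × 25 reps across 10–90%
  affected fractions) quantifying correction robustness.
- **`timedrift.mixing`** — the kBET mixing statistic (χ² test of local vs
  global batch composition; acceptance rate = % tested cells with p > 0.05),
  the proportionality similarity ρ_p = 2·cov/(var+var) between cells,
  balanced downsampling, per-gene r² variance attribution (one-way ANOVA
  η²), and a PC-weighted variance fraction.
- **`timedrift.pipeline` / CLI** — `timedrift run --config run.yaml` (or
  per-stage subcommands `simulate`, `demux`, `qc`, `dea`, `signature`,
  `score`, `correct`, `kbet`, `varexp`) orchestrating the stages with one
  global seed and MTX-triplet + CSV artifacts at every step.

## Worked example

```python
import timedrift as td

cfg = td.SimConfig(
    n_genes=2000, n_cells_per_condition=500, conditions=(0.0, 24.0),
    downreg_fraction=0.3, downreg_rate=0.05, n_donors=2, seed=11,
)
counts, truth = td.simulate_counts(cfg)
norm = td.size_factor_normalize(counts)
train = norm.subset_cells((norm.cell_meta["donor"] == "donor_0").values)
test = norm.subset_cells((norm.cell_meta["donor"] == "donor_1").values)

dea = td.wilcoxon_dea(train, train.cell_meta["affected"].values)
sig = td.define_signature(dea)
print(f"signature: {len(sig)} genes ...")

s_train = td.module_score(train, sig.index, seed=3)
model = td.fit_classifier(s_train, train.cell_meta["affected"].values)
s_test = td.module_score(test, sig.index, seed=3)
auc, _ = td.predict_auc(model, s_test, test.cell_meta["affected"].values)

corr = td.regress_out_score(test, s_test.values,
                            test.cell_meta["cell_type"].values)
```

Output:

```
signature: 251 genes (4 up, 247 down)
cross-donor test AUC: 1.000
kBET acceptance across sampling times: 0.0% -> 83.8%
```

Meaning: on data with 30% of genes decaying at 0.05/h over 24 h, the
rank-sum DEA on one donor recovers a 251-gene signature dominated by
downregulation; the module score trained on that donor classifies the
other donor's biased cells perfectly; before correction the two sampling
times are completely unmixed in PCA space (kBET acceptance 0%), and
regressing the score out per cell type restores mixing (83.8%) while
cell-type silhouette changes by only a few percent.

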
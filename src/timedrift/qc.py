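"""Quality control and normalization.

Damaged cells are removed by explicit thresholds on library size, library
complexity (detected genes) and mitochondrial fraction; low-coverage genes
by a minimum detection count. Normalization uses relative-library-size
factors scaled to mean 1 and a ``ln(1 + x / sf)`` transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from timedrift.containers import (
    ConfigError,
    CountMatrix,
    EmptyResultError,
    NormalizedMatrix,
)


@dataclass(frozen=True)
class QcThresholds:
    """Numeric cell- and gene-level QC cut-offs.

    ``min_gene_mean`` only applies in full-length presets where genes are
    additionally required to exceed an average expression.
    """

    min_counts: float = 0.0
    max_counts: float = np.inf
    min_genes: int = 0
    max_mito: float = 1.0
    min_cells_per_gene: int = 0
    min_gene_mean: float = 0.0

    def __post_init__(self) -> None:
        if not self.min_counts < self.max_counts:
            raise ConfigError("min_counts must be < max_counts")
        if not 0 <= self.max_mito <= 1:
            raise ConfigError("max_mito must lie in [0, 1]")


# Full-length (plate-based) preset: cells with < 75,000 or > 1,000,000 total
# counts, < 435 detected genes or > 20% mitochondrial reads are discarded;
# genes with average expression < 1 are dropped.
SMARTSEQ2_PRESET = QcThresholds(
    min_counts=75_000,
    max_counts=1_000_000,
    min_genes=435,
    max_mito=0.20,
    min_gene_mean=1.0,
)

DROPLET_PRESET = QcThresholds(
    min_counts=500,
    max_counts=50_000,
    min_genes=200,
    max_mito=0.20,
    min_cells_per_gene=10,
)

PRESETS = {"smartseq2": SMARTSEQ2_PRESET, "droplet": DROPLET_PRESET}


def mito_mask_from_names(gene_names, prefix: str = "MT-") -> np.ndarray:
    """Boolean mask of mitochondrial genes identified by a name prefix."""
    return np.asarray([str(g).upper().startswith(prefix.upper())
                       for g in gene_names])


def filter_cells(
    m: CountMatrix,
    t: QcThresholds,
    mito_gene_mask: Optional[np.ndarray] = None,
) -> tuple[CountMatrix, dict]:
    """Remove cells failing any QC rule; report removals per rule.

    A cell may fail several rules; the report holds both per-rule counts and
    the number of unique cells removed.
    """
    if mito_gene_mask is None:
        mito_gene_mask = np.zeros(m.n_genes, dtype=bool)
    mito_gene_mask = np.asarray(mito_gene_mask, dtype=bool)
    if mito_gene_mask.shape != (m.n_genes,):
        raise ConfigError("mito mask not aligned to the gene index")

    totals = m.cell_totals()
    n_genes_det = m.genes_detected_per_cell()
    mito_counts = np.asarray(m.counts[mito_gene_mask].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 1.0)

    fails = {
        "low_counts": totals < t.min_counts,
        "high_counts": totals > t.max_counts,
        "low_genes": n_genes_det < t.min_genes,
        "high_mito": mito_frac > t.max_mito,
    }
    any_fail = np.logical_or.reduce(list(fails.values()))
    if any_fail.all():
        raise EmptyResultError("QC thresholds removed every cell")

    report = {
        "thresholds": {
            "min_counts": float(t.min_counts),
            "max_counts": float(t.max_counts),
            "min_genes": int(t.min_genes),
            "max_mito": float(t.max_mito),
        },
        "n_cells_in": int(m.n_cells),
        "removed_per_rule": {k: int(v.sum()) for k, v in fails.items()},
        "removed_unique": int(any_fail.sum()),
        "n_cells_out": int((~any_fail).sum()),
    }
    return m.subset_cells(~any_fail), report


def filter_genes(m: CountMatrix, min_cells_per_gene: int) -> CountMatrix:
    """Drop genes detected (count > 0) in fewer than ``min_cells_per_gene``
    cells."""
    if min_cells_per_gene < 0:
        raise ConfigError("min_cells_per_gene must be >= 0")
    if min_cells_per_gene == 0:
        return m
    keep = m.cells_detected_per_gene() >= min_cells_per_gene
    if not keep.any():
        raise EmptyResultError("gene filter removed every gene")
    return m.subset_genes(keep)


def filter_genes_by_mean(m: CountMatrix, min_gene_mean: float) -> CountMatrix:
    """Drop genes whose average count across cells is below ``min_gene_mean``
    (full-length preset rule)."""
    if min_gene_mean <= 0:
        return m
    means = np.asarray(m.counts.mean(axis=1)).ravel()
    keep = means >= min_gene_mean
    if not keep.any():
        raise EmptyResultError("gene-mean filter removed every gene")
    return m.subset_genes(keep)


def size_factor_normalize(m: CountMatrix) -> NormalizedMatrix:
    """Relative-library-size factors, mean 1: ``sf_c = total_c / mean(total)``;
    values are ``ln(1 + x / sf)``."""
    totals = m.cell_totals().astype(float)
    if (totals <= 0).any():
        raise ConfigError(
            "cells with zero total count present; run QC filtering first"
        )
    sf = totals / totals.mean()
    dense = m.counts.toarray().astype(float)
    values = np.log1p(dense / sf[None, :])
    return NormalizedMatrix(values, m.gene_names, m.cell_meta, sf)
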
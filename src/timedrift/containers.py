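"""In-memory containers shared across the pipeline.

The orientation convention is genes x cells throughout (CellRanger triplet
layout); cell metadata rides along as a DataFrame indexed like the columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


class TimedriftError(Exception):
    """Base class for pipeline errors."""


class ConfigError(TimedriftError, ValueError):
    """Invalid configuration or parameters."""


class EmptyResultError(TimedriftError, ValueError):
    """A filter or threshold removed everything."""


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI counts with per-cell metadata.

    Attributes
    ----------
    counts
        ``scipy.sparse`` matrix of nonnegative integers, shape
        ``(n_genes, n_cells)``.
    gene_names
        Unique gene identifiers, length ``n_genes``.
    cell_meta
        Per-cell metadata; the index holds the barcodes. Standard columns
        written by the simulator: ``time_h``, ``donor``, ``batch``,
        ``temperature``, ``cell_type``, ``affected``.
    """

    counts: sp.spmatrix
    gene_names: pd.Index
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_names = pd.Index(self.gene_names)
        if self.counts.shape != (len(self.gene_names), len(self.cell_meta)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_names)} genes x {len(self.cell_meta)} cells"
            )
        if not self.gene_names.is_unique:
            raise ValueError("duplicate gene names")
        if not self.cell_meta.index.is_unique:
            raise ValueError("duplicate barcodes")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def barcodes(self) -> pd.Index:
        return self.cell_meta.index

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_detected_per_cell(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def cells_detected_per_gene(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.counts[:, idx], self.gene_names, self.cell_meta.iloc[idx]
        )

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(self.counts[idx, :], self.gene_names[idx], self.cell_meta)


@dataclass
class HtoMatrix:
    """Hashtag-oligo counts: hashtags x barcodes, nonnegative integers."""

    counts: np.ndarray
    hto_names: pd.Index
    barcode_ids: pd.Index

    def __post_init__(self) -> None:
        self.counts = np.asarray(
            self.counts.toarray() if sp.issparse(self.counts) else self.counts
        )
        self.hto_names = pd.Index(self.hto_names)
        self.barcode_ids = pd.Index(self.barcode_ids)
        if self.counts.shape != (len(self.hto_names), len(self.barcode_ids)):
            raise ValueError("counts shape does not match labels")
        if not self.hto_names.is_unique:
            raise ValueError("duplicate hashtag names")
        if not self.barcode_ids.is_unique:
            raise ValueError("duplicate barcode ids")
        if not np.isfinite(self.counts).all():
            raise ValueError("non-finite HTO counts")
        if (self.counts < 0).any():
            raise ValueError("negative HTO counts")

    @property
    def n_htos(self) -> int:
        return self.counts.shape[0]

    @property
    def n_barcodes(self) -> int:
        return self.counts.shape[1]


@dataclass
class NormalizedMatrix:
    """Log-normalized expression ``ln(1 + count / size_factor)``.

    ``values`` is dense genes x cells; ``size_factors`` are strictly positive
    per-cell scalars with mean 1.
    """

    values: np.ndarray
    gene_names: pd.Index
    cell_meta: pd.DataFrame
    size_factors: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(
            self.values.toarray() if sp.issparse(self.values) else self.values,
            dtype=float,
        )
        self.gene_names = pd.Index(self.gene_names)
        if self.size_factors is None:
            self.size_factors = np.ones(self.values.shape[1])
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if self.values.shape != (len(self.gene_names), len(self.cell_meta)):
            raise ValueError("values shape does not match labels")
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be strictly positive")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def barcodes(self) -> pd.Index:
        return self.cell_meta.index

    def subset_cells(self, mask_or_idx) -> "NormalizedMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormalizedMatrix(
            self.values[:, idx],
            self.gene_names,
            self.cell_meta.iloc[idx],
            self.size_factors[idx],
        )
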
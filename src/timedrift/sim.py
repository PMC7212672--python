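"""Synthetic single-cell data with a planted sampling-time artifact.

The generator emulates the structure the downstream analysis assumes:

* multimodal cell-type populations distinguished by elevated marker genes;
* a monotone, time-dependent global downregulation hitting a large fraction
  of genes (mean scaled by ``exp(-downreg_rate * t)``);
* a small up-regulated cold-shock module (mean scaled by
  ``exp(+coldshock_rate * t)``);
* time-dependent library-size decay;
* gene-wise multiplicative donor and batch effects (log-normal);
* gamma-Poisson (negative binomial) counting noise.

Every planted effect is returned as ground truth so downstream operations
can be tested against a known answer. Cells at sampling times above 2 h are
flagged ``affected`` — the biased class of the downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from timedrift.containers import ConfigError, CountMatrix, HtoMatrix

AFFECTED_THRESHOLD_H = 2.0


@dataclass
class SimConfig:
    """Parameters of the count simulator.

    Rates are per hour and act multiplicatively on negative-binomial means;
    ``dispersion`` is the NB size parameter (larger = less overdispersed).
    """

    n_genes: int = 2000
    n_cells_per_condition: int = 300
    conditions: tuple[float, ...] = (0.0, 2.0, 8.0, 24.0)
    n_cell_types: int = 3
    n_markers_per_type: int = 20
    marker_logfc: float = 1.5
    downreg_fraction: float = 0.3
    downreg_rate: float = 0.05
    coldshock_genes: int = 10
    coldshock_rate: float = 0.03
    base_mean_shape: float = 0.5
    base_mean_scale: float = 2.0
    dispersion: float = 2.0
    libsize_decay: float = 0.01
    n_donors: int = 2
    n_batches: int = 2
    donor_sd: float = 0.1
    batch_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_cells_per_condition": self.n_cells_per_condition,
            "n_cell_types": self.n_cell_types,
            "n_markers_per_type": self.n_markers_per_type,
            "coldshock_genes": self.coldshock_genes,
            "n_donors": self.n_donors,
            "n_batches": self.n_batches,
        }
        for name, v in counts.items():
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ConfigError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n_genes < 1 or self.n_cells_per_condition < 1:
            raise ConfigError("n_genes and n_cells_per_condition must be >= 1")
        if self.n_cell_types < 1 or self.n_donors < 1 or self.n_batches < 1:
            raise ConfigError("n_cell_types, n_donors, n_batches must be >= 1")
        rates = {
            "downreg_fraction": self.downreg_fraction,
            "downreg_rate": self.downreg_rate,
            "coldshock_rate": self.coldshock_rate,
            "base_mean_shape": self.base_mean_shape,
            "base_mean_scale": self.base_mean_scale,
            "dispersion": self.dispersion,
            "libsize_decay": self.libsize_decay,
            "donor_sd": self.donor_sd,
            "batch_sd": self.batch_sd,
            "marker_logfc": self.marker_logfc,
        }
        for name, v in rates.items():
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be finite and nonnegative, got {v!r}")
        if self.base_mean_shape <= 0 or self.base_mean_scale <= 0:
            raise ConfigError("gamma base-mean parameters must be positive")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if len(self.conditions) < 1:
            raise ConfigError("at least one condition required")
        for t in self.conditions:
            if not np.isfinite(t) or t < 0:
                raise ConfigError(f"condition times must be finite and >= 0, got {t!r}")
        if self.downreg_fraction > 1:
            raise ConfigError("downreg_fraction must be <= 1")
        n_down = int(round(self.downreg_fraction * self.n_genes))
        if n_down + self.coldshock_genes > self.n_genes:
            raise ConfigError(
                "downregulated plus cold-shock genes exceed the gene count"
            )


@dataclass
class SimTruth:
    """Ground truth for a simulation run.

    ``cells`` mirrors the cell metadata (condition, donor, batch, cell type,
    affected flag); ``genes`` records the planted direction and the true
    natural-log fold-change over the full simulated time range. For HTO
    simulations ``barcodes`` records the true identity of every droplet.
    """

    cells: pd.DataFrame = field(default_factory=pd.DataFrame)
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    barcodes: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw a gamma-Poisson count matrix with planted time effects.

    Genes are drawn a base mean from Gamma(shape, scale); affected genes'
    means decay as ``exp(-downreg_rate * t)`` and cold-shock genes grow as
    ``exp(+coldshock_rate * t)``. Marker genes are elevated
    (``exp(marker_logfc)``-fold) in their own cell type. Library-size decay
    multiplies every gene of a cell at time t by ``exp(-libsize_decay * t)``.
    Counts are NB via a gamma-Poisson mixture with size ``dispersion``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    n_cond = len(config.conditions)
    N = config.n_cells_per_condition * n_cond

    base_mean = rng.gamma(config.base_mean_shape, config.base_mean_scale, size=G)
    base_mean = np.maximum(base_mean, 1e-3)

    # planted gene roles: cold-shock genes first, then downregulated block
    n_down = int(round(config.downreg_fraction * G))
    up_idx = np.arange(min(config.coldshock_genes, G))
    down_idx = np.arange(len(up_idx), len(up_idx) + n_down)

    slope = np.zeros(G)
    slope[up_idx] = config.coldshock_rate
    slope[down_idx] = -config.downreg_rate
    # direction reflects the planted effect actually present (zero rate -> null)
    direction = np.where(slope > 0, "up", np.where(slope < 0, "down", "null"))
    direction = direction.astype(object)

    # markers: drawn from the null block so time truth stays clean
    null_idx = np.flatnonzero(direction == "null")
    marker_of_type = {}
    needed = config.n_cell_types * config.n_markers_per_type
    pool = null_idx[:needed] if needed <= len(null_idx) else null_idx
    for ct in range(config.n_cell_types):
        lo = ct * config.n_markers_per_type
        marker_of_type[ct] = pool[lo : lo + config.n_markers_per_type]

    # cell-level assignments
    time_h = np.repeat(np.asarray(config.conditions, dtype=float),
                       config.n_cells_per_condition)
    cell_type = rng.integers(config.n_cell_types, size=N)
    donor = rng.integers(config.n_donors, size=N)
    batch = rng.integers(config.n_batches, size=N)

    donor_fx = np.exp(rng.normal(0.0, config.donor_sd, size=(config.n_donors, G)))
    batch_fx = np.exp(rng.normal(0.0, config.batch_sd, size=(config.n_batches, G)))

    mu = np.empty((G, N))
    time_scale = np.exp(np.outer(slope, time_h))  # G x N
    lib_scale = np.exp(-config.libsize_decay * time_h)  # N
    mu[:] = base_mean[:, None] * time_scale * lib_scale[None, :]
    mu *= donor_fx[donor].T * batch_fx[batch].T
    marker_boost = np.ones((G, N))
    for ct, genes in marker_of_type.items():
        if len(genes):
            marker_boost[np.ix_(genes, np.flatnonzero(cell_type == ct))] = np.exp(
                config.marker_logfc
            )
    mu *= marker_boost

    lam = rng.gamma(config.dispersion, mu / config.dispersion)
    counts = rng.poisson(lam).astype(np.int64)

    t_span = max(config.conditions) - min(config.conditions)
    genes_df = pd.DataFrame(
        {
            "direction": direction,
            "true_logfc_per_h": slope,
            "true_logfc": slope * t_span,
            "marker_of_type": -1,
        },
        index=pd.Index([f"gene_{i:05d}" for i in range(G)], name="gene"),
    )
    for ct, genes in marker_of_type.items():
        genes_df.iloc[genes, genes_df.columns.get_loc("marker_of_type")] = ct

    barcodes = pd.Index([f"cell_{i:05d}" for i in range(N)], name="barcode")
    meta = pd.DataFrame(
        {
            "time_h": time_h,
            "donor": [f"donor_{d}" for d in donor],
            "batch": [f"batch_{b}" for b in batch],
            "temperature": "RT",
            "cell_type": [f"type_{c}" for c in cell_type],
            "affected": time_h > AFFECTED_THRESHOLD_H,
        },
        index=barcodes,
    )
    truth = SimTruth(cells=meta.copy(), genes=genes_df)
    return CountMatrix(counts, genes_df.index, meta), truth


def simulate_hto(
    n_barcodes: int,
    n_htos: int,
    fg_mean: float,
    bg_mean: float,
    dispersion: float = 10.0,
    doublet_rate: float = 0.05,
    negative_rate: float = 0.02,
    seed: int = 0,
) -> tuple[HtoMatrix, SimTruth]:
    """Simulate hashtag counts with singlets, doublets and negatives.

    Singlets draw their own hashtag from a foreground NB (mean ``fg_mean``)
    and every other hashtag from the background NB (mean ``bg_mean``);
    doublets draw foreground for two distinct hashtags; negatives draw
    background everywhere. Truth labels every barcode.
    """
    if n_htos < 2:
        raise ConfigError("n_htos must be >= 2")
    if not (fg_mean > bg_mean >= 0):
        raise ConfigError("require fg_mean > bg_mean >= 0")
    if not (0 <= doublet_rate < 1 and 0 <= negative_rate < 1
            and doublet_rate + negative_rate < 1):
        raise ConfigError("doublet/negative rates must lie in [0, 1) and sum < 1")
    if dispersion <= 0:
        raise ConfigError("dispersion must be positive")

    rng = np.random.default_rng(seed)

    def nb(mean: float, size) -> np.ndarray:
        if mean == 0:
            return np.zeros(size, dtype=np.int64)
        lam = rng.gamma(dispersion, mean / dispersion, size=size)
        return np.asarray(rng.poisson(lam), dtype=np.int64)

    counts = nb(bg_mean, (n_htos, n_barcodes))
    u = rng.random(n_barcodes)
    kind = np.where(
        u < doublet_rate, "doublet",
        np.where(u < doublet_rate + negative_rate, "negative", "singlet"),
    )
    identity = np.full(n_barcodes, "negative", dtype=object)
    for j in range(n_barcodes):
        if kind[j] == "singlet":
            h = rng.integers(n_htos)
            counts[h, j] = nb(fg_mean, ())
            identity[j] = f"hto_{h}"
        elif kind[j] == "doublet":
            h1, h2 = rng.choice(n_htos, size=2, replace=False)
            counts[h1, j] = nb(fg_mean, ())
            counts[h2, j] = nb(fg_mean, ())
            identity[j] = f"hto_{min(h1, h2)}+hto_{max(h1, h2)}"

    bc = pd.Index([f"bc_{i:05d}" for i in range(n_barcodes)], name="barcode")
    truth = SimTruth(
        barcodes=pd.DataFrame({"kind": kind, "identity": identity}, index=bc)
    )
    hto = HtoMatrix(
        counts, pd.Index([f"hto_{i}" for i in range(n_htos)]), bc
    )
    return hto, truth
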
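import numpy as np
import pandas as pd
import pytest

import timedrift as td
from timedrift.containers import NormalizedMatrix


@pytest.fixture(scope="session")
def planted_sim():
    """Two-condition simulation with a strong planted time effect."""
    cfg = td.SimConfig(
        n_genes=800,
        n_cells_per_condition=300,
        conditions=(0.0, 24.0),
        downreg_fraction=0.3,
        downreg_rate=0.05,
        n_donors=2,
        seed=5,
    )
    counts, truth = td.simulate_counts(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def planted_norm(planted_sim):
    _, counts, truth = planted_sim
    return td.size_factor_normalize(counts), truth


@pytest.fixture(scope="session")
def null_sim():
    """Simulation with every effect rate zero: exchangeable conditions."""
    cfg = td.SimConfig(
        n_genes=500,
        n_cells_per_condition=150,
        conditions=(0.0, 24.0),
        downreg_rate=0.0,
        coldshock_rate=0.0,
        libsize_decay=0.0,
        donor_sd=0.0,
        batch_sd=0.0,
        seed=0,
    )
    counts, truth = td.simulate_counts(cfg)
    return cfg, counts, truth


def make_norm(values, gene_names=None, meta=None):
    """Wrap a dense genes x cells array as a NormalizedMatrix."""
    values = np.asarray(values, dtype=float)
    g, c = values.shape
    if gene_names is None:
        gene_names = [f"g{i}" for i in range(g)]
    if meta is None:
        meta = pd.DataFrame(index=pd.Index([f"c{i}" for i in range(c)]))
    return NormalizedMatrix(values, pd.Index(gene_names), meta)
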
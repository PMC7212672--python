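"""Mixing and variance attribution.

kBET compares the batch-label composition of each tested cell's local
k-nearest neighborhood against the global composition with a Pearson chi^2
test; the acceptance rate is the percentage of tested cells whose
neighborhood is statistically indistinguishable from the global mix
(p > 0.05). Variance attribution uses the proportionality similarity rho_p
between cells, per-gene r^2 on categorical covariates (one-way-ANOVA eta^2)
and a PC-weighted variance fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from timedrift.containers import ConfigError, NormalizedMatrix

ALPHA = 0.05


@dataclass
class KbetResult:
    """Per-cell chi^2 statistics and the derived acceptance rate (percent)."""

    stats: pd.DataFrame  # columns: cell_index, chi2, pval
    acceptance_rate: float
    k: int
    n_tested: int

    @property
    def rejection_rate(self) -> float:
        return 100.0 - self.acceptance_rate


def default_k(batch_labels) -> int:
    """Neighborhood-size heuristic: max(10, floor(0.25 * mean batch size))."""
    counts = pd.Series(batch_labels).value_counts()
    return max(10, int(np.floor(0.25 * counts.mean())))


def kbet(
    embedding: np.ndarray,
    batch_labels,
    k: int | None = None,
    n_test: int | None = None,
    seed: int = 0,
) -> KbetResult:
    """k-nearest-neighbor batch-effect test on a cells x d embedding.

    For each of ``n_test`` randomly sampled cells, the label counts among
    its k nearest Euclidean neighbors (the cell included) are compared with
    ``k`` times the global label frequencies by a Pearson chi^2 test with
    (L - 1) degrees of freedom, asymptotic p-values. Acceptance rate =
    percentage of tested cells with p > 0.05.
    """
    X = np.asarray(embedding, dtype=float)
    labels = np.asarray(batch_labels)
    n = X.shape[0]
    if labels.shape != (n,):
        raise ConfigError("batch labels not aligned to embedding rows")
    uniq, enc = np.unique(labels, return_inverse=True)
    L = len(uniq)
    global_freq = np.bincount(enc, minlength=L) / n
    if (global_freq == 0).any():
        raise ConfigError("a batch label has zero global frequency")
    if k is None:
        k = default_k(labels)
    if k >= n:
        raise ConfigError(f"k={k} must be < n_cells={n}")
    if k < L:
        warnings.warn(
            "neighborhood smaller than the number of labels; chi^2 "
            "approximation will be poor",
            stacklevel=2,
        )
    if n_test is None or n_test >= n:
        test_idx = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        test_idx = rng.choice(n, size=n_test, replace=False)

    if L == 1:
        df = pd.DataFrame(
            {"cell_index": test_idx, "chi2": 0.0, "pval": 1.0}
        )
        return KbetResult(df, 100.0, k, len(test_idx))

    nn = NearestNeighbors(n_neighbors=k).fit(X)
    _, idx = nn.kneighbors(X[test_idx])  # self included: k nearest incl. cell
    neigh_labels = enc[idx]  # n_test x k
    obs = np.stack(
        [(neigh_labels == j).sum(axis=1) for j in range(L)], axis=1
    ).astype(float)
    exp = k * global_freq[None, :]
    chi2 = ((obs - exp) ** 2 / exp).sum(axis=1)
    pval = stats.chi2.sf(chi2, df=L - 1)
    df = pd.DataFrame({"cell_index": test_idx, "chi2": chi2, "pval": pval})
    acceptance = 100.0 * float((pval > ALPHA).mean())
    return KbetResult(df, acceptance, k, len(test_idx))


def proportionality_matrix(
    norm: NormalizedMatrix, cells_subset=None
) -> pd.DataFrame:
    """Pairwise proportionality rho_p between cells on log-scale expression.

    rho_p(x, y) = 2 cov(x, y) / (var(x) + var(y)), population (1/n)
    convention; bounded in [-1, 1], 1 on the diagonal. Constant cell vectors
    yield NaN rows/columns (undefined, reported as missing).
    """
    sub = norm if cells_subset is None else norm.subset_cells(cells_subset)
    if sub.n_cells < 2:
        raise ConfigError("need at least 2 cells")
    X = sub.values.T  # cells x genes
    Xc = X - X.mean(axis=1, keepdims=True)
    n_genes = X.shape[1]
    cov = (Xc @ Xc.T) / n_genes
    var = np.diag(cov).copy()
    denom = var[:, None] + var[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = 2.0 * cov / denom
    rho[(var == 0), :] = np.nan
    rho[:, (var == 0)] = np.nan
    ok = var > 0
    rho[np.ix_(ok, ok)] = np.clip(rho[np.ix_(ok, ok)], -1.0, 1.0)
    np.fill_diagonal(rho, np.where(ok, 1.0, np.nan))
    out = pd.DataFrame(rho, index=sub.barcodes, columns=sub.barcodes)
    if {"cell_type", "time_h"}.issubset(sub.cell_meta.columns):
        order = sub.cell_meta.sort_values(["cell_type", "time_h"]).index
        out = out.loc[order, order]
        out.attrs["ordering"] = "cell_type,time_h"
    return out


def downsample_balanced(
    norm: NormalizedMatrix,
    strata_labels,
    n_per_stratum: int = 50,
    seed: int = 0,
) -> NormalizedMatrix:
    """Sample at most ``n_per_stratum`` cells per stratum without
    replacement (undersized strata are kept whole), seeded."""
    labels = np.asarray(strata_labels)
    if labels.shape != (norm.n_cells,):
        raise ConfigError("strata labels not aligned to cells")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for s in pd.unique(labels):
        idx = np.flatnonzero(labels == s)
        if len(idx) > n_per_stratum:
            idx = rng.choice(idx, size=n_per_stratum, replace=False)
        keep.append(np.sort(idx))
    sel = np.sort(np.concatenate(keep))
    return norm.subset_cells(sel)


def variance_r2(
    norm: NormalizedMatrix,
    covariate,
    gene_subset=None,
) -> pd.Series:
    """Per-gene r^2 of expression on a categorical covariate.

    Equals between-group sum of squares over total sum of squares (one-way
    ANOVA eta^2 for the one-hot-coded OLS). Constant genes get r^2 = 0.
    """
    labels = np.asarray(covariate)
    if labels.shape != (norm.n_cells,):
        raise ConfigError("covariate not aligned to cells")
    if len(pd.unique(labels)) < 2:
        genes = norm.gene_names if gene_subset is None else pd.Index(gene_subset)
        return pd.Series(0.0, index=genes, name="r2")

    Y = norm.values
    genes = norm.gene_names
    if gene_subset is not None:
        pos = norm.gene_names.get_indexer(pd.Index(gene_subset))
        if (pos < 0).any():
            raise ConfigError("gene_subset contains unknown genes")
        Y = Y[pos]
        genes = pd.Index(gene_subset)

    grand = Y.mean(axis=1, keepdims=True)
    ss_tot = ((Y - grand) ** 2).sum(axis=1)
    ss_between = np.zeros(Y.shape[0])
    for s in pd.unique(labels):
        idx = np.flatnonzero(labels == s)
        gm = Y[:, idx].mean(axis=1)
        ss_between += len(idx) * (gm - grand.ravel()) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, ss_between / ss_tot, 0.0)
    return pd.Series(np.clip(r2, 0.0, 1.0), index=genes, name="r2")


def pc_variance_fraction(
    norm: NormalizedMatrix,
    covariate,
    n_pcs: int = 50,
    seed: int = 0,
) -> float:
    """Fraction of top-PC variance explained by a categorical covariate.

    PCA is run on the centered normalized matrix (cells as observations);
    the fraction is sum_i var(PC_i) * r2(PC_i ~ covariate) / sum_i var(PC_i)
    over the first ``n_pcs`` components.
    """
    labels = np.asarray(covariate)
    if labels.shape != (norm.n_cells,):
        raise ConfigError("covariate not aligned to cells")
    max_rank = min(norm.n_cells - 1, norm.n_genes)
    if n_pcs > max_rank:
        warnings.warn(
            f"n_pcs={n_pcs} exceeds the matrix rank; truncated to {max_rank}",
            stacklevel=2,
        )
        n_pcs = max_rank
    pca = PCA(n_components=n_pcs, random_state=seed)
    pcs = pca.fit_transform(norm.values.T)  # cells x n_pcs
    var = pcs.var(axis=0)
    if len(pd.unique(labels)) < 2 or var.sum() == 0:
        return 0.0
    pcs_nm = NormalizedMatrix(
        pcs.T, pd.Index([f"PC{i+1}" for i in range(pcs.shape[1])]), norm.cell_meta
    )
    r2 = variance_r2(pcs_nm, labels).values
    return float((var * r2).sum() / var.sum())
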
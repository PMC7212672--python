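"""Differential expression and the sampling-time signature.

Cells are split into time-biased (sampled > 2 h after draw) and time-unbiased
groups and every gene is tested with the two-sample Wilcoxon-Mann-Whitney
rank-sum test. The signature is the filtered table (|logFC| and adjusted-p
cuts); it is characterized by hypergeometric set enrichment and cross-study
overlap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from timedrift.containers import ConfigError, NormalizedMatrix

_EXACT_MAX = 8  # exact rank-sum null enumerated when both groups are this small


def _mannwhitney_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Mann-Whitney p per row of the genes x cells slices ``a``
    (biased) and ``b`` (unbiased).

    Exact null distribution when both groups have <= 8 observations and the
    row is tie-free; normal approximation with tie correction otherwise.
    """
    n1, n2 = a.shape[1], b.shape[1]
    if n1 <= _EXACT_MAX and n2 <= _EXACT_MAX:
        out = np.empty(a.shape[0])
        for g in range(a.shape[0]):
            row = np.concatenate([a[g], b[g]])
            method = "exact" if len(np.unique(row)) == len(row) else "asymptotic"
            out[g] = stats.mannwhitneyu(
                a[g], b[g], alternative="two-sided", method=method
            ).pvalue
        return out
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", axis=1
    )
    return np.atleast_1d(res.pvalue)


def wilcoxon_dea(
    norm: NormalizedMatrix,
    biased_mask: np.ndarray,
    pseudocount: float = 1.0,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Per-gene rank-sum differential expression, biased vs unbiased.

    Returns a DataFrame indexed by gene with columns ``logfc`` (natural log
    of pseudocounted de-logged group means, biased over unbiased),
    ``mean_biased``, ``mean_unbiased``, ``pval``, ``padj`` and ``direction``.

    ``adjust`` is ``"bonferroni"`` (default) or ``"bh"``
    (Benjamini-Hochberg).
    """
    biased_mask = np.asarray(biased_mask, dtype=bool)
    if biased_mask.shape != (norm.n_cells,):
        raise ConfigError("biased_mask not aligned to cells")
    if biased_mask.all() or not biased_mask.any():
        raise ConfigError("both groups must be non-empty")
    if adjust not in {"bonferroni", "bh"}:
        raise ConfigError(f"unknown adjustment {adjust!r}")

    a = norm.values[:, biased_mask]
    b = norm.values[:, ~biased_mask]

    # logFC on de-logged normalized means, pseudocounted, natural log
    mean_a = np.expm1(a).mean(axis=1)
    mean_b = np.expm1(b).mean(axis=1)
    logfc = np.log(mean_a + pseudocount) - np.log(mean_b + pseudocount)

    pval = _mannwhitney_p(a, b)
    # constant genes: identical distributions, p = 1
    const = (norm.values == norm.values[:, :1]).all(axis=1)
    pval = np.where(const, 1.0, pval)
    pval = np.clip(pval, 0.0, 1.0)

    method = "bonferroni" if adjust == "bonferroni" else "fdr_bh"
    padj = multipletests(pval, method=method)[1]

    direction = np.where(logfc > 0, "up", np.where(logfc < 0, "down", "none"))
    return pd.DataFrame(
        {
            "logfc": logfc,
            "mean_biased": np.log1p(mean_a),
            "mean_unbiased": np.log1p(mean_b),
            "pval": pval,
            "padj": padj,
            "direction": direction,
        },
        index=norm.gene_names,
    )


def define_signature(
    dea: pd.DataFrame,
    min_abs_logfc: float = 0.25,
    max_adj_p: float = 0.001,
    min_expr: float = 0.0,
) -> pd.DataFrame:
    """Filter a DEA table to the sampling-time signature.

    A gene enters when ``|logfc| >= min_abs_logfc``, ``padj < max_adj_p``
    and the larger of the two group means (log scale) is at least
    ``min_expr``. The result is sorted by |logfc|, descending, and carries
    the thresholds used as DataFrame attrs.
    """
    if min_abs_logfc < 0 or max_adj_p < 0 or min_expr < 0:
        raise ConfigError("signature thresholds must be nonnegative")
    if dea.empty:
        out = dea.copy()
    else:
        max_mean = dea[["mean_biased", "mean_unbiased"]].max(axis=1)
        keep = (
            (dea["logfc"].abs() >= min_abs_logfc)
            & (dea["padj"] < max_adj_p)
            & (max_mean >= min_expr)
        )
        out = dea.loc[keep].copy()
        out = out.reindex(out["logfc"].abs().sort_values(ascending=False).index)
    out.attrs["thresholds"] = {
        "min_abs_logfc": min_abs_logfc,
        "max_adj_p": max_adj_p,
        "min_expr": min_expr,
    }
    return out


def set_enrichment(
    target_genes,
    universe_genes,
    gene_sets: dict,
    min_size: int = 3,
    max_size_exclusive: int = 600,
    max_p: float = 0.05,
    min_or: float = 2.0,
) -> pd.DataFrame:
    """Over-representation of ``target_genes`` in each gene set.

    Term size (= universe genes annotated to the term) must satisfy
    ``min_size <= size < max_size_exclusive``; surviving terms are tested
    with the upper-tail hypergeometric p of the 2x2 overlap table, and rows
    are kept when ``p < max_p`` and sample odds ratio ``> min_or``
    (Haldane 0.5 correction applied when a table cell is zero).
    """
    universe = set(universe_genes)
    target = set(target_genes)
    stray = target - universe
    if stray:
        shown = sorted(stray)[:10]
        raise ConfigError(f"target genes not in universe: {shown}")

    N, n = len(universe), len(target)
    rows = []
    for term, members in gene_sets.items():
        term_in_universe = universe.intersection(members)
        K = len(term_in_universe)
        if K < min_size or K >= max_size_exclusive:
            continue
        k = len(target & term_in_universe)
        p = stats.hypergeom.sf(k - 1, N, K, n)
        a, b_, c, d = k, n - k, K - k, N - n - K + k
        if min(a, b_, c, d) == 0:
            a, b_, c, d = a + 0.5, b_ + 0.5, c + 0.5, d + 0.5
        odds = (a * d) / (b_ * c)
        rows.append((term, K, k, p, odds))
    out = pd.DataFrame(
        rows, columns=["term", "term_size", "overlap", "pval", "odds_ratio"]
    )
    if out.empty:
        return out
    out = out[(out["pval"] < max_p) & (out["odds_ratio"] > min_or)]
    return out.sort_values("pval").reset_index(drop=True)


def signature_overlap(
    sig_a: pd.DataFrame,
    sig_b: pd.DataFrame,
    top_n: int | None = None,
    rank_col: str = "logfc",
) -> dict:
    """Intersection report between two signature tables.

    With ``top_n``, both tables are truncated to the top-n genes by
    ``|rank_col|`` before intersecting (used to harmonize signature sizes
    across studies). Returns intersection genes, Jaccard index, and
    per-direction counts when both tables carry a ``direction`` column.
    """
    def top(sig: pd.DataFrame) -> pd.Index:
        if top_n is None:
            return sig.index
        if rank_col not in sig.columns:
            raise ConfigError(
                f"top_n requested but ranking column {rank_col!r} absent"
            )
        return sig[rank_col].abs().sort_values(ascending=False).index[:top_n]

    a, b = set(top(sig_a)), set(top(sig_b))
    inter = a & b
    union = a | b
    report = {
        "intersection": sorted(inter),
        "n_a": len(a),
        "n_b": len(b),
        "n_intersection": len(inter),
        "jaccard": len(inter) / len(union) if union else 1.0,
    }
    if "direction" in sig_a.columns and "direction" in sig_b.columns:
        for d in ("up", "down"):
            da = set(sig_a.index[sig_a["direction"] == d]) & a
            db = set(sig_b.index[sig_b["direction"] == d]) & b
            report[f"n_{d}_shared"] = len(da & db)
    return report
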
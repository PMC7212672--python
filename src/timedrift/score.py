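"""Per-cell time scoring, classification and regression-based correction.

The module score follows the expression-matched-control convention: genes
are binned by average expression, each signature gene draws control genes
from its own bin, and the score is the mean signature expression minus the
mean control expression per cell. A logistic model on the score classifies
time-biased cells; correction regresses each gene on the score within each
cell type and keeps the scaled, centered residuals. The bootstrap
silhouette procedure quantifies how much the affected/unaffected separation
survives correction across varying affected-cell fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import roc_curve, silhouette_score

from timedrift.containers import ConfigError, NormalizedMatrix

_COEF_CAP = 50.0  # logistic slope cap under perfect separation


def module_score(
    norm: NormalizedMatrix,
    signature_genes,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Expression-matched module score per cell.

    Genes are binned into ``n_bins`` expression bins by their average
    log-normalized expression. For every signature gene, ``n_ctrl``
    non-signature control genes are drawn from its bin (without replacement
    when the bin allows, with replacement otherwise); the score of cell c is

        mean_g in signature  norm[g, c]  -  mean_g in pooled controls  norm[g, c].

    Signature genes absent from the matrix are dropped with a warning.
    """
    sig = pd.Index(signature_genes)
    present = sig.intersection(norm.gene_names)
    if len(present) == 0:
        raise ConfigError("no signature gene present in the matrix")
    if len(present) < len(sig):
        warnings.warn(
            f"{len(sig) - len(present)} signature genes absent from the matrix",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)

    avg = norm.values.mean(axis=1)
    order = pd.Series(avg, index=norm.gene_names)
    n_bins_eff = min(n_bins, len(order))
    bins = pd.qcut(order.rank(method="first"), q=n_bins_eff, labels=False)

    sig_pos = norm.gene_names.get_indexer(present)
    sig_set = set(sig_pos)
    control_rows: list[int] = []
    for gpos in sig_pos:
        bin_id = bins.iloc[gpos]
        pool = np.flatnonzero((bins.values == bin_id))
        pool = np.array([p for p in pool if p not in sig_set])
        if len(pool) == 0:
            continue  # bin holds only signature genes; nothing to match
        replace = len(pool) < n_ctrl
        take = min(n_ctrl, len(pool)) if not replace else n_ctrl
        control_rows.extend(rng.choice(pool, size=take, replace=replace))

    sig_mean = norm.values[sig_pos].mean(axis=0)
    if control_rows:
        ctrl_mean = norm.values[np.asarray(control_rows)].mean(axis=0)
    else:
        ctrl_mean = np.zeros(norm.n_cells)
    scores = pd.Series(sig_mean - ctrl_mean, index=norm.barcodes, name="time_score")
    scores.attrs["provenance"] = {
        "n_signature_genes": int(len(present)),
        "n_bins": int(n_bins),
        "n_ctrl": int(n_ctrl),
        "seed": int(seed),
    }
    return scores


@dataclass
class LogisticTimeModel:
    """Unregularized logistic model of the affected flag on the time score."""

    intercept: float
    slope: float
    train_auc: float
    separation_warning: bool = False

    def predict_proba(self, scores) -> np.ndarray:
        z = self.intercept + self.slope * np.asarray(scores, dtype=float)
        return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: U / (n_pos * n_neg), ties counted one half."""
    pos = scores[labels]
    neg = scores[~labels]
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def fit_classifier(scores, labels) -> LogisticTimeModel:
    """Maximum-likelihood logistic fit of affected-vs-not on the time score.

    Perfect separation returns a model with capped coefficients plus a
    warning instead of failing.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ConfigError("both classes must be present to fit")

    X = sm.add_constant(s)
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y.astype(float), X).fit(disp=0, maxiter=200)
        beta0, beta1 = float(fit.params[0]), float(fit.params[1])
        if not np.isfinite([beta0, beta1]).all() or abs(beta1) > _COEF_CAP:
            raise ValueError("diverged")
    except Exception:
        separated = True
        # capped fallback: steep sigmoid through the class-boundary midpoint
        mid = (s[y].min() + s[~y].max()) / 2 if s[y].mean() >= s[~y].mean() else (
            (s[~y].min() + s[y].max()) / 2
        )
        sign = 1.0 if s[y].mean() >= s[~y].mean() else -1.0
        scale = max(np.std(s), 1e-12)
        beta1 = sign * _COEF_CAP / scale
        beta0 = -beta1 * mid
        warnings.warn(
            "perfect or quasi-perfect separation; coefficients capped",
            stacklevel=2,
        )
    # AUC of the fitted probabilities; sign-adjusted scores are the same
    # ranking without sigmoid saturation ties
    auc = _rank_auc(np.sign(beta1) * s if beta1 != 0 else s, y)
    return LogisticTimeModel(beta0, beta1, auc, separated)


def predict_auc(
    model: LogisticTimeModel | None, scores, labels
) -> tuple[float, pd.DataFrame]:
    """Rank-based AUC and ROC points of the (model-transformed) scores.

    The AUC is U / (n_pos * n_neg) with ties counted one half; because the
    logistic transform is monotone it is identical on raw scores and on
    predicted probabilities. ROC points are computed at every threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ConfigError("both classes must be present in test labels")
    if model is None:
        ranking, prob = s, s
    else:
        prob = model.predict_proba(s)
        # identical ranking to prob (monotone transform), no saturation ties
        ranking = np.sign(model.slope) * s if model.slope != 0 else prob
    auc = _rank_auc(ranking, y)
    fpr, tpr, thr = roc_curve(y, prob)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return auc, roc


def regress_out_score(
    norm: NormalizedMatrix,
    scores,
    cell_type_labels,
) -> np.ndarray:
    """Per-cell-type regression of each gene on the time score; the scaled
    and centered residual expression is returned (genes x cells, original
    cell order).

    Within each cell-type group the OLS slope of the gene on the score is
    estimated and the score-explained component ``slope * (score - mean
    score)`` subtracted, leaving the group mean in place so cell-identity
    structure survives the correction; the reassembled matrix is then
    centered and scaled to unit variance per gene (zero-variance genes map
    to all zeros). Correcting within cell types avoids Simpson's-paradox
    artifacts where a pooled slope mixes between-type and within-type
    relations.
    """
    s = np.asarray(scores, dtype=float)
    ct = np.asarray(cell_type_labels)
    if s.shape != (norm.n_cells,) or ct.shape != (norm.n_cells,):
        raise ConfigError("scores and cell-type labels must align to cells")

    corrected = np.empty_like(norm.values)
    for group in pd.unique(ct):
        idx = np.flatnonzero(ct == group)
        if len(idx) < 3:
            raise ConfigError(
                f"cell type group {group!r} has {len(idx)} cells; need >= 3"
            )
        Y = norm.values[:, idx]
        x = s[idx]
        xc = x - x.mean()
        ssx = (xc ** 2).sum()
        if ssx == 0:
            corrected[:, idx] = Y
        else:
            slope = (Y @ xc) / ssx
            corrected[:, idx] = Y - slope[:, None] * xc[None, :]
    corrected -= corrected.mean(axis=1, keepdims=True)
    sd = corrected.std(axis=1, keepdims=True)
    # residuals at rounding-noise scale count as zero variance
    tol = 1e-12 * max(1.0, float(np.abs(norm.values).max()))
    corrected = np.where(sd > tol, corrected / np.where(sd <= tol, 1, sd), 0.0)
    return corrected


def _pca_embed(values: np.ndarray, n_pcs: int, seed: int = 0) -> np.ndarray:
    """cells x n_pcs PCA embedding of a genes x cells matrix."""
    X = values.T
    n_pcs = min(n_pcs, min(X.shape) - 1)
    return PCA(n_components=max(n_pcs, 1), random_state=seed).fit_transform(X)


def bootstrap_silhouette(
    norm: NormalizedMatrix,
    scores,
    affected,
    cell_type_labels=None,
    pct_grid=tuple(range(10, 100, 10)),
    n_cells: int = 300,
    reps: int = 25,
    n_pcs: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Silhouette of the affected/unaffected split before vs after
    correction, bootstrapped across affected-cell fractions.

    For each percentage in ``pct_grid`` and each of ``reps`` replicates,
    ``n_cells`` cells are resampled with replacement at that approximate
    affected fraction; cells are embedded in ``n_pcs`` principal components
    and the average silhouette width of the affected/unaffected labels is
    computed on the raw resample and again after ``regress_out_score`` on
    the resample. Returns a tidy table
    (pct, rep, silhouette_before, silhouette_after).
    """
    y = np.asarray(affected, dtype=bool)
    s = np.asarray(scores, dtype=float)
    ct = (np.asarray(cell_type_labels) if cell_type_labels is not None
          else np.zeros(norm.n_cells, dtype=int))
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    if len(pos) == 0 or len(neg) == 0:
        raise ConfigError("both affected classes needed for resampling")
    rng = np.random.default_rng(seed)

    rows = []
    for pct in pct_grid:
        n_aff = int(round(n_cells * pct / 100))
        if n_aff == 0 or n_aff == n_cells:
            raise ConfigError(f"pct={pct} leaves one class empty at n={n_cells}")
        for rep in range(reps):
            idx = np.concatenate([
                rng.choice(pos, size=n_aff, replace=True),
                rng.choice(neg, size=n_cells - n_aff, replace=True),
            ])
            sub = norm.subset_cells(idx)
            sub.cell_meta = sub.cell_meta.copy()
            sub.cell_meta.index = pd.Index(
                [f"rs_{i}" for i in range(len(idx))]
            )
            lab = y[idx]
            emb = _pca_embed(sub.values, n_pcs, seed=seed)
            sil_before = silhouette_score(emb, lab)
            corr = regress_out_score(sub, s[idx], ct[idx])
            emb_after = _pca_embed(corr, n_pcs, seed=seed)
            sil_after = silhouette_score(emb_after, lab)
            rows.append((pct, rep, sil_before, sil_after))
    return pd.DataFrame(
        rows, columns=["pct", "rep", "silhouette_before", "silhouette_after"]
    )
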
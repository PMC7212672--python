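"""Hashed-sample demultiplexing: CLR normalization, k-medoids clustering,
background-quantile thresholding.

The procedure assigns each barcode to a hashtag (= pooled condition),
"multiplet" (exceeds the threshold of two or more hashtags) or "negative"
(exceeds none):

1. CLR-normalize counts per hashtag across barcodes.
2. Cluster barcodes by k-medoids (k = number of conditions) on the joint
   CLR profiles.
3. For each hashtag, the background is every barcode outside the cluster
   whose medoid carries the highest CLR value for that hashtag.
4. Trim the top fraction (default 0.5%) of background values as outliers;
   the calling threshold is the 0.99 quantile of the trimmed background —
   by default the quantile of a normal distribution fitted to the trimmed
   background (robust to residual doublet contamination of the background,
   mirroring the parametric background fit of the original hashing
   protocol), optionally the empirical sample quantile.
5. A barcode is positive for a hashtag when its CLR value strictly exceeds
   the threshold.

Demultiplexing is typically run per batch and donor; looping over strata is
left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from timedrift.containers import ConfigError, HtoMatrix

MULTIPLET = "multiplet"
NEGATIVE = "negative"


def clr_normalize(m: HtoMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio per hashtag: each count is divided by the geometric
    mean of that hashtag across barcodes and log-transformed.

    With pseudocount pc: ``clr[i, c] = ln(x[i, c] + pc) - mean_c ln(x[i, .] + pc)``.
    Every hashtag row has mean exactly zero.
    """
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be > 0")
    if m.n_htos == 0 or m.n_barcodes == 0:
        raise ConfigError("empty HTO matrix")
    logx = np.log(m.counts + pseudocount)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=m.hto_names, columns=m.barcode_ids)


def _kmedoids(X: np.ndarray, k: int, rng: np.random.Generator,
              max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """PAM-style k-medoids with k-means++-style seeding, Euclidean distance.

    Returns (labels, medoid_indices) for the n x d matrix ``X``.
    """
    n = X.shape[0]
    D = cdist(X, X)
    medoids = [int(rng.integers(n))]
    for _ in range(k - 1):
        d2 = np.min(D[:, medoids], axis=1) ** 2
        total = d2.sum()
        p = d2 / total if total > 0 else np.full(n, 1.0 / n)
        medoids.append(int(rng.choice(n, p=p)))
    medoids = np.asarray(medoids)
    labels = np.argmin(D[:, medoids], axis=1)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if len(members) == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[np.argmin(within)]
        new_labels = np.argmin(D[:, new_medoids], axis=1)
        if np.array_equal(new_medoids, medoids) and np.array_equal(new_labels, labels):
            break
        medoids, labels = new_medoids, new_labels
    return labels, medoids


@dataclass
class DemuxResult:
    """Per-barcode condition calls plus the per-hashtag CLR thresholds.

    ``calls`` maps barcode -> hashtag name, "multiplet" or "negative";
    ``n_exceeded`` counts thresholds exceeded per barcode; ``thresholds``
    is the CLR-scale cut per hashtag; ``background`` is the boolean
    hashtag x barcode membership mask of the (untrimmed) background.
    """

    calls: pd.Series
    n_exceeded: pd.Series
    thresholds: pd.Series
    background: pd.DataFrame
    cluster_labels: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"call": self.calls, "n_thresholds_exceeded": self.n_exceeded}
        )


def demultiplex_barcodes(
    clr: pd.DataFrame,
    k: int,
    outlier_trim: float = 0.005,
    q: float = 0.99,
    seed: int = 0,
    threshold_method: str = "fit",
) -> DemuxResult:
    """Call each barcode from its CLR profile via cluster-defined backgrounds.

    Parameters
    ----------
    clr
        hashtags x barcodes CLR matrix (``clr_normalize`` output).
    k
        Number of k-medoids clusters; normally the number of conditions.
    outlier_trim
        Fraction of the top background values discarded as outliers.
    q
        Background quantile used as threshold. Ties at exactly the
        threshold do not exceed it.
    threshold_method
        ``"fit"`` (default): q-quantile of a normal distribution fitted to
        the trimmed background (mean + z_q * sd), robust to doublets of
        other hashtags that leak into the background. ``"quantile"``: the
        empirical sample quantile (linear interpolation).
    """
    n_htos, n_barcodes = clr.shape
    if k < 2:
        raise ConfigError("k must be >= 2")
    if k > n_barcodes:
        raise ConfigError(f"k={k} exceeds the number of barcodes ({n_barcodes})")
    if not (0 <= outlier_trim < 1):
        raise ConfigError("outlier_trim must be in [0, 1)")
    if not (0 < q < 1):
        raise ConfigError("q must be in (0, 1)")
    if threshold_method not in {"fit", "quantile"}:
        raise ConfigError(f"unknown threshold_method {threshold_method!r}")

    X = clr.values.T  # barcodes x hashtags
    rng = np.random.default_rng(seed)
    labels, medoids = _kmedoids(X, k, rng)

    thresholds = np.empty(n_htos)
    background = np.empty((n_htos, n_barcodes), dtype=bool)
    medoid_profiles = X[medoids]  # k x n_htos
    for i in range(n_htos):
        fg_cluster = int(np.argmax(medoid_profiles[:, i]))
        bg_mask = labels != fg_cluster
        background[i] = bg_mask
        bg_vals = np.sort(X[bg_mask, i])
        n_trim = int(np.floor(outlier_trim * bg_vals.size))
        if n_trim:
            bg_vals = bg_vals[:-n_trim]
        if bg_vals.size == 0:
            raise ConfigError(
                f"empty background for hashtag {clr.index[i]!r} after trimming; "
                "clustering is degenerate"
            )
        if threshold_method == "fit":
            thresholds[i] = bg_vals.mean() + stats.norm.ppf(q) * bg_vals.std()
        else:
            thresholds[i] = np.quantile(bg_vals, q)

    exceeds = X > thresholds[None, :]  # strict: ties do not exceed
    n_exc = exceeds.sum(axis=1)
    calls = np.empty(n_barcodes, dtype=object)
    calls[n_exc == 0] = NEGATIVE
    calls[n_exc >= 2] = MULTIPLET
    singles = np.flatnonzero(n_exc == 1)
    if len(singles):
        calls[singles] = clr.index.values[np.argmax(exceeds[singles], axis=1)]

    barcodes = clr.columns
    return DemuxResult(
        calls=pd.Series(calls, index=barcodes, name="call"),
        n_exceeded=pd.Series(n_exc, index=barcodes, name="n_thresholds_exceeded"),
        thresholds=pd.Series(thresholds, index=clr.index, name="threshold"),
        background=pd.DataFrame(background, index=clr.index, columns=barcodes),
        cluster_labels=pd.Series(labels, index=barcodes, name="cluster"),
    )
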
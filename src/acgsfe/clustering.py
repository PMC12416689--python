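"""Dynamic hierarchical clustering of correlated features.

Two stages:

1. Choose the number of clusters ``k``. The candidate range is driven by
   the dataset's feature-to-observation ratio (high-dimensional sets get a
   wider range), and each candidate is scored on a Ward cut of the feature
   embedding with a combined Davies-Bouldin / Silhouette score; the ``k``
   minimising the combined score wins.
2. Cut the same Ward linkage at the chosen ``k`` to obtain one cluster
   label per feature.

The embedding clustered in both stages is the feature-by-feature Pearson
correlation matrix: each feature's row of correlations is its coordinate
vector, so features with similar co-expression profiles sit close in
Euclidean space, which is the metric Ward's variance criterion requires.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

__all__ = [
    "ClusterSearchRange",
    "ClusterScoreTable",
    "ClusterModel",
    "feature_obs_ratio",
    "cluster_search_range",
    "feature_embedding",
    "score_partition",
    "select_optimal_clusters",
    "assign_feature_clusters",
    "fit_cluster_model",
]


@dataclass
class ClusterSearchRange:
    min_clusters: int
    max_clusters: int
    divisor: int
    feature_obs_ratio: float


@dataclass
class ClusterScoreTable:
    """Per-candidate-k validity scores and the combined objective."""

    k_values: np.ndarray
    db_values: np.ndarray
    sil_values: np.ndarray
    normalized_db: np.ndarray
    normalized_sil: np.ndarray
    combined_score: np.ndarray


@dataclass
class ClusterModel:
    num_clusters: int
    feature_clusters: np.ndarray  # label per feature, 1..num_clusters
    score_table: ClusterScoreTable | None = field(default=None, repr=False)


def feature_obs_ratio(n_features: int, n_obs: int) -> float:
    """#features / #observations; e.g. 2000/62 -> 32.26 (2 dp)."""
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    return n_features / n_obs


def cluster_search_range(ratio: float) -> ClusterSearchRange:
    """Candidate-k range from the feature-to-observation ratio.

    Low-ratio datasets (< 300) get a larger divisor relative to the ratio
    (fewer clusters); higher ratios get a slightly smaller divisor (more
    clusters). ``max_clusters`` is clamped to at least 2 for tiny ratios.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if ratio < 300:
        divisor = 10 * math.ceil(ratio / 100)
    else:
        divisor = 10 * math.ceil(ratio / 100) - 10
    max_clusters = max(2, math.floor(ratio / divisor))
    return ClusterSearchRange(2, max_clusters, divisor, ratio)


def feature_embedding(train_values: np.ndarray) -> np.ndarray:
    """Feature-by-feature Pearson correlation matrix.

    Constant features (zero variance) get correlation 0 with every other
    feature by convention; the diagonal stays 1 so the result remains a
    valid correlation matrix.
    """
    X = np.asarray(train_values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 observations")
    sd = X.std(axis=0)
    constant = sd == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[np.isnan(corr)] = 0.0
    if constant.any():
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def _davies_bouldin(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean over clusters of the worst (S_i + S_j) / ||c_i - c_j|| ratio.

    Computed with direct Euclidean norms (not the quadratic expansion) so
    it agrees with the defining formula to full float precision.
    """
    ids = np.unique(labels)
    centroids = np.stack([points[labels == i].mean(axis=0) for i in ids])
    scatter = np.array([
        np.mean(np.linalg.norm(points[labels == i] - centroids[n], axis=1))
        for n, i in enumerate(ids)
    ])
    k = len(ids)
    worst = np.empty(k)
    for i in range(k):
        sep = np.linalg.norm(centroids - centroids[i], axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (scatter + scatter[i]) / sep
        ratio[i] = -np.inf
        worst[i] = ratio.max()
    return float(np.mean(worst))


def score_partition(
    embedding: np.ndarray, labels: np.ndarray, k: int
) -> tuple[float, float]:
    """Davies-Bouldin index and mean Silhouette for one candidate cut.

    Returns ``(nan, nan)`` when an index is uncomputable (e.g. all points
    coincide) rather than raising, mirroring a try/except-NaN policy.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    present = np.unique(labels)
    if len(present) != k:
        raise ValueError(f"expected {k} non-empty clusters, found {len(present)}")
    db = sil = float("nan")
    if np.all(embedding == embedding[0]):
        # zero scatter and zero separation everywhere: both indices are 0/0
        return db, sil
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            db = _davies_bouldin(np.asarray(embedding, dtype=float), labels)
            if not np.isfinite(db):
                db = float("nan")
        except Exception:
            pass
        try:
            sil = float(silhouette_score(embedding, labels))
        except Exception:
            pass
    return db, sil


def _normalize(values: np.ndarray) -> np.ndarray:
    """Min-max scale over non-NaN entries; constant -> all zeros."""
    out = np.full_like(values, np.nan, dtype=float)
    valid = ~np.isnan(values)
    if not valid.any():
        return out
    lo, hi = np.nanmin(values), np.nanmax(values)
    if hi == lo:
        out[valid] = 0.0
    else:
        out[valid] = (values[valid] - lo) / (hi - lo)
    return out


def select_optimal_clusters(
    embedding: np.ndarray, search_range: ClusterSearchRange
) -> ClusterModel:
    """Pick k in [min, max] minimising 0.5*norm_DB + 0.5*(1 - norm_Sil).

    The Ward linkage is computed once and cut at each candidate k. NaN
    scores (uncomputable indices, or a cut yielding fewer than k distinct
    clusters) exclude that k; if no candidate is valid the minimum of the
    range is returned. Ties go to the smallest k.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if n < search_range.min_clusters:
        raise ValueError("fewer points than min_clusters")
    kmax = min(search_range.max_clusters, n)
    ks = np.arange(search_range.min_clusters, kmax + 1)
    Z = linkage(embedding, method="ward")
    db = np.full(len(ks), np.nan)
    sil = np.full(len(ks), np.nan)
    cuts: list[np.ndarray | None] = []
    for i, k in enumerate(ks):
        lab = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(lab)) != k:
            cuts.append(None)
            continue
        cuts.append(lab)
        db[i], sil[i] = score_partition(embedding, lab, int(k))

    ndb = _normalize(db)
    nsil = _normalize(sil)
    combined = 0.5 * ndb + 0.5 * (1.0 - nsil)
    valid = ~np.isnan(combined)
    if valid.any():
        # argmin over valid entries; np.nanargmin ties -> first (smallest k)
        best_i = int(np.nanargmin(combined))
        best_k = int(ks[best_i])
        labels = cuts[best_i]
    else:
        best_k = search_range.min_clusters
        labels = fcluster(Z, t=best_k, criterion="maxclust")
    table = ClusterScoreTable(ks, db, sil, ndb, nsil, combined)
    return ClusterModel(best_k, np.asarray(labels, dtype=np.int64), table)


def assign_feature_clusters(train_values: np.ndarray, num_clusters: int) -> ClusterModel:
    """Ward-cluster the feature correlation matrix into ``num_clusters``."""
    X = np.asarray(train_values, dtype=float)
    if num_clusters > X.shape[1]:
        raise ValueError("num_clusters exceeds number of features")
    emb = feature_embedding(X)
    Z = linkage(emb, method="ward")
    labels = fcluster(Z, t=num_clusters, criterion="maxclust")
    return ClusterModel(num_clusters, np.asarray(labels, dtype=np.int64))


def fit_cluster_model(train_values: np.ndarray) -> ClusterModel:
    """Full pipeline: ratio -> candidate range -> optimal k -> feature labels."""
    X = np.asarray(train_values, dtype=float)
    ratio = feature_obs_ratio(X.shape[1], X.shape[0])
    rng_ = cluster_search_range(ratio)
    emb = feature_embedding(X)
    model = select_optimal_clusters(emb, rng_)
    return model
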
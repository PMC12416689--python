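"""Joint-histogram mutual information between features and class labels.

MI(X, Y) = sum_{x,y} p(x,y) * ln[ p(x,y) / (p(x) p(y)) ]

estimated from a 2-D histogram: continuous feature values are discretized
into equal-width bins over their observed range, labels are used as-is
(never binned), and cells with zero joint probability are skipped. Values
are in nats; the base only rescales scores and the ranking downstream is
base-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MIScores", "mutual_information", "rank_features_by_mi", "mi_profile"]

DEFAULT_BINS = 10


@dataclass
class MIScores:
    """MI (nats) per feature index, at a fixed bin count."""

    scores: dict[int, float]
    bins: int


def _equal_width_bin(x: np.ndarray, bins: int) -> np.ndarray:
    """Bin indices 0..bins-1 over [min, max]; constant x -> all zeros."""
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(len(x), dtype=np.int64)
    idx = np.floor((x - lo) / (hi - lo) * bins).astype(np.int64)
    return np.minimum(idx, bins - 1)


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int = DEFAULT_BINS) -> float:
    """MI in nats between a numeric vector and discrete labels.

    ``x`` is discretized into ``bins`` equal-width bins; ``y`` codes are
    taken as distinct discrete values. A constant ``x`` occupies a single
    bin and yields MI 0 exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    xi = _equal_width_bin(x, bins)
    _, yi = np.unique(y, return_inverse=True)
    ny = yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=bins * ny).reshape(bins, ny)
    joint = joint / joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mask = joint > 0
    expected = np.outer(px, py)
    return float(np.sum(joint[mask] * np.log(joint[mask] / expected[mask])))


def mi_profile(
    train_values: np.ndarray, y: np.ndarray, bins: int = DEFAULT_BINS
) -> np.ndarray:
    """MI of every feature column against the labels (one pass, cached by callers)."""
    X = np.asarray(train_values, dtype=float)
    return np.array([mutual_information(X[:, j], y, bins) for j in range(X.shape[1])])


def rank_features_by_mi(
    feature_indices: np.ndarray,
    train_values: np.ndarray,
    y: np.ndarray,
    bins: int = DEFAULT_BINS,
    *,
    mi_scores: np.ndarray | None = None,
) -> np.ndarray:
    """Feature indices sorted by MI descending; ties break to the lower index.

    ``mi_scores`` may supply precomputed per-feature MI for the whole
    matrix (as from :func:`mi_profile`) to avoid recomputation in hot loops.
    """
    idx = np.asarray(feature_indices, dtype=np.int64)
    if len(idx) == 0:
        return idx
    if mi_scores is not None:
        mi = np.asarray(mi_scores, dtype=float)[idx]
    else:
        X = np.asarray(train_values, dtype=float)
        mi = np.array([mutual_information(X[:, j], y, bins) for j in idx])
    order = np.lexsort((idx, -mi))
    return idx[order]
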
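"""Adaptive MI-based intra-cluster regularization.

After the search operators propose a candidate mask, each feature cluster
is pruned to its most label-informative members. The per-cluster cap
shrinks as the search budget is consumed:

    base  = max(1, ceil((FEs_max - FEs) / FEs_max * 3))      # 3 -> 1
    SF    = 1 + (1 - progress) * 0.5 * u,   u ~ U[0, 1]      # 1.5 -> 1
    limit = ceil(base * SF)                                  # 5 -> 1

Early in the run up to ceil(3 * 1.5) = 5 features per cluster survive,
encouraging exploration; by the end at most ceil(1 * SF) <= 2 do, forcing
a compact subset. Within each cluster the surviving features are the
top-MI candidates. Two candidate-set scopes exist:

* ``scope="all"`` (default): every member of the cluster is a candidate,
  so the output mask is rebuilt from the MI ranking and the stochastic
  cap alone. Across independent runs the accepted subsets are then nearly
  identical, which is what gives the method its characteristic
  run-to-run stability.
* ``scope="selected"``: candidates are the intersection of the cluster
  with the incoming mask, so the step only ever prunes what the wrapper
  operators proposed.
"""

from __future__ import annotations

import math

import numpy as np

from .clustering import ClusterModel
from .mi import DEFAULT_BINS, mi_profile, rank_features_by_mi

__all__ = [
    "adaptive_base_limit",
    "scaling_factor",
    "adaptive_feature_limit",
    "apply_regularization",
]


def adaptive_base_limit(fes: int, fes_max: int) -> int:
    """Base per-cluster cap: 3 early in the budget, decaying to 1."""
    if not 1 <= fes <= fes_max:
        raise ValueError("require 1 <= fes <= fes_max")
    return max(1, math.ceil((fes_max - fes) / fes_max * 3))


def scaling_factor(progress_factor: float, u: float) -> float:
    """Stochastic inflation of the cap, in [1, 1.5]; shrinks to 1 as progress -> 1."""
    return 1.0 + (1.0 - progress_factor) * 0.5 * u


def adaptive_feature_limit(base: int, sf: float) -> int:
    """Final per-cluster cap: ceil(base * SF)."""
    return math.ceil(base * sf)


def apply_regularization(
    mask: np.ndarray,
    cluster_model: ClusterModel,
    train_values: np.ndarray,
    y: np.ndarray,
    base: int,
    progress_factor: float,
    rng: np.random.Generator,
    bins: int = DEFAULT_BINS,
    *,
    mi_scores: np.ndarray | None = None,
    scope: str = "all",
) -> np.ndarray:
    """Prune a candidate mask cluster-by-cluster to its top-MI members.

    One fresh uniform draw per cluster feeds the scaling factor, in
    ascending cluster-label order, so results are deterministic under a
    fixed ``rng`` stream. Clusters whose candidate set is empty contribute
    nothing (the output can be empty; the search's selection operator
    rescues that case).
    """
    mask = np.asarray(mask, dtype=bool)
    labels = cluster_model.feature_clusters
    if len(mask) != len(labels):
        raise ValueError("mask length does not match cluster labels")
    if scope not in ("selected", "all"):
        raise ValueError("scope must be 'selected' or 'all'")
    if mi_scores is None:
        mi_scores = mi_profile(train_values, y, bins)
    out = np.zeros_like(mask)
    for cluster_id in np.unique(labels):
        u = rng.random()
        limit = adaptive_feature_limit(base, scaling_factor(progress_factor, u))
        members = np.flatnonzero(labels == cluster_id)
        candidates = members[mask[members]] if scope == "selected" else members
        if len(candidates) == 0:
            continue
        ranked = rank_features_by_mi(candidates, train_values, y, bins,
                                     mi_scores=mi_scores)
        out[ranked[: min(limit, len(ranked))]] = True
    return out
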
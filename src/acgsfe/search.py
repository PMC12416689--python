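"""The ACG-SFE wrapper search.

A single-agent hill-climb over binary feature masks. Each iteration
(one function evaluation, FE):

1. *Non-selection*: clear ``round(UR * Nvar)`` randomly chosen selected
   bits, where the non-selection rate UR decays linearly from ``UR_max``
   to ``UR_min`` over the budget — aggressive pruning early, fine-grained
   late.
2. *Selection* (rescue): if the mask emptied, restore it and switch ``SN``
   non-selected bits on, guaranteeing at least one selected feature.
3. *Regularization*: prune the candidate per feature cluster to its
   top-MI members under the shrinking adaptive cap.
4. *Fitness*: mean stratified k-fold cross-validated accuracy of a
   1-nearest-neighbour classifier restricted to the selected features.
   The candidate replaces the incumbent iff its fitness is >= (ties
   accepted, which lets the search drift across accuracy plateaus toward
   smaller subsets).

Clustering is fitted once per dataset on the training partition; every
run shares the same split and folds but uses independent search RNG
streams. Disabling clustering/regularization (``mode="sfe"``) recovers
the plain SFE baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KNeighborsClassifier

from .clustering import ClusterModel, fit_cluster_model
from .io import LabeledMatrix, SplitPlan, make_split_plan
from .metrics import confusion_counts, f_measure
from .mi import mi_profile
from .regularize import adaptive_base_limit, apply_regularization

__all__ = [
    "SearchConfig",
    "RunResult",
    "ur_value",
    "nonselection_operator",
    "selection_operator",
    "evaluate_fitness",
    "run_acg_sfe",
    "run_batch",
]

log = logging.getLogger(__name__)


@dataclass
class SearchConfig:
    """All knobs of the search; defaults follow the benchmark protocol."""

    fes_max: int = 6000          # function-evaluation budget per run
    run_max: int = 30            # independent runs
    ur_max: float = 0.3          # initial non-selection rate
    ur_min: float = 0.001        # final non-selection rate
    sn: int = 1                  # bits switched on by the rescue operator
    k_folds: int = 5
    knn_k: int = 1
    mi_bins: int = 10
    split_seed: int = 42         # drives holdout + folds, shared across runs
    test_fraction: float = 0.2
    run_seeds: list[int] | None = None
    regularize_scope: str = "all"
    use_clustering: bool = True
    use_regularization: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.ur_min < self.ur_max < 1:
            raise ValueError("require 0 < ur_min < ur_max < 1")
        if self.sn < 1:
            raise ValueError("sn must be >= 1")

    @classmethod
    def sfe_baseline(cls, **kwargs) -> "SearchConfig":
        """Plain-SFE configuration: no clustering, no regularization."""
        kwargs.setdefault("use_clustering", False)
        kwargs.setdefault("use_regularization", False)
        return cls(**kwargs)

    def resolved_run_seeds(self) -> list[int]:
        if self.run_seeds is not None:
            if len(self.run_seeds) != self.run_max:
                raise ValueError("run_seeds length must equal run_max")
            return list(self.run_seeds)
        ss = np.random.SeedSequence([self.split_seed, 0x5FE])
        return [int(s) for s in ss.generate_state(self.run_max) >> 1]


@dataclass
class RunResult:
    """Outcome of one independent search run."""

    best_mask: np.ndarray
    fitness_trajectory: np.ndarray  # best validation accuracy after each FE
    n_selected: int
    train_accuracy: float
    test_accuracy: float
    f_measure: float
    seed: int
    selected_features: np.ndarray = field(default=None, repr=False)
    # optional per-FE log of (adaptive base, candidate mask), see run_acg_sfe
    candidate_log: list = field(default=None, repr=False)


def ur_value(fes: int, fes_max: int, ur_max: float = 0.3, ur_min: float = 0.001) -> float:
    """Linearly decaying non-selection rate: ur_max at FEs=0 down to ur_min."""
    if not 0 <= fes <= fes_max:
        raise ValueError("require 0 <= fes <= fes_max")
    return (ur_max - ur_min) * ((fes_max - fes) / fes_max) + ur_min


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def nonselection_operator(
    mask: np.ndarray, ur: float, nvar: int, rng: np.random.Generator
) -> np.ndarray:
    """Clear round(ur * nvar) distinct selected bits (all of them if fewer)."""
    mask = np.asarray(mask, dtype=bool)
    un = _round_half_away(ur * nvar)
    out = mask.copy()
    if un <= 0:
        return out
    selected = np.flatnonzero(mask)
    k = min(un, len(selected))
    if k:
        out[rng.choice(selected, size=k, replace=False)] = False
    return out


def selection_operator(
    mask: np.ndarray, original: np.ndarray, sn: int, rng: np.random.Generator
) -> np.ndarray:
    """Rescue an empty mask: restore ``original`` and switch ``sn`` bits on.

    A non-empty mask passes through unchanged; a fully selected original
    (no non-selected bit to flip) is restored as-is.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.any():
        return mask.copy()
    out = np.asarray(original, dtype=bool).copy()
    nonselected = np.flatnonzero(~out)
    if len(nonselected):
        out[rng.choice(nonselected, size=min(sn, len(nonselected)), replace=False)] = True
    return out


def evaluate_fitness(
    mask: np.ndarray,
    train_values: np.ndarray,
    labels: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    knn_k: int = 1,
) -> float:
    """Mean k-fold CV accuracy (%) of a KNN restricted to the selected features."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot evaluate an empty feature mask")
    X = np.asarray(train_values, dtype=float)[:, mask]
    y = np.asarray(labels)
    accs = []
    for tr, te in folds:
        clf = KNeighborsClassifier(n_neighbors=knn_k)
        clf.fit(X[tr], y[tr])
        accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
    return 100.0 * float(np.mean(accs))


def run_acg_sfe(
    config: SearchConfig,
    data: LabeledMatrix,
    split: SplitPlan,
    run_seed: int,
    cluster_model: ClusterModel | None = None,
    log_candidates: bool = False,
) -> RunResult:
    """One independent search run under ``run_seed``.

    Two named RNG streams are derived from the run seed — one for the
    search operators, one for the regularization scaling factor — so
    toggling regularization does not perturb the operator draws.
    With ``log_candidates`` the result carries the per-FE adaptive base
    and evaluated candidate mask (memory: fes_max x n_features bits).
    """
    Xtr = data.values[split.train_idx]
    ytr = data.labels[split.train_idx]
    folds = split.folds()
    nvar = data.n_features

    ss = np.random.SeedSequence(run_seed)
    search_rng, reg_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    regularize = config.use_regularization and config.use_clustering
    if regularize and cluster_model is None:
        cluster_model = fit_cluster_model(Xtr)
    mi_scores = mi_profile(Xtr, ytr, config.mi_bins) if regularize else None

    mask = search_rng.random(nvar) < 0.5
    if not mask.any():  # probability 2^-nvar, but keep the contract
        mask[search_rng.integers(nvar)] = True
    best_fit = evaluate_fitness(mask, Xtr, ytr, folds, config.knn_k)

    trajectory = np.empty(config.fes_max)
    candidate_log = [] if log_candidates else None
    for fes in range(1, config.fes_max + 1):
        ur = ur_value(fes - 1, config.fes_max, config.ur_max, config.ur_min)
        candidate = nonselection_operator(mask, ur, nvar, search_rng)
        candidate = selection_operator(candidate, mask, config.sn, search_rng)
        base = adaptive_base_limit(fes, config.fes_max)
        if regularize:
            pre_reg = candidate
            candidate = apply_regularization(
                candidate, cluster_model, Xtr, ytr, base,
                fes / config.fes_max, reg_rng, config.mi_bins,
                mi_scores=mi_scores, scope=config.regularize_scope,
            )
            candidate = selection_operator(candidate, pre_reg, config.sn, search_rng)
        fit = evaluate_fitness(candidate, Xtr, ytr, folds, config.knn_k)
        if fit >= best_fit:
            mask, best_fit = candidate, fit
        trajectory[fes - 1] = best_fit
        if log_candidates:
            candidate_log.append((base, candidate.copy()))
    log.info("run seed=%d: best CV accuracy %.2f%%, %d features",
             run_seed, best_fit, int(mask.sum()))

    # held-out evaluation of the final subset
    clf = KNeighborsClassifier(n_neighbors=config.knn_k)
    clf.fit(Xtr[:, mask], ytr)
    train_acc = 100.0 * float(np.mean(clf.predict(Xtr[:, mask]) == ytr))
    Xte = data.values[split.test_idx][:, mask]
    yte = data.labels[split.test_idx]
    pred = clf.predict(Xte)
    test_acc = 100.0 * float(np.mean(pred == yte))
    cc = confusion_counts(yte, pred, positive=data.minority_class)
    return RunResult(
        best_mask=mask,
        fitness_trajectory=trajectory,
        n_selected=int(mask.sum()),
        train_accuracy=train_acc,
        test_accuracy=test_acc,
        f_measure=f_measure(cc),
        seed=run_seed,
        selected_features=np.flatnonzero(mask),
        candidate_log=candidate_log,
    )


def run_batch(
    config: SearchConfig,
    data: LabeledMatrix,
    split: SplitPlan | None = None,
) -> list[RunResult]:
    """``run_max`` independent runs over a shared split and cluster model."""
    if split is None:
        split = make_split_plan(data, config.test_fraction, config.k_folds,
                                config.split_seed)
    cluster_model = None
    if config.use_regularization and config.use_clustering:
        cluster_model = fit_cluster_model(data.values[split.train_idx])
        log.info("cluster model: k=%d", cluster_model.num_clusters)
    return [
        run_acg_sfe(config, data, split, seed, cluster_model)
        for seed in config.resolved_run_seeds()
    ]
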
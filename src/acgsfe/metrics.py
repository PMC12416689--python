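"""Evaluation metrics and multi-run aggregation.

Per-run metrics: test accuracy, F-measure (positive class defaults to
the minority class), the train/test RMSE that quantifies overfitting,
number of selected features and the feature reduction rate (FRR).
Across runs: worst/best/mean/sample-std summaries plus feature-selection
stability as the mean pairwise Jaccard similarity of the selected
subsets, and the "stable" features chosen in more than half the runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "accuracy",
    "f_measure",
    "rmse_train_test",
    "frr",
    "jaccard_similarity",
    "stability_summary",
    "aggregate_runs",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true, y_pred, positive: int = 1) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def accuracy(c: ConfusionCounts) -> float:
    """100 * (TP + TN) / total."""
    if c.total == 0:
        raise ValueError("no evaluated samples")
    return 100.0 * (c.tp + c.tn) / c.total


def f_measure(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall, as a percentage; 0 when TP = 0."""
    if c.tp == 0:
        return 0.0
    precision = c.tp / (c.tp + c.fp)
    recall = c.tp / (c.tp + c.fn)
    return 100.0 * 2 * precision * recall / (precision + recall)


def rmse_train_test(train_acc: Sequence[float], test_acc: Sequence[float]) -> float:
    """Root mean squared train-test accuracy gap (%); |train - test| for one run."""
    train = np.asarray(train_acc, dtype=float)
    test = np.asarray(test_acc, dtype=float)
    if train.shape != test.shape or train.size == 0:
        raise ValueError("train and test accuracy lists must match and be non-empty")
    return float(np.sqrt(np.mean((train - test) ** 2)))


def frr(n_selected: int, n_total: int) -> float:
    """Feature reduction rate: 100 * (1 - selected/total)."""
    if n_total <= 0 or not 0 <= n_selected <= n_total:
        raise ValueError("require 0 <= n_selected <= n_total, n_total > 0")
    return 100.0 * (1.0 - n_selected / n_total)


def jaccard_similarity(a: Iterable[int], b: Iterable[int]) -> float:
    """100 * |a ∩ b| / |a ∪ b|; two empty sets count as identical (100)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 100.0
    return 100.0 * len(a & b) / len(union)


def _summary(values: np.ndarray, *, lower_is_better: bool = False) -> dict[str, float]:
    """worst/best/mean/sample-std; orientation set by ``lower_is_better``."""
    values = np.asarray(values, dtype=float)
    std = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    lo, hi = float(values.min()), float(values.max())
    worst, best = (hi, lo) if lower_is_better else (lo, hi)
    return {"worst": worst, "best": best, "mean": float(values.mean()), "std": std}


def stability_summary(masks: Sequence[np.ndarray]) -> dict:
    """Pairwise Jaccard statistics plus per-feature selection frequencies.

    ``masks`` are boolean vectors of equal length. The stable set contains
    features selected in more than half of the runs.
    """
    if len(masks) < 2:
        raise ValueError("need at least 2 masks")
    masks = [np.asarray(m, dtype=bool) for m in masks]
    sets = [np.flatnonzero(m) for m in masks]
    pair_values = [
        jaccard_similarity(sets[i], sets[j])
        for i in range(len(sets))
        for j in range(i + 1, len(sets))
    ]
    freq = np.sum(masks, axis=0)
    stable = np.flatnonzero(freq > len(masks) / 2)
    return {
        "jaccard": _summary(np.asarray(pair_values)),
        "pairwise_jaccard": np.asarray(pair_values),
        "selection_frequency": freq,
        "stable_features": stable,
    }


@dataclass
class MetricsReport:
    """Aggregate of a batch of runs, shaped like the benchmark tables."""

    n_runs: int
    n_total_features: int
    test_accuracy: dict[str, float]
    f_measure: dict[str, float]
    rmse: dict[str, float]
    n_selected: dict[str, float]
    frr: dict[str, float]
    jaccard: dict[str, float]
    stable_features: np.ndarray = field(repr=False, default=None)
    selection_frequency: np.ndarray = field(repr=False, default=None)
    per_run: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def to_rows(self) -> list[dict]:
        rows = []
        for metric in ("test_accuracy", "f_measure", "rmse", "n_selected",
                       "frr", "jaccard"):
            stats = getattr(self, metric)
            rows.append({"metric": metric, **stats})
        return rows


def aggregate_runs(results: Sequence, n_total_features: int) -> MetricsReport:
    """Build a MetricsReport from RunResult-like objects.

    Each result needs ``test_accuracy``, ``train_accuracy``, ``f_measure``,
    ``n_selected`` and ``best_mask`` attributes. Per-run RMSE is the
    absolute train-test gap; "worst" is the maximum for RMSE and the
    number of selected features, the minimum for everything else.
    """
    if len(results) == 0:
        raise ValueError("need at least 1 run")
    test = np.array([r.test_accuracy for r in results])
    train = np.array([r.train_accuracy for r in results])
    fm = np.array([r.f_measure for r in results])
    nsel = np.array([r.n_selected for r in results], dtype=float)
    rmse_runs = np.abs(train - test)
    frr_runs = np.array([frr(int(n), n_total_features) for n in nsel])

    if len(results) >= 2:
        stab = stability_summary([r.best_mask for r in results])
        jac = stab["jaccard"]
        stable = stab["stable_features"]
        freq = stab["selection_frequency"]
    else:
        jac = {"worst": 100.0, "best": 100.0, "mean": 100.0, "std": 0.0}
        stable = np.flatnonzero(results[0].best_mask)
        freq = np.asarray(results[0].best_mask, dtype=int)

    return MetricsReport(
        n_runs=len(results),
        n_total_features=n_total_features,
        test_accuracy=_summary(test),
        f_measure=_summary(fm),
        rmse=_summary(rmse_runs, lower_is_better=True),
        n_selected=_summary(nsel, lower_is_better=True),
        frr=_summary(frr_runs),
        jaccard=jac,
        stable_features=stable,
        selection_frequency=freq,
        per_run={
            "test_accuracy": test,
            "train_accuracy": train,
            "f_measure": fm,
            "n_selected": nsel,
            "rmse": rmse_runs,
            "frr": frr_runs,
        },
    )
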
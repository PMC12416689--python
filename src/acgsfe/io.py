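"""Loading, validating and splitting labeled expression matrices.

The canonical in-memory container is :class:`LabeledMatrix`: a dense
``n_obs x n_features`` matrix of expression-like values with binary class
labels. Matrices arrive as delimited text (CSV/TSV) with samples as rows;
a ``transpose`` flag accommodates the features-as-rows dialect common for
microarray distributions.

Splitting follows the evaluation protocol used throughout the package: a
stratified 80/20 holdout plus stratified k-fold cross-validation folds
inside the training partition, all driven by a single integer seed through
a dedicated RNG stream so that the partitions are shared across search
runs while the searches themselves use independent randomness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "LabeledMatrix",
    "SplitPlan",
    "load_labeled_matrix",
    "write_labeled_matrix",
    "stratified_holdout",
    "stratified_kfold",
    "make_split_plan",
]


@dataclass
class LabeledMatrix:
    """A samples x features numeric matrix with binary {0,1} labels."""

    values: np.ndarray
    labels: np.ndarray
    feature_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (samples x features)")
        n_obs, n_features = self.values.shape
        if self.labels.shape != (n_obs,):
            raise ValueError(
                f"labels length {self.labels.shape} does not match {n_obs} samples"
            )
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, [0, 1]):
            raise ValueError("labels must contain both classes coded {0,1}")
        if np.isnan(self.values).any():
            raise ValueError("matrix contains missing values")
        counts = np.bincount(self.labels.astype(int), minlength=2)
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 samples")
        if not self.feature_ids:
            self.feature_ids = [f"f{i}" for i in range(n_features)]
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n_obs)]
        if len(self.feature_ids) != n_features:
            raise ValueError("feature_ids length mismatch")
        if len(set(self.feature_ids)) != n_features:
            raise ValueError("feature_ids must be unique")
        if len(self.sample_ids) != n_obs:
            raise ValueError("sample_ids length mismatch")
        self.labels = self.labels.astype(np.int64)

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def minority_class(self) -> int:
        """Class code of the minority class (class 0 on exact ties)."""
        counts = np.bincount(self.labels, minlength=2)
        return int(np.argmin(counts))  # argmin prefers 0 on ties

    @property
    def imbalance_ratio(self) -> float:
        counts = np.bincount(self.labels, minlength=2)
        return counts.max() / counts.min()


@dataclass
class SplitPlan:
    """Holdout and cross-validation index sets over a LabeledMatrix.

    ``train_idx``/``test_idx`` index the full sample axis; the fold index
    pairs are *relative* positions into ``train_idx`` so a fold can be
    applied directly to the training partition.
    """

    train_idx: np.ndarray
    test_idx: np.ndarray
    fold_train_idx: list[np.ndarray] = field(default_factory=list)
    fold_test_idx: list[np.ndarray] = field(default_factory=list)
    seed: int = 0
    k_folds: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": int(self.seed),
                "k_folds": int(self.k_folds),
                "train_idx": [int(i) for i in self.train_idx],
                "test_idx": [int(i) for i in self.test_idx],
                "fold_train_idx": [[int(i) for i in f] for f in self.fold_train_idx],
                "fold_test_idx": [[int(i) for i in f] for f in self.fold_test_idx],
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        d = json.loads(text)
        return cls(
            train_idx=np.asarray(d["train_idx"], dtype=np.int64),
            test_idx=np.asarray(d["test_idx"], dtype=np.int64),
            fold_train_idx=[np.asarray(f, dtype=np.int64) for f in d["fold_train_idx"]],
            fold_test_idx=[np.asarray(f, dtype=np.int64) for f in d["fold_test_idx"]],
            seed=d["seed"],
            k_folds=d["k_folds"],
        )

    def folds(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return list(zip(self.fold_train_idx, self.fold_test_idx))


def _recode_labels(raw: pd.Series) -> np.ndarray:
    """Map two distinct label values to {0,1}, lexicographically smaller -> 0."""
    uniq = sorted({str(v) for v in raw})
    if len(uniq) != 2:
        raise ValueError(
            f"not binary: found {len(uniq)} distinct label values {uniq[:5]}"
        )
    mapping = {uniq[0]: 0, uniq[1]: 1}
    return np.array([mapping[str(v)] for v in raw], dtype=np.int64)


def load_labeled_matrix(
    path: str | Path,
    label_spec: str | Path,
    *,
    transpose: bool = False,
    sep: str | None = None,
) -> LabeledMatrix:
    """Read a delimited numeric matrix plus binary labels.

    Parameters
    ----------
    path
        CSV/TSV file, samples as rows (set ``transpose=True`` for the
        features-as-rows dialect). A header row of feature ids is used
        when present.
    label_spec
        Either the name of a column inside the matrix file holding the
        class labels, or the path of a one-column companion file with one
        label per sample.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")

    labels: np.ndarray | None = None
    label_spec_s = str(label_spec)
    if not transpose and label_spec_s in df.columns:
        labels = _recode_labels(df[label_spec_s])
        df = df.drop(columns=[label_spec_s])
    else:
        lp = Path(label_spec_s)
        if not lp.exists():
            raise ValueError(
                f"label column {label_spec_s!r} not found and no such label file"
            )
        raw = pd.read_csv(lp, header=None).iloc[:, -1]
        labels = _recode_labels(raw)

    if transpose:
        df = df.T

    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df.iloc[:, j], errors="coerce")
            bad = coerced.isna() & df.iloc[:, j].notna()
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"non-numeric cell at row {i}, column {col!r}: "
                    f"{df.iloc[i, j]!r}"
                )
        values = df.apply(pd.to_numeric).to_numpy()
    values = values.astype(float)
    if np.isnan(values).any():
        i, j = map(int, np.argwhere(np.isnan(values))[0])
        raise ValueError(f"missing value at row {i}, column {j}")

    feature_ids = [str(c) for c in df.columns]
    sample_ids = [str(i) for i in df.index] if transpose else [
        f"s{i}" for i in range(values.shape[0])
    ]
    return LabeledMatrix(values, labels, feature_ids, sample_ids)


def write_labeled_matrix(data: LabeledMatrix, path: str | Path, *, label_col: str = "label") -> None:
    """Write matrix + labels to CSV so that ``load_labeled_matrix`` round-trips."""
    df = pd.DataFrame(data.values, columns=data.feature_ids)
    df[label_col] = data.labels
    df.to_csv(path, index=False, float_format="%.17g")


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


def stratified_holdout(
    data: LabeledMatrix, test_fraction: float, seed: int
) -> SplitPlan:
    """Deterministic stratified train/test split.

    Per-class test counts are ``round(class_count * test_fraction)``
    (round-half-to-even); the largest class is then adjusted by +/-1 steps
    so the total equals ``round(n_obs * test_fraction)``. With the class
    sizes of the benchmark microarray sets this yields e.g. 12 test
    samples for 62 obs (40/22) and 15 for 77 obs (58/19) at fraction 0.2.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    labels = data.labels
    n = data.n_obs
    target_total = _round_half_even(n * test_fraction)
    classes = [0, 1]
    counts = {c: int(np.sum(labels == c)) for c in classes}
    test_counts = {c: _round_half_even(counts[c] * test_fraction) for c in classes}
    largest = max(classes, key=lambda c: counts[c])
    test_counts[largest] += target_total - sum(test_counts.values())
    for c in classes:
        if not 1 <= test_counts[c] <= counts[c] - 1:
            raise ValueError(
                f"class {c} too small to stratify: {counts[c]} samples, "
                f"{test_counts[c]} requested for test"
            )
    rng = np.random.default_rng(seed)
    test_parts, train_parts = [], []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        perm = rng.permutation(idx)
        test_parts.append(perm[: test_counts[c]])
        train_parts.append(perm[test_counts[c]:])
    test_idx = np.sort(np.concatenate(test_parts))
    train_idx = np.sort(np.concatenate(train_parts))
    return SplitPlan(train_idx=train_idx, test_idx=test_idx, seed=seed)


def stratified_kfold(labels: Sequence[int] | np.ndarray, k: int, seed: int) -> SplitPlan:
    """Stratified k-fold partition of a (training) label vector.

    Returns a SplitPlan whose fold indices are positions 0..len(labels)-1;
    ``train_idx`` covers all positions and ``test_idx`` is empty.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(labels.astype(int), minlength=2)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} samples < k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_train, fold_test = [], []
    for tr, te in skf.split(np.zeros((len(labels), 1)), labels):
        fold_train.append(np.asarray(tr, dtype=np.int64))
        fold_test.append(np.asarray(te, dtype=np.int64))
    return SplitPlan(
        train_idx=np.arange(len(labels), dtype=np.int64),
        test_idx=np.array([], dtype=np.int64),
        fold_train_idx=fold_train,
        fold_test_idx=fold_test,
        seed=seed,
        k_folds=k,
    )


def make_split_plan(
    data: LabeledMatrix,
    test_fraction: float = 0.2,
    k_folds: int = 5,
    seed: int = 42,
) -> SplitPlan:
    """Holdout + in-training CV folds in one plan (the evaluation protocol)."""
    plan = stratified_holdout(data, test_fraction, seed)
    fold_plan = stratified_kfold(data.labels[plan.train_idx], k_folds, seed)
    plan.fold_train_idx = fold_plan.fold_train_idx
    plan.fold_test_idx = fold_plan.fold_test_idx
    plan.k_folds = k_folds
    return plan
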
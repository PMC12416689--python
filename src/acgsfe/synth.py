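"""Synthetic high-dimensional binary-classification data.

Emulates the statistical shape of microarray benchmarks: far more features
than samples, features organised into correlated blocks (co-expressed gene
groups), a handful of class-informative features, and balanced to
moderately imbalanced labels.

Construction
------------
Labels are drawn with exact class counts matching the requested imbalance
ratio. Each feature block shares a latent Gaussian factor ``f_b``; feature
``j`` in block ``b`` is

    x_j = sqrt(rho) * f_b + sqrt(1 - rho) * eps_j,      eps_j ~ N(0, noise_sd^2·(unit))

so every within-block pair has correlation ``rho`` in expectation while
blocks are mutually independent. Informative features additionally receive
a class-conditional mean shift of ``effect_size`` standard deviations and
are spread across blocks round-robin, so that intra-cluster ranking has
signal to find in several clusters rather than one.

Not modelled: heteroscedastic noise, batch effects, heavy-tailed intensity
distributions of real arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import LabeledMatrix

__all__ = ["SyntheticSpec", "GroundTruth", "generate"]


@dataclass
class SyntheticSpec:
    """Parameters of the block-correlated generator.

    Defaults are a mid-scale regime of the benchmark shapes: many more
    features than samples, moderate within-block correlation, balanced
    classes and unit noise.
    """

    n_samples: int = 100
    n_features: int = 1000
    n_blocks: int = 5
    block_rho: float = 0.5
    n_informative: int = 10
    effect_size: float = 1.0
    imbalance_ratio: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must be in [0, 1)")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must be <= n_features")
        if self.n_blocks > self.n_features or self.n_blocks < 1:
            raise ValueError("n_blocks must be in [1, n_features]")
        if self.imbalance_ratio < 1:
            raise ValueError("imbalance_ratio is majority/minority, must be >= 1")


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    block_labels: np.ndarray        # block id per feature, 1..n_blocks
    informative_idx: np.ndarray     # indices of class-informative features
    spec: SyntheticSpec = field(repr=False, default=None)


def _draw_labels(n: int, imbalance_ratio: float, rng: np.random.Generator) -> np.ndarray:
    n_minority = int(round(n / (1.0 + imbalance_ratio)))
    if n_minority < 2:
        raise ValueError(
            f"infeasible imbalance: minority class would have {n_minority} < 2 samples"
        )
    labels = np.zeros(n, dtype=np.int64)
    labels[:n_minority] = 1  # class 1 = minority
    rng.shuffle(labels)
    return labels


def generate(spec: SyntheticSpec) -> tuple[LabeledMatrix, GroundTruth]:
    """Generate a LabeledMatrix plus the planted ground truth.

    Deterministic: the same spec (including seed) yields a bit-identical
    matrix.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_features

    labels = _draw_labels(n, spec.imbalance_ratio, rng)

    # contiguous, near-equal block sizes
    block_labels = 1 + (np.arange(d) * spec.n_blocks) // d
    factors = rng.standard_normal((n, spec.n_blocks))
    eps = rng.standard_normal((n, d))
    rho = spec.block_rho
    values = np.sqrt(rho) * factors[:, block_labels - 1] + np.sqrt(1.0 - rho) * eps
    values *= spec.noise_sd

    # informative features: one per block round-robin (first feature of
    # each block, then second, ...) so signal is spread over clusters
    block_starts = np.searchsorted(block_labels, np.arange(1, spec.n_blocks + 1))
    informative = []
    offset = 0
    while len(informative) < spec.n_informative:
        for b in range(spec.n_blocks):
            j = block_starts[b] + offset
            if (j < d and block_labels[j] == b + 1
                    and len(informative) < spec.n_informative):
                informative.append(j)
        offset += 1
    informative_idx = np.array(sorted(informative), dtype=np.int64)

    shift = spec.effect_size * spec.noise_sd
    values[:, informative_idx] += shift * labels[:, None]

    data = LabeledMatrix(
        values,
        labels,
        feature_ids=[f"g{j}" for j in range(d)],
        sample_ids=[f"s{i}" for i in range(n)],
    )
    truth = GroundTruth(block_labels=block_labels, informative_idx=informative_idx,
                        spec=spec)
    return data, truth
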
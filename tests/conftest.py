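import numpy as np
import pytest

from acgsfe import LabeledMatrix, SyntheticSpec, generate


@pytest.fixture
def tiny_matrix() -> LabeledMatrix:
    """12 samples x 6 features; feature 0 mirrors the label."""
    rng = np.random.default_rng(7)
    labels = np.array([0, 1] * 6)
    values = rng.standard_normal((12, 6))
    values[:, 0] = labels * 3.0
    return LabeledMatrix(values, labels)


@pytest.fixture
def blocky_data():
    """200 samples x 40 features in 4 strongly correlated blocks."""
    spec = SyntheticSpec(n_samples=200, n_features=40, n_blocks=4, block_rho=0.9,
                         n_informative=4, effect_size=1.0, seed=11)
    return generate(spec)
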
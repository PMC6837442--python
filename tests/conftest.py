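import numpy as np
import pytest

from valbias.synthetic_data import Dataset, generate_discriminable, generate_noise


@pytest.fixture
def noise_small():
    """20 samples x 50 noise features."""
    return generate_noise(20, 50, seed=101)


@pytest.fixture
def noise_medium():
    """60 samples x 50 noise features."""
    return generate_noise(60, 50, seed=202)


@pytest.fixture
def discriminable_big():
    """1000 samples, default discriminable generator."""
    return generate_discriminable(1000, seed=303)


@pytest.fixture
def blobs_2d():
    """Two well-separated 2-D blobs, trivially linearly separable."""
    rng = np.random.default_rng(9)
    n = 40
    x0 = rng.normal(0.0, 0.3, size=(n // 2, 2)) + [-3.0, -3.0]
    x1 = rng.normal(0.0, 0.3, size=(n // 2, 2)) + [3.0, 3.0]
    feats = np.vstack([x0, x1])
    labels = np.repeat([0, 1], n // 2)
    return Dataset(features=feats, labels=labels, meta={"generator": "blobs"})


@pytest.fixture
def xor_points():
    """The classic 4-point XOR arrangement (no linear separator)."""
    feats = np.array([[-1.0, -1.0], [1.0, 1.0], [-1.0, 1.0], [1.0, -1.0]])
    labels = np.array([0, 0, 1, 1])
    return feats, labels
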
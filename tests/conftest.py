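import numpy as np
import pytest

from resphs import (
    HyperparameterSpace,
    TrainingConfig,
    generate_dataset,
    split_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_space():
    """64-candidate space: 2 values per axis, two conv layers."""
    return HyperparameterSpace(
        cld=2, ks_min=3, ks_max=5, kc_min=16, kc_max=17, dlnc_min=256, dlnc_max=257
    )


@pytest.fixture
def full_space():
    """The published search space: odd kernel sizes 3-81, counts 16-1024,
    dense widths 256-4096, three conv layers."""
    return HyperparameterSpace()


@pytest.fixture(scope="session")
def small_dataset():
    """Low-noise dataset shared across CNN tests: 3 subjects x 5 x 12 pieces
    at 10 Hz, split 120/30/30."""
    rng = np.random.default_rng(777)
    ds = generate_dataset(3, 12, fs=10.0, duration=10.0, rng=rng, noise=0.02)
    split_dataset(ds, 150, 0.2, rng)
    return ds


@pytest.fixture
def fast_training():
    return TrainingConfig(epochs=10, batch_size=30, learning_rate=0.1)
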
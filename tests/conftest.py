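import numpy as np
import pytest

from specnn.dataset import SpectralDataset
from specnn.synth import SimSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """10 samples x 5 bands, 2 classes, deterministic."""
    rng = np.random.default_rng(0)
    X = rng.uniform(0.1, 0.9, size=(10, 5))
    return SpectralDataset(
        reflectance=X,
        wavelengths=np.array([400.0, 450.0, 500.0, 550.0, 600.0]),
        labels=np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1]),
        class_names=["A", "B"],
        sample_ids=[f"s{i}" for i in range(10)],
    )


@pytest.fixture
def balanced_dataset():
    """660 samples (3 x 220) on the visnir grid, mild difficulty."""
    return generate(SimSpec(preset="visnir", n_per_class=220, seed=42))


@pytest.fixture
def small_synthetic():
    """Small, fast dataset: 3 x 30 samples, visnir grid."""
    return generate(SimSpec(preset="visnir", n_per_class=30, seed=3))
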
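import numpy as np
import pytest

from cropgcnn import GCNNConfig, ImageBatch, SyntheticSpec, generate_synthetic


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_rgb_batch():
    """A small batch of random RGB images in [0, 1]."""
    gen = np.random.default_rng(42)
    return ImageBatch(gen.random((4, 8, 8, 3)), space="RGB", normalized=False)


@pytest.fixture(scope="session")
def default_synthetic():
    """Default 10-class synthetic set at moderate size."""
    return generate_synthetic(SyntheticSpec(n_per_class=30, seed=5))


@pytest.fixture()
def tiny_config():
    """A small but structurally complete GCNN configuration."""
    return GCNNConfig(
        input_size=(16, 16),
        stage1_filters=6,
        stage2_filters=12,
        dense_units=(16, 8),
        n_classes=4,
        seed=3,
    )
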
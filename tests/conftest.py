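import numpy as np
import pytest

from histoclust import (
    SyntheticParams,
    TrainConfig,
    build_model1,
    generate_synthetic_dataset,
    stratified_split,
    train_softmax,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def separable_ds():
    """Noise-free synthetic tiles: the classes are linearly separable by design."""
    return generate_synthetic_dataset(SyntheticParams(n_images=160, seed=11).noise_free())


@pytest.fixture(scope="session")
def trained_small(separable_ds):
    """A small CNN trained briefly on the separable data (shared across tests)."""
    train_ds, test_ds = stratified_split(separable_ds, 0.3, seed=4)
    net = build_model1(conv_maps=(4, 4, 4, 4, 16), seed=21)
    net, history = train_softmax(net, train_ds, test_ds,
                                 TrainConfig(epochs=15, learning_rate=3e-3, seed=22))
    return net, history, train_ds, test_ds


@pytest.fixture(scope="session")
def three_gaussian_points():
    """60 colour points from three tight, well-separated Gaussians."""
    rng = np.random.default_rng(42)
    means = (0.15, 0.5, 0.85)
    pts = np.vstack([rng.normal(m, 0.02, size=(20, 3)) for m in means])
    labels = np.repeat(np.arange(3), 20)
    return pts, np.array([[m] * 3 for m in means], dtype=float), labels
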
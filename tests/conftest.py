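import numpy as np
import pytest

import sweepnet as sn


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_neutral_reps():
    """Small neutral equilibrium replicates (scaled rates, no recombination)."""
    cfg = sn.SimConfig(theta=20.0, rho=0.0, n_samples=10)
    return sn.simulate(cfg, 10, seed=101)


@pytest.fixture(scope="session")
def toy_training_data():
    """Linearly separable window images: all-black vs all-gray."""
    black = np.zeros((150, 12, 30), dtype=np.uint8)
    gray = np.full((150, 12, 30), 127, dtype=np.uint8)
    x = np.concatenate([black, gray])
    y = np.array([0] * 150 + [1] * 150)
    return x, y


@pytest.fixture(scope="session")
def small_arch():
    return sn.ArchSpec(filters=(4, 4), dense_sizes=(8,))


@pytest.fixture(scope="session")
def toy_model(toy_training_data, small_arch):
    x, y = toy_training_data
    net = sn.build_model(small_arch, input_shape=x.shape[1:], seed=0)
    return sn.train(net, x, y, epochs=3, seed=0)
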
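import numpy as np
import pytest

from farnet import BackboneConfig, FARNet, make_default_spec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_spec():
    return make_default_spec(seed=0)


@pytest.fixture(scope="session")
def tiny_net():
    """A small assembled network with fixed weights, shared across tests."""
    return FARNet(BackboneConfig(arch="tiny"), n_labels=8, seed=7).eval()


@pytest.fixture(scope="session")
def image_batch():
    gen = np.random.default_rng(99)
    return gen.uniform(0.0, 1.0, size=(4, 64, 64, 3))
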
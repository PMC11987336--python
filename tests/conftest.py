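import numpy as np
import pytest

from rxnsearch.encoder import EncoderConfig, init_model
from rxnsearch.synthetic_fixtures import FixtureConfig, generate_reactions


@pytest.fixture(scope="session")
def small_records():
    """80 deterministic synthetic reaction records."""
    return generate_reactions(FixtureConfig(n_reactions=80, seed=3))


@pytest.fixture(scope="session")
def tiny_config():
    return EncoderConfig(gnn_layers=2, gnn_hidden=24, projection_hidden=32, p=16, seed=5)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    """An untrained small encoder shared across read-only tests."""
    return init_model(tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def numeric_grad(fn, x, eps=1e-6):
    """Central-difference gradient of a scalar function of one array."""
    x = np.asarray(x, dtype=np.float64)
    grad = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp = x.copy()
        xp[idx] += eps
        xm = x.copy()
        xm[idx] -= eps
        grad[idx] = (fn(xp) - fn(xm)) / (2 * eps)
        it.iternext()
    return grad
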
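import numpy as np
import pytest

from busseg.network import ModelConfig
from busseg.ssm import SSMParams

# A deliberately tiny architecture for fast unit tests (not the
# miniature benchmark config; just enough structure to exercise paths).
TINY = ModelConfig(
    image_size=32,
    level_channels=(4, 8, 16, 32),
    blocks_per_level=(1, 1, 1, 1),
    heads_per_level=(1, 2, 2, 4),
    ssm=SSMParams(d_state=4),
    dropout=0.1,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    return TINY


@pytest.fixture(scope="session")
def tiny_model():
    from busseg.network import build_model

    return build_model(TINY)


@pytest.fixture(scope="session")
def phantom_batch():
    """Eight deterministic 64x64 phantoms with masks."""
    from busseg.phantom import PhantomSpec, load_samples

    spec = PhantomSpec(image_size=64, lesion_count=1, seed=11)
    return load_samples(spec, 8, k_folds=2)


def fd_gradient(f, x, eps=1e-6):
    """Central finite-difference gradient of a scalar function of an array."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    flat, gf = x.ravel(), g.ravel()
    for i in range(flat.size):
        old = flat[i]
        flat[i] = old + eps
        fp = f(x)
        flat[i] = old - eps
        fm = f(x)
        flat[i] = old
        gf[i] = (fp - fm) / (2 * eps)
    return g
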
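import numpy as np
import pytest

from t1liver.grid import VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom():
    """A fast, noiseless 24^3 phantom shared across modules."""
    from t1liver.synthetic import PhantomSpec, generate_phantom

    spec = PhantomSpec(grid_shape=(24, 24, 24), noise_sd=0.0, rng_seed=42)
    return generate_phantom(spec)


def make_grid(values, spacing=(1.0, 1.0, 1.0)):
    return VolumeGrid(np.asarray(values, dtype=float), spacing)
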
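import numpy as np
import pytest

from phasedprior import (
    make_coil_maps,
    make_complex_phantom,
    simulate_kspace,
)
from phasedprior.types import SamplingMask


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom64():
    return make_complex_phantom(n=64, seed=0)


@pytest.fixture(scope="session")
def full_mask64():
    return SamplingMask(np.ones((64, 64), dtype=bool))


@pytest.fixture(scope="session")
def acquisition64(phantom64, full_mask64):
    """Noiseless fully sampled 4-coil acquisition of the seeded phantom."""
    coils = make_coil_maps(64, 4, seed=1)
    y = simulate_kspace(phantom64, coils, full_mask64, noise_std=0.0)
    return phantom64, coils, y


def random_complex(rng, shape, scale=1.0):
    return scale * (rng.normal(size=shape) + 1j * rng.normal(size=shape))
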
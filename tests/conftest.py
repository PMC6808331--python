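import numpy as np
import pytest

from rakikit import SamplingScheme
from rakikit.simulate import make_dataset, make_linear_consistent_kspace


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """Noiseless 4-coil 64x64 acquisition, R=2, 16 ACS lines (fast tests)."""
    return make_dataset(nc=4, Nx=64, Ny=64, R=2, acs_width=16, seed=7)


@pytest.fixture(scope="session")
def planted():
    """Linearly consistent k-space with a known 5x4 kernel (R=4, 8 coils)."""
    scheme = SamplingScheme.centered(128, 4, 32)
    k, kernel = make_linear_consistent_kspace(8, 128, 128, scheme, seed=11)
    return k, kernel, scheme
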
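import numpy as np
import pytest

from autorad3d.phantom import PhantomSpec, make_phantom_volume


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Default-size noiseless phantom specification."""
    return PhantomSpec(noise_sd=0.0)


@pytest.fixture(scope="session")
def phantom_volume(small_spec):
    return make_phantom_volume(small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
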
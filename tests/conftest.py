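import numpy as np
import pytest

from wingquant import CannyParams, PhantomSpec, ThresholdSpec, generate_phantom


@pytest.fixture
def canny_params():
    return CannyParams()


@pytest.fixture
def threshold_spec():
    return ThresholdSpec(threshold=0.5)


@pytest.fixture(scope="session")
def clean_phantom():
    """A noise-free phantom with a 0.25 stripe, shared across tests."""
    spec = PhantomSpec(noise_sd=0.0, photon_scale=0.0, stripe_fraction=0.25, seed=7)
    return generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
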
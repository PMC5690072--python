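import numpy as np
import pytest
from hypothesis import settings

from drifttrack import SimConfig, simulate_pair, simulate_session

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def noiseless_config(**overrides) -> SimConfig:
    """A disturbance-free configuration: the model class is exactly realized."""
    base = dict(noise_ext_mm=0.0, noise_int_mm=0.0, cardiac_amp_mm=0.0, amp_mod=0.0)
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def clean_pair():
    """Noiseless, drift-free first/nth session pair with ground truth."""
    return simulate_pair(noiseless_config(seed=7))


@pytest.fixture(scope="session")
def clean_session(clean_pair):
    first, _, truth = clean_pair
    return first, truth


@pytest.fixture(scope="session")
def noisy_pair():
    """A default-noise, drift-free pair (cardiac + measurement noise on)."""
    return simulate_pair(SimConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
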
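import numpy as np
import pytest

from ietmix import EMMParams, sample_emm


@pytest.fixture
def two_component_params() -> EMMParams:
    """Well-separated two-component mixture used across tests."""
    return EMMParams(weights=np.array([0.5, 0.5]), means=np.array([1.0, 100.0]))


@pytest.fixture
def two_component_sample(two_component_params):
    return sample_emm(two_component_params, 2000, seed=1234)


@pytest.fixture
def exponential_sample():
    rng = np.random.default_rng(99)
    return rng.exponential(5.0, size=2000)
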
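import numpy as np
import pytest

from nichesim import SimParams, simulate


@pytest.fixture(scope="session")
def default_primed_trajectory():
    """One default primed-variant run, shared read-only across tests."""
    return simulate(SimParams(seed=11))


@pytest.fixture(scope="session")
def default_rtg_trajectory():
    """One default return-to-ground run, shared read-only across tests."""
    return simulate(SimParams(variant="return_to_ground", seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
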
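import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neoscore.simulate import SyntheticConfig, simulate_cohort

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cohort154():
    """One study-sized synthetic cohort, shared across tests."""
    return simulate_cohort(SyntheticConfig(n=154, seed=1))


@pytest.fixture(scope="session")
def cohort_large():
    """A large cohort for distributional checks on the generator."""
    return simulate_cohort(SyntheticConfig(n=20000, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
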
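import pytest
from hypothesis import HealthCheck, settings

from afenrich.simulate import SimulationConfig, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-site default-design dataset shared across read-only tests."""
    return simulate_dataset(SimulationConfig(n_sites=300, seed=11))


@pytest.fixture(scope="session")
def taqman_pairs():
    from afenrich.datasets import load_taqman_validation

    return load_taqman_validation()
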
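import pytest
from hypothesis import HealthCheck, settings

from ciloss.simulate import SimulationConfig, simulate_all

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset under the default study conditions."""
    return simulate_all(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Default conditions with annotation noise and incompleteness off."""
    return simulate_all(
        SimulationConfig(seed=0, misannotation_prob=0.0, incomplete_genome_prob=0.0)
    )
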
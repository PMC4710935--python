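import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from esacea import CEAConfig, SimulationParams, load_table3_fixture, simulate_cohort


@pytest.fixture(scope="session")
def config():
    return CEAConfig()


@pytest.fixture(scope="session")
def table3():
    return load_table3_fixture()


@pytest.fixture(scope="session")
def default_cohort():
    """Deterministic synthetic crossover cohort (75 patients, 2 phases)."""
    return simulate_cohort(SimulationParams(seed=1))
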
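import numpy as np
import pytest
from hypothesis import settings

from compsel import GroundTruthScenario, SimulationConfig
from compsel.cohort import simulate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

N_MID = 200_000  # big enough for ±3/sqrt(n) checks, small enough to stay fast


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def mid_config():
    return SimulationConfig(n_applicants=N_MID, seed=11)


@pytest.fixture(scope="session")
def invalid_test_cohort(mid_config):
    return simulate_cohort(GroundTruthScenario.from_name("invalid_test"), mid_config)


@pytest.fixture(scope="session")
def valid_uncorrelated_cohort(mid_config):
    return simulate_cohort(
        GroundTruthScenario.from_name("valid_uncorrelated"), mid_config
    )


@pytest.fixture(scope="session")
def valid_correlated_cohort(mid_config):
    return simulate_cohort(
        GroundTruthScenario.from_name("valid_correlated"), mid_config
    )
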
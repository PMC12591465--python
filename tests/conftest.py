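import numpy as np
import pytest

from edna_biomass import RunConfig, SimulationDesign, simulate_survey


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def survey(config):
    """One default 70-site synthetic survey shared across read-only tests."""
    return simulate_survey(SimulationDesign(seed=42), config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
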
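import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from rewiremap.config import ModelConfig
from rewiremap.cortex import CortexGeometry
from rewiremap.rewiring import Simulation
from rewiremap.stimulus_lgn import (LGNRFParams, build_response_table,
                                    single_orientation_ensemble,
                                    twelve_orientation_ensemble)


@pytest.fixture(scope="session")
def rf_params():
    return LGNRFParams()


@pytest.fixture(scope="session")
def tiny_geometry():
    """4x4 cortex, 2x2 LGN, 8 sites: fast unit-test geometry."""
    return CortexGeometry.tiny()


@pytest.fixture(scope="session")
def reduced_geometry():
    return CortexGeometry.reduced()


@pytest.fixture(scope="session")
def tiny_single_table(tiny_geometry, rf_params):
    return build_response_table(single_orientation_ensemble(90.0),
                                tiny_geometry.lgn, rf_params)


@pytest.fixture(scope="session")
def tiny_twelve_table(tiny_geometry, rf_params):
    return build_response_table(twelve_orientation_ensemble(),
                                tiny_geometry.lgn, rf_params)


@pytest.fixture
def tiny_sim(tiny_geometry, tiny_twelve_table):
    return Simulation(tiny_geometry, tiny_twelve_table, seed=7)


@pytest.fixture(scope="session")
def model_config():
    return ModelConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
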
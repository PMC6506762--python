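import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from leafkin.boundary_layer import PoreGeometry
from leafkin.synthetic import Protocol, simulate_experiment, simulate_replica


@pytest.fixture(scope="session")
def short_protocol():
    """Compressed dark/light/dark schedule for fast end-to-end tests."""
    return Protocol(durations=(120.0, 600.0, 600.0), seed=5)


@pytest.fixture(scope="session")
def short_experiment(short_protocol):
    return simulate_experiment(short_protocol)


@pytest.fixture(scope="session")
def replica_geometry():
    """Nominal replica membrane geometry: 0.5 mm pores, 40 µm deep,
    160 per square inch."""
    return PoreGeometry.from_inch_density(0.5e-3, 40e-6, 160.0)


@pytest.fixture(scope="session")
def short_replica(short_protocol, replica_geometry):
    return simulate_replica(short_protocol, replica_geometry)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
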
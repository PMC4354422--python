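import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chondrosim.parameters import (
    DomainConfig,
    ModelParams,
    NumericsConfig,
    default_params,
)
from chondrosim.simulator import make_grids, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return default_params()


@pytest.fixture(scope="session")
def domain() -> DomainConfig:
    return DomainConfig()


@pytest.fixture(scope="session")
def numerics() -> NumericsConfig:
    return NumericsConfig()


@pytest.fixture(scope="session")
def baseline(params, domain, numerics):
    """The full 14-day baseline run at the default resolution, shared by
    the conservation, threshold and qualitative-dynamics tests."""
    traj = simulate(params, domain, numerics)
    grids = make_grids(domain, numerics)
    return traj, grids


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240214)
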
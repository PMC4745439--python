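import numpy as np
import pytest

from stenoflow import FlowConditions, FluidParams, GeometryParams


@pytest.fixture
def default_fluid():
    return FluidParams(N=0.75, m=50.0)


@pytest.fixture
def default_flow():
    return FlowConditions(Q=1.0, u=0.01)


@pytest.fixture
def nontapered_geom():
    return GeometryParams(zeta=0.0, eps=0.1, gamma=0.5, Gamma=0.5, rc=0.1)


@pytest.fixture
def converging_geom():
    return GeometryParams.from_taper_angle(-0.05, eps=0.1, gamma=0.5,
                                           Gamma=0.5, rc=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_station(rng):
    """An admissible (h, rc, fluid) triple for property tests."""
    h = rng.uniform(0.6, 1.1)
    rc = rng.uniform(0.03, 0.45) * h
    fluid = FluidParams(N=rng.uniform(0.02, 0.95), m=rng.uniform(1.5, 90.0))
    return h, rc, fluid
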
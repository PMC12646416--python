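import numpy as np
import pytest

from nichebranch.core import (
    CommunityState,
    EcomorphState,
    Model1Params,
    ResourceState,
)
from nichebranch.equilibrium import find_equilibrium
from nichebranch.scenarios import default_params


@pytest.fixture(scope="session")
def two_resource_params() -> Model1Params:
    """Calibrated two-resource landscape: theta = (1, 2), D/tau = 2.86."""
    return default_params(n=2)


@pytest.fixture(scope="session")
def simple_params() -> Model1Params:
    """Small hand-set parameter values for closed-form rate checks."""
    return Model1Params(
        n=2, theta=np.array([1.0, 2.0]), D=1.0, tau=0.3, rho=0.1,
        F_max=np.array([10.0, 10.0]), alpha=0.5, gamma=0.6, epsilon=0.5,
        nu=0.1, w=10.0, delta_max=0.1, delta_A=0.02,
    )


def make_resident(eta: float, ell: float, inoculum: float = 1e-3) -> CommunityState:
    return CommunityState(
        ecomorphs=[EcomorphState(id=0, lineage_id=0, eta=eta, ell=ell,
                                 J=inoculum, A=inoculum)],
        resources=None,
    )


def resident_equilibrium(eta: float, ell: float, params: Model1Params,
                         **kwargs):
    community = CommunityState(
        ecomorphs=[EcomorphState(id=0, lineage_id=0, eta=eta, ell=ell,
                                 J=1e-3, A=1e-3)],
        resources=ResourceState(params.F_max.copy()),
    )
    return find_equilibrium(community, params, **kwargs)


@pytest.fixture(scope="session")
def midpoint_equilibrium(two_resource_params):
    """Single resident at the midpoint singular niche trait, near-optimal ell."""
    return resident_equilibrium(1.5, 1.7476, two_resource_params)
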
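"""Standard resource landscapes and initial communities.

The default organismal parameter set was calibrated once so that, on the
two-resource landscape, the coupled run reproduces the canonical
diversification sequence: a colonizer at (eta, ell) = (1.3, 1) first
specializes on the nearer resource, offspring size then evolves toward its
optimum, the niche trait crosses to the midpoint between the resource
optima, and the population branches there; with offspring size held fixed
the colonizer remains a single specialist.  See docs/methods.md for the
calibration rationale.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .core import CommunityState, EcomorphState, Model1Params, ResourceState

__all__ = ["default_params", "generate_scenario"]

#: Calibrated organismal defaults (shared by all presets).
ORGANISMAL_DEFAULTS = dict(
    tau=0.35,        # niche breadth (trait units); D/tau = 2.86 > 2
    rho=0.1,         # resource renewal rate (per unit time)
    alpha=3.0,       # maximum attack rate (volume per unit time)
    gamma=0.7,       # juvenile feeding scale
    epsilon=0.5,     # assimilation efficiency
    nu=0.05,         # metabolic maintenance cost (per unit time)
    w=30.0,          # maturation size (mass)
    delta_max=1.4,   # juvenile mortality scale (per unit time)
    delta_A=0.3,     # adult mortality (per unit time)
)

#: Carrying capacity per resource (mass / volume); with rho = 0.1 and ten
#: resources this makes the total productivity exactly 2.
F_MAX_PER_RESOURCE = 2.0


def default_params(n: int = 2, D: float = 1.0, theta1: float = 1.0,
                   F_max_each: float = F_MAX_PER_RESOURCE,
                   **overrides) -> Model1Params:
    """Equally spaced landscape of ``n`` resources with calibrated organismal defaults."""
    kw = dict(ORGANISMAL_DEFAULTS)
    kw.update(overrides)
    theta = theta1 + D * np.arange(n)
    return Model1Params(n=n, theta=theta, D=D,
                        F_max=np.full(n, float(F_max_each)), **kw)


def generate_scenario(kind: str, **knobs) -> tuple[Model1Params, CommunityState]:
    """Build a named scenario: parameters plus the initial community.

    Kinds
    -----
    two_resource
        Resources at theta = (1, 2); one colonizing lineage at
        eta = 1.3, ell = 1 (knobs: eta0, ell0, inoculum, plus any
        Model1Params override).
    ten_resource
        Resources at theta = 1..10 (total productivity 2); two lineages
        seeded at the extremes eta = 0.8 and 10.2, both with ell = 1.
    custom
        Explicit n, D, theta1 and overrides; single colonizer unless
        seeds=[(eta, ell), ...] is given.
    """
    inoculum = float(knobs.pop("inoculum", 0.01))
    if kind == "two_resource":
        eta0 = float(knobs.pop("eta0", 1.3))
        ell0 = float(knobs.pop("ell0", 1.0))
        params = default_params(n=2, **knobs)
        seeds = [(eta0, ell0)]
    elif kind == "ten_resource":
        params = default_params(n=10, **knobs)
        seeds = [(0.8, 1.0), (10.2, 1.0)]
    elif kind == "custom":
        seeds = knobs.pop("seeds", None)
        n = int(knobs.pop("n", 2))
        params = default_params(n=n, **knobs)
        if seeds is None:
            mid = 0.5 * (params.theta[0] + params.theta[-1])
            seeds = [(mid, 1.0)]
    else:
        raise ValueError(f"unknown scenario kind: {kind!r}")

    ecomorphs = [
        EcomorphState(id=i, lineage_id=i, eta=float(eta), ell=float(ell),
                      J=inoculum, A=inoculum)
        for i, (eta, ell) in enumerate(seeds)
    ]
    community = CommunityState(ecomorphs=ecomorphs,
                               resources=ResourceState(params.F_max.copy()))
    return params, community
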
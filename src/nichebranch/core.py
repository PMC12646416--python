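"""Stage-structured consumer-resource model: rate functions and ODE right-hand side.

The model describes ``m`` consumer ecomorphs, each split into juveniles and
adults, competing for ``n`` substitutable food resources arranged along a
one-dimensional niche axis.  An ecomorph is characterised by two heritable
traits: a feeding-niche trait ``eta`` that sets its Gaussian attack-rate
profile over the resources, and an offspring size ``ell`` that trades
offspring number against juvenile survival.

All functions here are pure and deterministic; densities and rates are
treated as dimensionally consistent but unit-opaque (resource densities in
mass per volume, time in model time units).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Model1Params",
    "ResourceState",
    "EcomorphState",
    "CommunityState",
    "attack_rate",
    "attack_profile",
    "feeding_rates",
    "growth_flux",
    "juvenile_mortality",
    "maturation_rate",
    "birth_rate",
    "community_rhs",
    "pack_state",
    "unpack_state",
    "rhs_flat",
]

# Relative half-width of the band around phi = delta_J inside which the
# maturation rate switches to its analytic limit (the raw expression is 0/0).
_MATURATION_SINGULAR_BAND = 1e-7


@dataclass(frozen=True)
class Model1Params:
    """All ecological and organismal constants plus the resource landscape.

    Parameters
    ----------
    n : int
        Number of food resources (>= 1).
    theta : ndarray
        Optimal niche-trait values ``theta_i``, strictly increasing and
        equally spaced by ``D``.
    D : float
        Spacing between adjacent resource optima (> 0 when n >= 2).
    tau : float
        Width of the Gaussian attack-rate kernel (niche breadth).
    rho : float
        Resource renewal rate (per time).
    F_max : ndarray
        Resource carrying capacities (mass / volume), all > 0.
    alpha : float
        Maximum attack rate (volume / time per individual).
    gamma : float
        Juvenile feeding scale, 0 < gamma < 1.
    epsilon : float
        Assimilation efficiency, 0 < epsilon <= 1.
    nu : float
        Metabolic maintenance cost (per time).
    w : float
        Body size at maturation (mass); offspring size must stay below it.
    delta_max : float
        Juvenile mortality scale: mortality at offspring size zero.
    delta_A : float
        Adult mortality rate (per time).
    """

    n: int
    theta: np.ndarray
    D: float
    tau: float
    rho: float
    F_max: np.ndarray
    alpha: float
    gamma: float
    epsilon: float
    nu: float
    w: float
    delta_max: float
    delta_A: float

    def __post_init__(self) -> None:
        theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        F_max = np.atleast_1d(np.asarray(self.F_max, dtype=float))
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "F_max", F_max)
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if theta.shape != (self.n,):
            raise ValueError(f"theta must have length n={self.n}")
        if F_max.shape != (self.n,):
            raise ValueError(f"F_max must have length n={self.n}")
        if self.n >= 2:
            diffs = np.diff(theta)
            if np.any(diffs <= 0):
                raise ValueError("theta must be strictly increasing")
            scale = max(abs(self.D), 1e-300)
            if np.any(np.abs(diffs - self.D) > 1e-12 * scale):
                raise ValueError("theta spacing must equal D (constant spacing)")
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must satisfy 0 < gamma < 1")
        if not (0.0 < self.epsilon <= 1.0):
            raise ValueError("epsilon must satisfy 0 < epsilon <= 1")
        for name in ("rho", "alpha", "nu", "w", "delta_max", "delta_A", "tau"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")
        if np.any(F_max <= 0.0):
            raise ValueError("F_max entries must be strictly positive")

    def with_productivity(self, P: float) -> "Model1Params":
        """Rescale all carrying capacities so total productivity rho*sum(F_max) = P."""
        current = self.rho * float(np.sum(self.F_max))
        if P <= 0:
            raise ValueError("productivity must be positive")
        return replace(self, F_max=self.F_max * (P / current))


@dataclass
class ResourceState:
    """Densities of the n food resources."""

    F: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.atleast_1d(np.asarray(self.F, dtype=float))
        if np.any(self.F < 0):
            raise ValueError("resource densities must be non-negative")

    def copy(self) -> "ResourceState":
        return ResourceState(self.F.copy())


@dataclass
class EcomorphState:
    """One consumer ecomorph: its traits, stage densities and lineage bookkeeping."""

    id: int
    lineage_id: int
    eta: float
    ell: float
    J: float
    A: float
    parent_id: Optional[int] = None

    @property
    def N(self) -> float:
        """Total density J + A."""
        return self.J + self.A

    @property
    def C(self) -> float:
        """Fraction of adults A / N (defined only for N > 0)."""
        N = self.N
        if N <= 0:
            raise ValueError("C undefined for N = 0")
        return self.A / N

    def copy(self) -> "EcomorphState":
        return EcomorphState(
            id=self.id, lineage_id=self.lineage_id, eta=self.eta,
            ell=self.ell, J=self.J, A=self.A, parent_id=self.parent_id,
        )


@dataclass
class CommunityState:
    """Resident community: ecomorphs plus the resource vector at ecological time t."""

    ecomorphs: list[EcomorphState]
    resources: ResourceState
    t: float = 0.0

    def __post_init__(self) -> None:
        ids = [e.id for e in self.ecomorphs]
        if len(ids) != len(set(ids)):
            raise ValueError("ecomorph ids must be unique")

    @property
    def m(self) -> int:
        return len(self.ecomorphs)

    def copy(self) -> "CommunityState":
        return CommunityState(
            ecomorphs=[e.copy() for e in self.ecomorphs],
            resources=self.resources.copy(),
            t=self.t,
        )


def attack_rate(eta: float, theta_i, params: Model1Params):
    """Gaussian attack rate of a consumer with niche trait ``eta`` on resource optimum ``theta_i``.

    Peaks at ``alpha`` when eta == theta_i and decays with Gaussian width ``tau``.
    """
    d = np.asarray(eta, dtype=float) - np.asarray(theta_i, dtype=float)
    return params.alpha * np.exp(-(d * d) / (2.0 * params.tau * params.tau))


def attack_profile(eta: float, params: Model1Params) -> np.ndarray:
    """Vector of attack rates on all n resources for niche trait ``eta``."""
    return attack_rate(eta, params.theta, params)


def feeding_rates(eta: float, F, params: Model1Params) -> tuple[float, float]:
    """Juvenile and adult per-capita intake rates (c_J, c_A) given resource densities.

    Adults take ``c_A = sum_i a_i(eta) F_i``; juveniles feed at the
    gamma-scaled rate ``c_J = gamma * c_A`` (smaller bodies forage less).
    """
    Fv = F.F if isinstance(F, ResourceState) else np.asarray(F, dtype=float)
    c_A = float(np.dot(attack_profile(eta, params), Fv))
    return params.gamma * c_A, c_A


def growth_flux(c_J: float, params: Model1Params) -> float:
    """Energy flux to juvenile somatic growth: assimilated intake net of maintenance, floored at zero."""
    return max(params.epsilon * c_J - params.nu, 0.0)


def juvenile_mortality(ell: float, params: Model1Params) -> float:
    """Juvenile mortality rate, declining exponentially with offspring size."""
    return params.delta_max * np.exp(-ell)


def maturation_rate(phi: float, delta_J: float, ell: float, params: Model1Params) -> float:
    """Stage-transfer rate from juveniles to adults.

    Follows the juvenile cohort through its growth from size ``ell`` to
    maturation size ``w`` under mortality ``delta_J``:

        Phi = (phi - delta_J) / (1 - (ell/w)**(1 - delta_J/phi))   for phi > delta_J

    and 0 when growth cannot outpace mortality.  At phi == delta_J the
    expression is 0/0 with limit ``delta_J / ln(w/ell)``; a narrow relative
    band around that point returns the limit to avoid catastrophic
    cancellation.
    """
    if not (0.0 < ell < params.w):
        raise ValueError("maturation requires 0 < ell < w")
    if phi <= 0.0:
        return 0.0
    log_ratio = np.log(ell / params.w)  # negative
    if delta_J > 0.0 and abs(phi / delta_J - 1.0) < _MATURATION_SINGULAR_BAND:
        return -delta_J / log_ratio
    if phi <= delta_J:
        return 0.0
    expo = 1.0 - delta_J / phi
    return (phi - delta_J) / (1.0 - np.exp(expo * log_ratio))


def birth_rate(c_A: float, ell: float, params: Model1Params) -> float:
    """Adult per-capita birth rate: net assimilated energy divided by offspring size.

    The 1/ell factor is the offspring size-number tradeoff; starving adults
    (epsilon*c_A <= nu) do not reproduce.
    """
    if ell <= 0:
        raise ValueError("offspring size must be positive")
    return max(params.epsilon * c_A - params.nu, 0.0) / ell


def ecomorph_rates(eta: float, ell: float, F, params: Model1Params) -> dict:
    """All per-capita rates of a phenotype (eta, ell) in resource environment F."""
    c_J, c_A = feeding_rates(eta, F, params)
    phi = growth_flux(c_J, params)
    dJ = juvenile_mortality(ell, params)
    Phi = maturation_rate(phi, dJ, ell, params)
    beta = birth_rate(c_A, ell, params)
    return {"c_J": c_J, "c_A": c_A, "phi": phi, "delta_J": dJ, "Phi": Phi, "beta": beta}


def community_rhs(state: CommunityState, params: Model1Params):
    """Time derivatives (dJ, dA, dF) of the full ecological system.

    Resources renew logistically-forced toward F_max at rate rho and are
    consumed by all ecomorphs (juveniles at the gamma-scaled rate); juveniles
    are produced by births, mature at rate Phi and die at delta_J; adults are
    recruited by maturation and die at delta_A.
    """
    m = state.m
    F = state.resources.F
    dJ = np.zeros(m)
    dA = np.zeros(m)
    consumption = np.zeros(params.n)
    for k, e in enumerate(state.ecomorphs):
        a = attack_profile(e.eta, params)
        r = ecomorph_rates(e.eta, e.ell, F, params)
        dJ[k] = r["beta"] * e.A - r["Phi"] * e.J - r["delta_J"] * e.J
        dA[k] = r["Phi"] * e.J - params.delta_A * e.A
        consumption += a * F * (params.gamma * e.J + e.A)
    dF = params.rho * (params.F_max - F) - consumption
    return dJ, dA, dF


# --- flat-vector plumbing for ODE solvers -----------------------------------
# Packing order: [J_1..J_m, A_1..A_m, F_1..F_n].

def pack_state(state: CommunityState) -> np.ndarray:
    J = np.array([e.J for e in state.ecomorphs])
    A = np.array([e.A for e in state.ecomorphs])
    return np.concatenate([J, A, state.resources.F])


def unpack_state(y: np.ndarray, template: CommunityState) -> CommunityState:
    m = template.m
    out = template.copy()
    for k, e in enumerate(out.ecomorphs):
        e.J = max(float(y[k]), 0.0)
        e.A = max(float(y[m + k]), 0.0)
    out.resources.F = np.maximum(np.asarray(y[2 * m:], dtype=float), 0.0)
    return out


def rhs_flat(y: np.ndarray, etas: np.ndarray, ells: np.ndarray, params: Model1Params) -> np.ndarray:
    """Flat RHS for solve_ivp / Newton: traits passed as arrays, state as [J, A, F]."""
    m = len(etas)
    J = y[:m]
    A = y[m:2 * m]
    F = y[2 * m:]
    dJ = np.empty(m)
    dA = np.empty(m)
    consumption = np.zeros(params.n)
    for k in range(m):
        a = attack_profile(etas[k], params)
        c_A = float(np.dot(a, F))
        c_J = params.gamma * c_A
        phi = growth_flux(c_J, params)
        dJm = juvenile_mortality(ells[k], params)
        Phi = maturation_rate(phi, dJm, ells[k], params)
        beta = birth_rate(c_A, ells[k], params)
        dJ[k] = beta * A[k] - Phi * J[k] - dJm * J[k]
        dA[k] = Phi * J[k] - params.delta_A * A[k]
        consumption += a * F * (params.gamma * J[k] + A[k])
    dF = params.rho * (params.F_max - F) - consumption
    return np.concatenate([dJ, dA, dF])
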
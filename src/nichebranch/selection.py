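"""Invasion fitness, selection gradients, curvature and the diversification conditions.

Invasion fitness of a rare mutant phenotype (eta_m, ell_m) is the dominant
eigenvalue of its juvenile/adult stage matrix evaluated in the fixed resource
environment set by the resident community at its ecological equilibrium.
Gradients and curvature are obtained by Richardson-extrapolated central
differences; the eigenvalue is smooth and cheap, and equilibrium noise is
controlled by the tight solver tolerances.

Two analytic diversification conditions are exposed:

* mutual invasibility at the midpoint singular strategy requires the
  resource spacing-to-niche-width ratio D/tau > 2;
* convergence stability of that strategy requires total productivity above
  P_min = rho * G * D^2 * exp(D^2/(8 tau^2)) / (4 * E * tau^2 * alpha),
  with E and G evaluated at the singular resident's equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .core import (
    CommunityState,
    EcomorphState,
    Model1Params,
    ResourceState,
    birth_rate,
    feeding_rates,
    growth_flux,
    juvenile_mortality,
    maturation_rate,
)
from .equilibrium import EquilibriumResult, find_equilibrium

__all__ = [
    "SelectionReport",
    "invasion_fitness",
    "selection_gradient",
    "fitness_curvature",
    "classify_selection",
    "convergence_stable",
    "condition1_ratio",
    "productivity_threshold",
]

Regime = Literal["directional", "stabilizing", "disruptive"]

# Relative finite-difference steps (one Richardson level on top).
H_ETA = 1e-5
H_ELL = 1e-5


@dataclass
class SelectionReport:
    """Per-ecomorph local selection analysis at a resident equilibrium."""

    gradient_eta: float
    gradient_ell: float
    curvature_eta: Optional[float]
    regime: Optional[Regime]
    convergence_stable: Optional[bool]
    h_eta: float
    h_ell: float


def invasion_fitness(eta_m: float, ell_m: float, F, params: Model1Params) -> float:
    """Long-term per-capita growth rate of a rare mutant in environment F.

    The mutant's juvenile/adult dynamics at fixed resources are linear with
    stage matrix [[-(Phi+delta_J), beta], [Phi, -delta_A]]; the invasion
    fitness is its dominant eigenvalue

        lambda = 0.5 * [-(Phi+delta_J+delta_A) + sqrt((Phi+delta_J-delta_A)^2 + 4 beta Phi)]

    whose sign agrees with sign(R0 - 1), R0 = beta*Phi / (delta_A*(Phi+delta_J)).
    """
    if not (0.0 < ell_m < params.w):
        raise ValueError("mutant offspring size must lie in (0, w)")
    c_J, c_A = feeding_rates(eta_m, F, params)
    phi = growth_flux(c_J, params)
    dJ = juvenile_mortality(ell_m, params)
    Phi = maturation_rate(phi, dJ, ell_m, params)
    beta = birth_rate(c_A, ell_m, params)
    p = Phi + dJ
    disc = (p - params.delta_A) ** 2 + 4.0 * beta * Phi
    return 0.5 * (-(p + params.delta_A) + np.sqrt(disc))


def _richardson_gradient(f, x: float, h: float) -> float:
    """Central difference with one Richardson level: O(h^4)."""
    g = lambda hh: (f(x + hh) - f(x - hh)) / (2.0 * hh)
    return (4.0 * g(h / 2.0) - g(h)) / 3.0


def _richardson_curvature(f, x: float, h: float) -> float:
    f0 = f(x)
    c = lambda hh: (f(x + hh) - 2.0 * f0 + f(x - hh)) / (hh * hh)
    return (4.0 * c(h / 2.0) - c(h)) / 3.0


def selection_gradient(j: int, eq: EquilibriumResult, params: Model1Params) -> tuple[float, float]:
    """Selection gradients (d lambda/d eta_m, d lambda/d ell_m) for ecomorph j.

    Partial derivatives of invasion fitness with respect to the mutant
    traits, evaluated at the resident's own trait values in the resident
    equilibrium environment.
    """
    e = eq.community.ecomorphs[j]
    F = eq.F_star
    h_eta = H_ETA * max(1.0, abs(e.eta))
    h_ell = H_ELL * max(1.0, abs(e.ell))
    g_eta = _richardson_gradient(lambda x: invasion_fitness(x, e.ell, F, params), e.eta, h_eta)
    g_ell = _richardson_gradient(lambda x: invasion_fitness(e.eta, x, F, params), e.ell, h_ell)
    return g_eta, g_ell


def fitness_curvature(j: int, eq: EquilibriumResult, params: Model1Params) -> float:
    """Second derivative of invasion fitness in the mutant niche trait at the resident value."""
    e = eq.community.ecomorphs[j]
    F = eq.F_star
    h_eta = 10.0 * H_ETA * max(1.0, abs(e.eta))
    return _richardson_curvature(lambda x: invasion_fitness(x, e.ell, F, params), e.eta, h_eta)


def classify_selection(gradient_eta: float, curvature_eta: float,
                       cessation_threshold: float) -> Regime:
    """Directional while the niche gradient is above threshold, otherwise
    disruptive/stabilizing by the sign of the curvature."""
    if abs(gradient_eta) >= cessation_threshold:
        return "directional"
    return "disruptive" if curvature_eta > 0 else "stabilizing"


def _resident_equilibrium(eta: float, ell: float, params: Model1Params,
                          inoculum: float = 1e-3, **kwargs) -> EquilibriumResult:
    community = CommunityState(
        ecomorphs=[EcomorphState(id=0, lineage_id=0, eta=eta, ell=ell,
                                 J=inoculum, A=inoculum)],
        resources=ResourceState(params.F_max.copy()),
    )
    return find_equilibrium(community, params, **kwargs)


def convergence_stable(eta_star: float, ell: float, params: Model1Params,
                       h: float = 1e-4, **eq_kwargs) -> bool:
    """Whether the singular niche trait eta_star is an evolutionary attractor.

    Re-solves the single-resident equilibrium at eta_star +/- h and
    differences the niche selection gradients: the singular point is
    convergence stable iff d g_eta / d eta_resident < 0.
    """
    slopes = []
    for s in (+1.0, -1.0):
        eq = _resident_equilibrium(eta_star + s * h, ell, params, **eq_kwargs)
        if eq.community.m == 0:
            raise RuntimeError("resident went extinct while probing convergence stability")
        g_eta, _ = selection_gradient(0, eq, params)
        slopes.append(g_eta)
    return (slopes[0] - slopes[1]) / (2.0 * h) < 0.0


def condition1_ratio(params: Model1Params) -> tuple[float, bool]:
    """Mutual-invasibility condition: the midpoint strategy is a fitness
    minimum iff the spacing-to-width ratio D/tau exceeds 2 (strict)."""
    if params.n < 2:
        raise ValueError("mutual invasibility is undefined for a single resource")
    ratio = params.D / params.tau
    return ratio, ratio > 2.0


def productivity_threshold(E: float, G: float, params: Model1Params) -> float:
    """Minimum total productivity for the midpoint singular strategy to be
    an evolutionary attractor:

        P_min = rho * G * D^2 * exp(D^2 / (8 tau^2)) / (4 * E * tau^2 * alpha)

    Decreasing in E (stronger birth-rate scaling) and increasing in G
    (faster biomass loss); vanishes as the resource spacing D -> 0.
    """
    if E <= 0:
        raise ValueError("E must be positive")
    if G <= 0:
        raise ValueError("G must be positive")
    D, tau = params.D, params.tau
    return (params.rho * G * D * D * np.exp(D * D / (8.0 * tau * tau))
            / (4.0 * E * tau * tau * params.alpha))


def analyze_ecomorph(j: int, eq: EquilibriumResult, params: Model1Params,
                     cessation_threshold: float = 1e-8,
                     with_convergence: bool = False) -> SelectionReport:
    """Full local selection report for ecomorph j at a converged equilibrium."""
    e = eq.community.ecomorphs[j]
    g_eta, g_ell = selection_gradient(j, eq, params)
    curv = fitness_curvature(j, eq, params)
    regime = classify_selection(g_eta, curv, cessation_threshold)
    conv = None
    if with_convergence and regime != "directional":
        conv = convergence_stable(e.eta, e.ell, params)
    return SelectionReport(
        gradient_eta=g_eta, gradient_ell=g_ell, curvature_eta=curv,
        regime=regime, convergence_stable=conv,
        h_eta=H_ETA * max(1.0, abs(e.eta)), h_ell=H_ELL * max(1.0, abs(e.ell)))
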
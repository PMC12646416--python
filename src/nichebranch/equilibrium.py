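"""Ecological steady states of a resident community.

The equilibrium of the coupled consumer-resource ODE system is found by
forward integration until transients decay, interleaved with cheap Newton
polish attempts on the algebraic system; a Newton solution is only accepted
if it is locally stable (the returned state must be the attractor reached
from the supplied initial state, not an unstable interior focus).
Equilibria feed numerical differentiation of invasion fitness, so the
polish tolerance is tight by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .core import (
    CommunityState,
    EcomorphState,
    Model1Params,
    ResourceState,
    ecomorph_rates,
    pack_state,
    rhs_flat,
)

__all__ = [
    "EquilibriumError",
    "NonConvergence",
    "OscillationDetected",
    "EquilibriumResult",
    "find_equilibrium",
    "compound_EG",
    "total_productivity",
]


class EquilibriumError(RuntimeError):
    """Base class for equilibrium-solver failures."""


class NonConvergence(EquilibriumError):
    """t_max reached with the RHS residual still above tolerance."""


class OscillationDetected(EquilibriumError):
    """Persistent cycling or sliding: the residual stagnates while the
    state keeps moving (reported, never silently averaged)."""


@dataclass
class EquilibriumResult:
    """A community's ecological steady state and derived per-ecomorph summaries.

    Attributes
    ----------
    community : CommunityState
        The state at (numerical) steady state; only viable ecomorphs remain.
    residual : float
        Max absolute component of the ODE right-hand side at the returned state.
    converged : bool
    F_star : ndarray
        Equilibrium resource densities.
    N_star, C_star, E, G : ndarray
        Per retained ecomorph: total density, adult fraction, birth-rate
        scaling factor E = eps*C/ell and biomass-loss rate
        G = nu*C/ell + delta_A*C + delta_J(ell)*(1-C).
    viable : ndarray of bool
        Starvation-free flags of retained ecomorphs (all True on success).
    removed : list[EcomorphState]
        Ecomorphs culled during the solve (extinct or starving).
    """

    community: CommunityState
    residual: float
    converged: bool
    F_star: np.ndarray
    N_star: np.ndarray
    C_star: np.ndarray
    E: np.ndarray
    G: np.ndarray
    viable: np.ndarray
    removed: list = field(default_factory=list)


def total_productivity(params: Model1Params) -> float:
    """Total resource productivity P = rho * sum_i F_i^max (mass/volume/time)."""
    return params.rho * float(np.sum(params.F_max))


def _is_viable(e: EcomorphState, F: np.ndarray, params: Model1Params,
               extinction_threshold: float) -> bool:
    if e.N <= extinction_threshold:
        return False
    r = ecomorph_rates(e.eta, e.ell, F, params)
    return (params.epsilon * r["c_J"] > params.nu
            and params.epsilon * r["c_A"] > params.nu)


def _summaries(community: CommunityState, params: Model1Params,
               extinction_threshold: float):
    F = community.resources.F
    m = community.m
    N = np.empty(m)
    C = np.empty(m)
    E = np.empty(m)
    G = np.empty(m)
    viable = np.empty(m, dtype=bool)
    for k, e in enumerate(community.ecomorphs):
        N[k] = e.N
        C[k] = e.A / e.N if e.N > 0 else np.nan
        dJ = params.delta_max * np.exp(-e.ell)
        E[k] = params.epsilon * C[k] / e.ell
        G[k] = params.nu * C[k] / e.ell + params.delta_A * C[k] + dJ * (1.0 - C[k])
        viable[k] = _is_viable(e, F, params, extinction_threshold)
    return N, C, E, G, viable


def compound_EG(eq: EquilibriumResult, params: Model1Params) -> tuple[np.ndarray, np.ndarray]:
    """Per-ecomorph compound variables (E, G) at equilibrium.

    E = eps*C*/ell scales the population birth rate; G is the per-capita
    biomass-loss rate through maintenance and stage-specific mortality.
    Both enter the productivity threshold for convergence stability.
    """
    if not eq.converged:
        raise EquilibriumError("compound variables require a converged equilibrium")
    return eq.E.copy(), eq.G.copy()


def _jacobian(y, etas, ells, params, h=1e-7):
    d = len(y)
    J = np.empty((d, d))
    f0 = rhs_flat(y, etas, ells, params)
    for i in range(d):
        step = h * max(1.0, abs(y[i]))
        yp = y.copy()
        yp[i] += step
        J[:, i] = (rhs_flat(yp, etas, ells, params) - f0) / step
    return J


def _is_stable(y, etas, ells, params, tol=1e-6) -> bool:
    if len(y) == 0:
        return True
    lam = np.linalg.eigvals(_jacobian(y, etas, ells, params))
    return float(np.max(lam.real)) < tol


def _try_newton(y0, etas, ells, params, newton_tol, extinction_threshold):
    """Newton polish; returns polished y or None if it fails, leaves the
    positive cone, or lands on an unstable (non-attracting) root."""
    fun = lambda y: rhs_flat(y, etas, ells, params)
    sol = root(fun, y0, method="hybr")
    y = sol.x
    if not sol.success:
        return None
    res = float(np.max(np.abs(fun(y))))
    if res > newton_tol:
        return None
    m = len(etas)
    if np.any(y < -1e-10):
        return None
    # Newton must not manufacture density for an ecomorph that integration
    # found (near-)extinct.
    N0 = y0[:m] + y0[m:2 * m]
    N1 = y[:m] + y[m:2 * m]
    if np.any((N0 < 10 * extinction_threshold) & (N1 > 10 * extinction_threshold)):
        return None
    y = np.maximum(y, 0.0)
    if not _is_stable(y, etas, ells, params):
        return None
    return y


def find_equilibrium(
    initial: CommunityState,
    params: Model1Params,
    tol: float = 1e-9,
    t_max: float = 1e6,
    newton_tol: float = 1e-12,
    extinction_threshold: float = 1e-9,
) -> EquilibriumResult:
    """Solve for the ecological attractor reached from ``initial``.

    Forward-integrates the ODE system in bounded chunks, culling ecomorphs
    whose total density falls below ``extinction_threshold`` (the solve is
    restarted without them), and attempts a Newton polish after every chunk.
    Starving ecomorphs at the polished state are likewise removed and the
    solve restarted.

    Raises
    ------
    NonConvergence
        If ``t_max`` is exhausted (or progress stalls) with the residual
        above ``tol``.
    OscillationDetected
        If the residual stagnates while the state keeps moving (persistent
        cycling, or chattering on the maturation threshold).
    """
    community = initial.copy()
    removed: list[EcomorphState] = []

    while True:  # restart loop after culling
        etas = np.array([e.eta for e in community.ecomorphs])
        ells = np.array([e.ell for e in community.ecomorphs])
        m = len(etas)

        if m == 0:
            community = CommunityState(
                ecomorphs=[], resources=ResourceState(params.F_max.copy()), t=community.t)
            N, C, E, G, viable = _summaries(community, params, extinction_threshold)
            return EquilibriumResult(
                community=community, residual=0.0, converged=True,
                F_star=community.resources.F.copy(),
                N_star=N, C_star=C, E=E, G=G, viable=viable, removed=removed)

        fun = lambda t, y: rhs_flat(y, etas, ells, params)
        y = pack_state(community)

        # warm starts land directly in the Newton basin
        y_pol = _try_newton(y, etas, ells, params, newton_tol, extinction_threshold)
        if y_pol is not None:
            culled = _apply(community, y_pol, params, extinction_threshold, removed)
            if culled:
                continue
            return _finalize(community, params, extinction_threshold, removed)

        t = 0.0
        chunk = 50.0
        residual_hist: list[float] = []
        state_hist: list[np.ndarray] = []
        culled_restart = False
        while t < t_max:
            sol = solve_ivp(fun, (t, t + chunk), y, method="LSODA",
                            rtol=1e-8, atol=1e-10)
            if not sol.success:
                raise NonConvergence(f"integrator failed at t={t}: {sol.message}")
            y = np.maximum(sol.y[:, -1], 0.0)
            t = sol.t[-1]
            residual = float(np.max(np.abs(fun(t, y))))
            residual_hist.append(residual)
            state_hist.append(y.copy())

            N_now = y[:m] + y[m:2 * m]
            if np.any(N_now < extinction_threshold):
                _apply(community, y, params, extinction_threshold, removed, cull_only=True)
                culled_restart = True
                break

            y_pol = _try_newton(y, etas, ells, params, newton_tol, extinction_threshold)
            if y_pol is not None:
                culled = _apply(community, y_pol, params, extinction_threshold, removed)
                if culled:
                    culled_restart = True
                    break
                return _finalize(community, params, extinction_threshold, removed)
            if residual < tol:
                _apply(community, y, params, extinction_threshold, removed)
                return _finalize(community, params, extinction_threshold, removed)

            # stagnation guard: no order-of-magnitude progress over the last
            # 12 chunks and Newton keeps failing -> cycling or sliding mode
            if len(residual_hist) >= 12:
                recent = residual_hist[-12:]
                if recent[-1] > 0.3 * max(recent):
                    states = np.array(state_hist[-12:])
                    moving = float(np.max(np.std(states, axis=0)))
                    if moving > 100 * tol:
                        raise OscillationDetected(
                            f"residual stagnated at {recent[-1]:.3e} with state "
                            f"still moving (spread {moving:.3e}) at t={t:.1f}")
                    raise NonConvergence(
                        f"progress stalled at residual {recent[-1]:.3e} at t={t:.1f}")
            chunk = min(chunk * 1.5, 2000.0)

        if culled_restart:
            continue
        raise NonConvergence(
            f"t_max={t_max} reached with residual {residual_hist[-1]:.3e} > tol={tol}")


def _apply(community, y, params, extinction_threshold, removed, cull_only=False) -> bool:
    """Write y back into community; cull extinct (and, post-polish, starving)
    ecomorphs.  Returns True if anything was culled (caller restarts)."""
    m = community.m
    for k, e in enumerate(community.ecomorphs):
        e.J = max(float(y[k]), 0.0)
        e.A = max(float(y[m + k]), 0.0)
    community.resources.F = np.maximum(np.asarray(y[2 * m:], dtype=float), 0.0)

    doomed = []
    for e in community.ecomorphs:
        if e.N < extinction_threshold:
            doomed.append(e)
        elif not cull_only and not _is_viable(e, community.resources.F, params,
                                              extinction_threshold):
            doomed.append(e)
    for e in doomed:
        removed.append(e.copy())
        community.ecomorphs.remove(e)
    return bool(doomed)


def _finalize(community, params, extinction_threshold, removed):
    etas = np.array([e.eta for e in community.ecomorphs])
    ells = np.array([e.ell for e in community.ecomorphs])
    y = pack_state(community)
    residual = float(np.max(np.abs(rhs_flat(y, etas, ells, params)))) if community.m else 0.0
    N, C, E, G, viable = _summaries(community, params, extinction_threshold)
    return EquilibriumResult(
        community=community, residual=residual, converged=True,
        F_star=community.resources.F.copy(),
        N_star=N, C_star=C, E=E, G=G, viable=viable, removed=removed)
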
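"""Coupled eco-evolutionary dynamics on the ecological equilibrium manifold.

Trait dynamics follow a canonical-equation-style update: per evolutionary
step, each ecomorph's traits move proportionally to its equilibrium density
times the local selection gradient, with per-lineage rate constants that
absorb mutation rate and mutational variance.  Between steps the ecological
system is re-equilibrated (adaptive-dynamics timescale separation).  When
directional selection on the niche trait ceases (per-step displacement
below the cessation threshold), the curvature of the local fitness
landscape decides between a branching event (disruptive: the ecomorph is
split into two, displaced 0.1% either side, each with half the abundance)
and stabilization.  A run terminates when every ecomorph experiences
stabilizing selection and, where the life-history trait evolves, its
displacement has likewise ceased.

The engine contains no randomness: identical inputs give bit-identical
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import CommunityState, EcomorphState, Model1Params, ResourceState
from .equilibrium import (
    EquilibriumError,
    EquilibriumResult,
    find_equilibrium,
)
from .selection import (
    condition1_ratio,
    convergence_stable,
    fitness_curvature,
    selection_gradient,
)

__all__ = [
    "EvoRunConfig",
    "EvoTrajectory",
    "EventLog",
    "MaxStepsExceeded",
    "trait_step",
    "branch_ecomorph",
    "run_adaptive_dynamics",
    "landscape_scan",
    "preset_fig3",
    "preset_fig4a",
    "convergence_boundary",
]

RateSpec = Union[float, dict[int, float]]


class MaxStepsExceeded(RuntimeError):
    """The evolutionary loop hit max_steps before all selection stabilized."""


@dataclass(frozen=True)
class EvoRunConfig:
    """Knobs of the evolutionary engine.

    k_eta, k_ell : float or {lineage_id: float}
        Trait-update rate constants (canonical-equation scale, absorbing
        mutation rate and variance); k_ell = 0 freezes the life-history
        trait (the null model).
    dt_evo : float
        Evolutionary step length; halved adaptively whenever a niche-trait
        displacement would exceed 1% of the resource spacing D.
    cessation_threshold : float
        Per-step |delta eta| below which directional selection is deemed
        ceased and the curvature test is applied.
    branch_offset : float
        Relative trait displacement at a branching event (children at
        eta*(1 +/- branch_offset)).
    extinction_threshold : float
        Density floor below which an ecomorph is culled.
    merge_tolerance : float or None
        Trait distance below which same-lineage ecomorphs are merged
        (defaults to 1e-4 * D at run time).
    """

    k_eta: RateSpec = 0.5
    k_ell: RateSpec = 0.1
    dt_evo: float = 1.0
    cessation_threshold: float = 1e-8
    branch_offset: float = 0.001
    extinction_threshold: float = 1e-9
    max_steps: int = 2_000_000
    merge_tolerance: Optional[float] = None
    ell_min: float = 1e-6
    ell_margin: float = 1e-6
    eq_tol: float = 1e-9
    newton_tol: float = 1e-12
    t_max_eco: float = 1e6
    record_every: int = 1

    def rate(self, spec: RateSpec, lineage_id: int) -> float:
        if isinstance(spec, dict):
            return spec[lineage_id]
        return float(spec)


@dataclass
class EvoTrajectory:
    """Tidy per-step records of traits, densities and selection measures."""

    rows: list = field(default_factory=list)

    def record(self, evo_time, e: EcomorphState, N, C, g_eta, g_ell, curvature):
        self.rows.append((evo_time, e.id, e.lineage_id, e.eta, e.ell,
                          N, C, g_eta, g_ell, curvature))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["evo_time", "ecomorph_id", "lineage_id", "eta", "ell",
                     "N", "C", "g_eta", "g_ell", "curvature_eta"],
        )


@dataclass
class EventLog:
    """Ordered discrete events of an adaptive-dynamics run."""

    events: list = field(default_factory=list)

    def add(self, evo_time, kind, ids, **info):
        self.events.append({"evo_time": evo_time, "kind": kind,
                            "ecomorph_ids": list(ids), **info})

    def of_kind(self, kind: str) -> list:
        return [ev for ev in self.events if ev["kind"] == kind]

    def to_frame(self) -> pd.DataFrame:
        if not self.events:
            return pd.DataFrame(columns=["evo_time", "kind", "ecomorph_ids"])
        return pd.DataFrame(self.events)


def trait_step(eq: EquilibriumResult, gradients: list[tuple[float, float]],
               params: Model1Params, config: EvoRunConfig) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-ecomorph trait displacements for one evolutionary step.

    delta_eta_j = k_eta(lineage_j) * N_j* * g_eta_j * dt and likewise for
    ell; dt is halved until no niche displacement exceeds 1% of D, keeping
    the trait path on the slow manifold.  Returns (delta_eta, delta_ell,
    dt_used).
    """
    ecos = eq.community.ecomorphs
    base_eta = np.array([
        config.rate(config.k_eta, e.lineage_id) * eq.N_star[k] * gradients[k][0]
        for k, e in enumerate(ecos)])
    base_ell = np.array([
        config.rate(config.k_ell, e.lineage_id) * eq.N_star[k] * gradients[k][1]
        for k, e in enumerate(ecos)])
    dt = config.dt_evo
    cap = 0.01 * params.D if params.n >= 2 else 0.01
    while dt > 0 and np.max(np.abs(base_eta)) * dt > cap:
        dt *= 0.5
    return base_eta * dt, base_ell * dt, dt


def _clip_ell(ell: float, params: Model1Params, config: EvoRunConfig) -> float:
    lo = config.ell_min
    hi = params.w * (1.0 - config.ell_margin)
    return min(max(ell, lo), hi)


def branch_ecomorph(parent: EcomorphState, config: EvoRunConfig,
                    next_id: int) -> tuple[EcomorphState, EcomorphState]:
    """Split a disruptively selected ecomorph into two.

    Children sit at eta*(1 +/- branch_offset) with the parent's offspring
    size and stage composition, each carrying exactly half the parent's
    total density (total N conserved)."""
    off = config.branch_offset
    c1 = EcomorphState(id=next_id, lineage_id=parent.lineage_id,
                       parent_id=parent.id, eta=parent.eta * (1.0 + off),
                       ell=parent.ell, J=parent.J / 2.0, A=parent.A / 2.0)
    c2 = EcomorphState(id=next_id + 1, lineage_id=parent.lineage_id,
                       parent_id=parent.id, eta=parent.eta * (1.0 - off),
                       ell=parent.ell, J=parent.J / 2.0, A=parent.A / 2.0)
    return c1, c2


def _solve(community: CommunityState, params: Model1Params, config: EvoRunConfig):
    return find_equilibrium(
        community, params, tol=config.eq_tol, t_max=config.t_max_eco,
        newton_tol=config.newton_tol,
        extinction_threshold=config.extinction_threshold)


def run_adaptive_dynamics(
    initial: CommunityState,
    params: Model1Params,
    config: EvoRunConfig,
) -> tuple[EvoTrajectory, EventLog, CommunityState]:
    """Drive the community through trait space until all selection stabilizes.

    Per step: solve the ecological equilibrium (culling extinct or starving
    ecomorphs), compute selection gradients, advance traits.  Ecomorphs
    whose niche displacement has ceased are tested for curvature: disruptive
    ones branch (all qualifying ecomorphs in the same step, in id order);
    stabilizing ones count toward termination.  Same-lineage ecomorphs
    closer than the merge tolerance are merged.  Every discrete event is
    logged with its evolutionary time.
    """
    community = initial.copy()
    traj = EvoTrajectory()
    log = EventLog()
    evo_time = 0.0
    next_id = max((e.id for e in community.ecomorphs), default=-1) + 1
    merge_tol = (config.merge_tolerance if config.merge_tolerance is not None
                 else 1e-4 * (params.D if params.n >= 2 else 1.0))

    for step in range(config.max_steps):
        eq = _solve(community, params, config)
        for e in eq.removed:
            log.add(evo_time, "extinction", [e.id])
        community = eq.community
        if community.m == 0:
            log.add(evo_time, "stop", [], reason="all ecomorphs extinct")
            return traj, log, community

        gradients = [selection_gradient(k, eq, params)
                     for k in range(community.m)]
        d_eta, d_ell, dt = trait_step(eq, gradients, params, config)
        if any(config.rate(config.k_ell, e.lineage_id) > 0
               for e in community.ecomorphs):
            ell_ceased = bool(np.all(np.abs(d_ell) < config.cessation_threshold))
        else:
            ell_ceased = True

        to_branch: list[int] = []
        all_stabilizing = True
        curvatures: dict[int, float] = {}
        for k, e in enumerate(community.ecomorphs):
            if abs(d_eta[k]) < config.cessation_threshold:
                curv = fitness_curvature(k, eq, params)
                curvatures[k] = curv
                if curv > 0:
                    to_branch.append(k)
                    all_stabilizing = False
            else:
                all_stabilizing = False

        if step % config.record_every == 0 or to_branch or (all_stabilizing and ell_ceased):
            for k, e in enumerate(community.ecomorphs):
                traj.record(evo_time, e, eq.N_star[k], eq.C_star[k],
                            gradients[k][0], gradients[k][1],
                            curvatures.get(k))

        if to_branch:
            # necessary condition for coexistence of the daughters
            _, cond1 = condition1_ratio(params) if params.n >= 2 else (0.0, False)
            new_ecos = []
            for k, e in enumerate(community.ecomorphs):
                if k in to_branch and cond1:
                    c1, c2 = branch_ecomorph(e, config, next_id)
                    next_id += 2
                    log.add(evo_time, "branch", [e.id, c1.id, c2.id],
                            eta=e.eta, ell=e.ell)
                    new_ecos.extend([c1, c2])
                else:
                    if k in to_branch and not cond1:
                        log.add(evo_time, "cessation", [e.id], eta=e.eta,
                                note="disruptive but mutual invasibility fails")
                    new_ecos.append(e)
            if any(ev["kind"] == "branch" and ev["evo_time"] == evo_time
                   for ev in log.events):
                community = CommunityState(ecomorphs=new_ecos,
                                           resources=community.resources.copy(),
                                           t=community.t)
                evo_time += dt
                continue

        if all_stabilizing and ell_ceased:
            for k, e in enumerate(community.ecomorphs):
                log.add(evo_time, "cessation", [e.id], eta=e.eta, ell=e.ell)
            log.add(evo_time, "stop", [e.id for e in community.ecomorphs],
                    reason="all ecomorphs under stabilizing selection")
            return traj, log, community

        for k, e in enumerate(community.ecomorphs):
            e.eta = e.eta + d_eta[k]
            e.ell = _clip_ell(e.ell + d_ell[k], params, config)
        evo_time += dt

        community = _merge_close(community, merge_tol, log, evo_time)

    raise MaxStepsExceeded(
        f"max_steps={config.max_steps} reached at evo_time={evo_time}")


def _merge_close(community: CommunityState, merge_tol: float,
                 log: EventLog, evo_time: float) -> CommunityState:
    """Merge same-lineage ecomorphs whose niche traits drifted together."""
    ecos = sorted(community.ecomorphs, key=lambda e: e.id)
    merged = True
    while merged:
        merged = False
        for i in range(len(ecos)):
            for j in range(i + 1, len(ecos)):
                a, b = ecos[i], ecos[j]
                if (a.lineage_id == b.lineage_id
                        and abs(a.eta - b.eta) < merge_tol
                        and abs(a.ell - b.ell) < merge_tol):
                    a.J += b.J
                    a.A += b.A
                    log.add(evo_time, "merge", [a.id, b.id])
                    ecos.pop(j)
                    merged = True
                    break
            if merged:
                break
    if len(ecos) != community.m:
        return CommunityState(ecomorphs=ecos,
                              resources=community.resources.copy(),
                              t=community.t)
    return community


def preset_fig3(params: Optional[Model1Params] = None,
                config: Optional[EvoRunConfig] = None) -> dict:
    """Two lineages racing across ten unexploited niches.

    Lineages are seeded at the extremes of the niche axis (traits 0.8 and
    10.2, offspring size 1) and differ only in the life-history trait-update
    rate (default 2:1); total resource productivity is 2.  Returns the run
    products plus per-lineage first-branch times and final ecomorph counts.
    """
    from .scenarios import generate_scenario

    default_params, community = generate_scenario("ten_resource")
    if params is None:
        params = default_params
    if config is None:
        config = EvoRunConfig(k_eta=0.5, k_ell={0: 0.1, 1: 0.05},
                              record_every=200)
    traj, log, final = run_adaptive_dynamics(community, params, config)

    id_lineage = {e.id: e.lineage_id for e in community.ecomorphs}
    first_branch: dict[int, float] = {}
    for ev in log.of_kind("branch"):
        parent, c1, c2 = ev["ecomorph_ids"]
        lin = id_lineage.get(parent)
        id_lineage[c1] = lin
        id_lineage[c2] = lin
        if lin is not None and lin not in first_branch:
            first_branch[lin] = ev["evo_time"]
    counts = {}
    for e in final.ecomorphs:
        counts[e.lineage_id] = counts.get(e.lineage_id, 0) + 1
    return {
        "trajectory": traj,
        "events": log,
        "final": final,
        "first_branch_time": first_branch,
        "ecomorph_count": counts,
        "k_ell": dict(config.k_ell) if isinstance(config.k_ell, dict) else config.k_ell,
    }


def convergence_boundary(ell: float, params: Model1Params,
                         P_lo: float, P_hi: float, iters: int = 14,
                         **eq_kwargs) -> float:
    """Bisect total productivity P for the convergence-stability flip of the
    midpoint singular strategy at fixed offspring size.

    The bracket [P_lo, P_hi] must straddle the flip (repeller at P_lo,
    attractor at P_hi)."""
    mid_eta = 0.5 * (params.theta[0] + params.theta[-1])
    def stable(P):
        return convergence_stable(mid_eta, ell, params.with_productivity(P),
                                  **eq_kwargs)
    s_lo, s_hi = stable(P_lo), stable(P_hi)
    if s_lo or not s_hi:
        raise ValueError(
            f"bracket [{P_lo}, {P_hi}] does not straddle the stability flip "
            f"(stable at lo={s_lo}, at hi={s_hi})")
    for _ in range(iters):
        P_mid = 0.5 * (P_lo + P_hi)
        if stable(P_mid):
            P_hi = P_mid
        else:
            P_lo = P_mid
    return 0.5 * (P_lo + P_hi)


def preset_fig4a(params: Model1Params, config: Optional[EvoRunConfig],
                 ell_grid: np.ndarray, P_grid: np.ndarray,
                 delta_max_scenarios: tuple[float, ...]) -> pd.DataFrame:
    """Diversification map over offspring size and productivity.

    For each juvenile-mortality scenario and each (ell, P) cell, the niche
    trait is held at the midpoint singular value (only eta would evolve and
    the singular point is symmetry-pinned) and the cell is flagged
    diversification-enabled iff that singular point is convergence stable
    and the fitness curvature there is positive.  Each cell also carries
    the offspring-size selection gradient and the analytic productivity
    threshold computed from the singular resident's equilibrium (E, G).
    Cells whose resident is not viable, or whose equilibrium fails, are
    flagged rather than dropped.
    """
    from dataclasses import replace as _replace

    config = config or EvoRunConfig()
    eq_kwargs = dict(tol=config.eq_tol, t_max=config.t_max_eco,
                     newton_tol=config.newton_tol,
                     extinction_threshold=config.extinction_threshold)
    mid_eta = 0.5 * (params.theta[0] + params.theta[-1])
    rows = []
    for dmax in delta_max_scenarios:
        p_dm = _replace(params, delta_max=dmax)
        for ell in ell_grid:
            # E, G, g_ell and the analytic threshold do not depend on the
            # carrying capacities; evaluate them at the most productive cell
            # where the resident is most likely viable.
            ref = p_dm.with_productivity(float(np.max(P_grid)))
            g_ell = curv = P_min = np.nan
            try:
                eq_ref = _resident_eq(mid_eta, ell, ref, **eq_kwargs)
                if eq_ref.community.m:
                    _, g_ell = selection_gradient(0, eq_ref, ref)
                    from .selection import productivity_threshold
                    P_min = productivity_threshold(eq_ref.E[0], eq_ref.G[0], ref)
            except EquilibriumError:
                pass
            for P in P_grid:
                p_cell = p_dm.with_productivity(float(P))
                failed = False
                viable = False
                stable = False
                curv = np.nan
                try:
                    eq = _resident_eq(mid_eta, ell, p_cell, **eq_kwargs)
                    viable = eq.community.m > 0
                    if viable:
                        curv = fitness_curvature(0, eq, p_cell)
                        stable = convergence_stable(mid_eta, ell, p_cell,
                                                    **eq_kwargs)
                except EquilibriumError:
                    failed = True
                rows.append({
                    "delta_max": dmax, "ell": float(ell), "P": float(P),
                    "viable": viable, "equilibrium_failed": failed,
                    "curvature_eta": curv, "convergence_stable": stable,
                    "diversification": bool(viable and stable and curv > 0),
                    "g_ell": g_ell, "P_min_analytic": P_min,
                })
    return pd.DataFrame(rows)


def _resident_eq(eta, ell, params, **eq_kwargs):
    community = CommunityState(
        ecomorphs=[EcomorphState(id=0, lineage_id=0, eta=float(eta),
                                 ell=float(ell), J=1e-3, A=1e-3)],
        resources=ResourceState(params.F_max.copy()))
    return find_equilibrium(community, params, **eq_kwargs)


def landscape_scan(ell: float, params: Model1Params, eta_grid: np.ndarray,
                   config: Optional[EvoRunConfig] = None) -> dict:
    """Map the niche-trait selection landscape at fixed offspring size.

    Solves the single-resident equilibrium along ``eta_grid``, locates the
    zeros of the niche selection gradient by sign change plus bisection, and
    labels each singular point as attractor/repeller (convergence
    stability) and fitness minimum/maximum (curvature sign).  Grid points
    where the resident is not viable are flagged.
    """
    config = config or EvoRunConfig()

    def g_of(eta):
        comm = CommunityState(
            ecomorphs=[EcomorphState(id=0, lineage_id=0, eta=eta, ell=ell,
                                     J=1e-3, A=1e-3)],
            resources=ResourceState(params.F_max.copy()))
        eq = _solve(comm, params, config)
        if eq.community.m == 0:
            return None, None
        return selection_gradient(0, eq, params)[0], eq

    grid_g = []
    viable = []
    for eta in eta_grid:
        try:
            g, _ = g_of(eta)
        except EquilibriumError:
            g = None
        grid_g.append(g)
        viable.append(g is not None)

    singular = []
    for i in range(len(eta_grid) - 1):
        g0, g1 = grid_g[i], grid_g[i + 1]
        if g0 is None or g1 is None or g0 * g1 > 0:
            continue
        lo, hi = float(eta_grid[i]), float(eta_grid[i + 1])
        glo = g0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            gm, _ = g_of(mid)
            if gm is None:
                break
            if glo * gm <= 0:
                hi = mid
            else:
                lo, glo = mid, gm
        eta_s = 0.5 * (lo + hi)
        _, eq_s = g_of(eta_s)
        curv = fitness_curvature(0, eq_s, params)
        attractor = convergence_stable(eta_s, ell, params,
                                       tol=config.eq_tol,
                                       t_max=config.t_max_eco,
                                       newton_tol=config.newton_tol,
                                       extinction_threshold=config.extinction_threshold)
        singular.append({
            "eta": eta_s,
            "curvature": curv,
            "fitness_extremum": "minimum" if curv > 0 else "maximum",
            "classification": "attractor" if attractor else "repeller",
        })
    return {
        "eta_grid": np.asarray(eta_grid, dtype=float),
        "g_eta": grid_g,
        "viable": np.asarray(viable),
        "singular_points": singular,
    }
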
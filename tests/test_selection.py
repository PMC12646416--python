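"""Invasion fitness, gradients, curvature and the diversification conditions."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from nichebranch.core import (
    birth_rate,
    feeding_rates,
    growth_flux,
    juvenile_mortality,
    maturation_rate,
)
from nichebranch.selection import (
    classify_selection,
    condition1_ratio,
    convergence_stable,
    fitness_curvature,
    invasion_fitness,
    productivity_threshold,
    selection_gradient,
    _richardson_curvature,
    _richardson_gradient,
)

from conftest import resident_equilibrium


def mutant_ode_growth_sign(eta_m, ell_m, F, params, horizon=3000.0):
    """Brute-force invasion oracle: integrate the rare mutant's (J, A)
    system at frozen resources and read the sign of its long-run growth."""
    c_J, c_A = feeding_rates(eta_m, F, params)
    phi = growth_flux(c_J, params)
    dJ = juvenile_mortality(ell_m, params)
    Phi = maturation_rate(phi, dJ, ell_m, params)
    beta = birth_rate(c_A, ell_m, params)

    def rhs(t, y):
        J, A = y
        return [beta * A - (Phi + dJ) * J, Phi * J - params.delta_A * A]

    sol = solve_ivp(rhs, (0.0, horizon), [1e-6, 1e-6], method="LSODA",
                    rtol=1e-10, atol=1e-30)
    n0 = sum(sol.y[:, 0])
    nT = sum(sol.y[:, -1])
    return np.sign(np.log(nT / n0))


class TestInvasionFitness:
    def test_starving_adults_give_pure_decay(self, simple_params):
        # beta = 0: the stage matrix is triangular; the slowest decay wins
        F = np.zeros(2)   # no food at all: phi = 0, Phi = 0, beta = 0
        lam = invasion_fitness(1.5, 1.0, F, simple_params)
        dJ = juvenile_mortality(1.0, simple_params)
        assert lam == pytest.approx(-min(dJ, simple_params.delta_A), rel=1e-12)

    def test_sign_matches_R0(self, two_resource_params):
        p = two_resource_params
        eq = resident_equilibrium(1.5, 1.7, p)
        F = eq.F_star
        for eta_m, ell_m in [(1.1, 1.7), (1.5, 1.2), (1.35, 2.4), (0.8, 1.0)]:
            c_J, c_A = feeding_rates(eta_m, F, p)
            phi = growth_flux(c_J, p)
            dJ = juvenile_mortality(ell_m, p)
            Phi = maturation_rate(phi, dJ, ell_m, p)
            beta = birth_rate(c_A, ell_m, p)
            lam = invasion_fitness(eta_m, ell_m, F, p)
            if Phi > 0:
                R0 = beta * Phi / (p.delta_A * (Phi + dJ))
                assert np.sign(lam) == np.sign(R0 - 1.0)
            else:
                assert lam < 0

    def test_rejects_mutant_size_outside_range(self, two_resource_params):
        with pytest.raises(ValueError):
            invasion_fitness(1.5, -0.1, np.ones(2), two_resource_params)
        with pytest.raises(ValueError):
            invasion_fitness(1.5, two_resource_params.w, np.ones(2),
                             two_resource_params)

    def test_eigenvalue_equals_per_capita_growth_at_stationary_stage_mix(
            self, two_resource_params):
        """The dominant eigenvalue coincides with the per-capita growth rate
        beta*C - (delta_J*(1-C) + delta_A*C) evaluated at the mutant's own
        stationary stage distribution."""
        p = two_resource_params
        eq = resident_equilibrium(1.5, 1.7, p)
        for eta_m, ell_m in [(1.2, 1.5), (1.5, 2.2), (1.7, 1.0)]:
            c_J, c_A = feeding_rates(eta_m, eq.F_star, p)
            phi = growth_flux(c_J, p)
            dJ = juvenile_mortality(ell_m, p)
            Phi = maturation_rate(phi, dJ, ell_m, p)
            beta = birth_rate(c_A, ell_m, p)
            lam = invasion_fitness(eta_m, ell_m, eq.F_star, p)
            # stationary stage mix: Phi*J = (lam + delta_A)*A
            C = Phi / (Phi + lam + p.delta_A)
            W = beta * C - (dJ * (1 - C) + p.delta_A * C)
            assert W == pytest.approx(lam, rel=1e-9, abs=1e-12)


class TestSelectionGradient:
    def test_symmetry_pins_niche_gradient_at_midpoint(self, midpoint_equilibrium,
                                                      two_resource_params):
        g_eta, _ = selection_gradient(0, midpoint_equilibrium,
                                      two_resource_params)
        assert abs(g_eta) < 1e-8

    def test_agreement_with_coarse_finite_difference(self, two_resource_params):
        p = two_resource_params
        eq = resident_equilibrium(1.25, 1.6, p)
        e = eq.community.ecomorphs[0]
        g_eta, g_ell = selection_gradient(0, eq, p)
        h = 1e-4
        coarse_eta = (invasion_fitness(e.eta + h, e.ell, eq.F_star, p)
                      - invasion_fitness(e.eta - h, e.ell, eq.F_star, p)) / (2 * h)
        coarse_ell = (invasion_fitness(e.eta, e.ell + h, eq.F_star, p)
                      - invasion_fitness(e.eta, e.ell - h, eq.F_star, p)) / (2 * h)
        assert g_eta == pytest.approx(coarse_eta, rel=1e-4)
        assert g_ell == pytest.approx(coarse_ell, rel=1e-4)

    def test_offspring_size_gradient_crosses_zero_once(self, two_resource_params):
        grid = np.arange(1.3, 2.3, 0.1)
        gs = [selection_gradient(0, resident_equilibrium(1.5, float(l),
                                                         two_resource_params),
                                 two_resource_params)[1]
              for l in grid]
        signs = np.sign(gs)
        assert gs[0] > 0 and gs[-1] < 0
        assert int(np.sum(np.diff(signs) != 0)) == 1

    def test_antisymmetric_about_midpoint(self, two_resource_params):
        g_l = selection_gradient(
            0, resident_equilibrium(1.3, 1.6, two_resource_params),
            two_resource_params)[0]
        g_r = selection_gradient(
            0, resident_equilibrium(1.7, 1.6, two_resource_params),
            two_resource_params)[0]
        assert g_l == pytest.approx(-g_r, rel=1e-6)


class TestCurvature:
    def test_quadratic_synthetic_oracle(self):
        f = lambda x: 3.0 - 0.7 * (x - 1.2) ** 2
        assert _richardson_curvature(f, 1.2, 1e-4) == pytest.approx(-1.4, rel=1e-6)
        g = lambda x: 0.3 * x ** 2 + x
        assert _richardson_gradient(g, 2.0, 1e-4) == pytest.approx(2.2, rel=1e-9)

    def test_narrow_niche_midpoint_is_fitness_minimum(self, midpoint_equilibrium,
                                                      two_resource_params):
        # D/tau = 2.86 > 2: disruptive at the midpoint singular point
        assert fitness_curvature(0, midpoint_equilibrium,
                                 two_resource_params) > 0

    def test_broad_niche_midpoint_is_fitness_maximum(self, two_resource_params):
        p = dataclasses.replace(two_resource_params, tau=2.0 / 3.0)  # D/tau = 1.5
        eq = resident_equilibrium(1.5, 1.7476, p)
        assert fitness_curvature(0, eq, p) < 0


class TestClassification:
    @pytest.mark.parametrize("g,c,expected", [
        (1e-3, 0.5, "directional"),
        (1e-10, 0.02, "disruptive"),
        (1e-10, -0.02, "stabilizing"),
    ])
    def test_regimes(self, g, c, expected):
        assert classify_selection(g, c, cessation_threshold=1e-8) == expected


class TestCondition1:
    def test_ratio_and_strict_threshold(self, simple_params):
        ratio, ok = condition1_ratio(simple_params)  # D=1, tau=0.3
        assert ratio == pytest.approx(1 / 0.3)
        assert ok
        p2 = dataclasses.replace(simple_params, tau=0.5)
        ratio2, ok2 = condition1_ratio(p2)
        assert ratio2 == pytest.approx(2.0)
        assert not ok2  # strict inequality

    def test_single_resource_undefined(self):
        from nichebranch.scenarios import default_params
        with pytest.raises(ValueError):
            condition1_ratio(default_params(n=1))


class TestProductivityThreshold:
    def test_functional_form(self, two_resource_params):
        p = two_resource_params
        base = productivity_threshold(0.2, 0.3, p)
        assert productivity_threshold(0.4, 0.3, p) == pytest.approx(base / 2)
        assert productivity_threshold(0.2, 0.6, p) == pytest.approx(2 * base)
        assert productivity_threshold(0.2, 0.3, p) == pytest.approx(
            p.rho * 0.3 * p.D ** 2 * np.exp(p.D ** 2 / (8 * p.tau ** 2))
            / (4 * 0.2 * p.tau ** 2 * p.alpha))

    def test_vanishes_with_resource_spacing(self, two_resource_params):
        small_D = dataclasses.replace(
            two_resource_params, D=1e-4,
            theta=np.array([1.0, 1.0 + 1e-4]))
        assert productivity_threshold(0.2, 0.3, small_D) < 1e-7

    def test_rejects_nonpositive_scaling(self, two_resource_params):
        with pytest.raises(ValueError):
            productivity_threshold(0.0, 0.3, two_resource_params)


class TestConvergenceStability:
    def test_midpoint_attractor_near_optimal_offspring_size(self,
                                                            two_resource_params):
        assert convergence_stable(1.5, 1.7476, two_resource_params)

    def test_midpoint_repeller_below_threshold_productivity(self,
                                                            two_resource_params):
        p_low = two_resource_params.with_productivity(0.25)
        assert not convergence_stable(1.5, 1.7476, p_low)
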
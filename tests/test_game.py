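"""Best responses, Nash equilibria, control and the coordination benchmark."""

import numpy as np
import pytest

from leakytrade import (
    ProductionProfile,
    RegulationScenario,
    best_response,
    controlled_profile,
    full_specialization_profile,
    max_sustainable_growth,
    nash_equilibrium,
    population_equilibrium,
    solve_steady_state,
    verify_nash,
)
from leakytrade.game import _growths, deviation_growth, pool_concentrations
from leakytrade.fixtures import trade_params
from leakytrade.steady_state import isolated_optimal_growth


class TestBestResponse:
    def test_without_diffusion_reduces_to_isolated_optimum(self):
        params = trade_params(0.67, 1.49, D=0.0)
        for opp in (0.0, 0.3, 0.9):
            assert best_response(1, opp, 0.5, params) == pytest.approx(0.5, abs=1e-9)

    def test_vanishing_partner_reduces_to_isolated_optimum(self, example_params):
        f_iso, _ = isolated_optimal_growth(example_params.type1, example_params.mu)
        assert best_response(1, 0.3, 1.0, example_params) == pytest.approx(f_iso, abs=1e-8)

    def test_full_specialization_against_strong_B_producer(self):
        # where the partner is a far better B producer, type 1 makes only A
        params = trade_params(1.0, 10.0)
        eq = population_equilibrium(RegulationScenario.COMPETITIVE_NASH, params)
        assert eq.solution.profile.f1 == 1.0

    def test_grid_search_oracle(self, example_params):
        # brute force at the fixed pool confirms the marginal-condition solve
        f2, n1 = 0.3, 0.6
        f1_star = best_response(1, f2, n1, example_params)
        steady = solve_steady_state(ProductionProfile(f1_star, f2), n1, example_params)
        pool = pool_concentrations(steady, n1)
        grid = np.linspace(0, 1, 1001)
        g_dev = deviation_growth(grid, example_params.type1, pool, example_params)
        assert float(grid[np.argmax(g_dev)]) == pytest.approx(f1_star, abs=1e-3)


class TestNashEquilibrium:
    def test_symmetric_system_is_label_swap_invariant(self, symmetric_params):
        sol = nash_equilibrium(0.5, symmetric_params)
        assert sol.profile.f1 == pytest.approx(1.0 - sol.profile.f2, abs=1e-8)
        assert sol.steady.g1 == pytest.approx(sol.steady.g2, abs=1e-10)

    def test_growth_rates_equalize_at_population_equilibrium(
            self, example_params, example_competitive_eq):
        sol = example_competitive_eq.solution
        assert sol.steady.g1 == pytest.approx(sol.steady.g2, abs=1e-7)

    @pytest.mark.parametrize("seed", range(6))
    def test_no_deviation_improves_growth(self, seed):
        rng = np.random.default_rng(seed)
        params = trade_params(rng.uniform(0.1, 1.0), rng.uniform(1.0, 3.0))
        n1 = rng.uniform(0.1, 0.9)
        sol = nash_equilibrium(n1, params)
        assert verify_nash(sol, n1, params, grid_step=0.01)

    def test_perturbed_profile_fails_verification(self, example_params):
        sol = nash_equilibrium(0.5, example_params)
        bad_f1 = sol.profile.f1 - 0.2
        perturbed = solve_steady_state(ProductionProfile(bad_f1, sol.profile.f2),
                                       0.5, example_params)
        from leakytrade.game import GameSolution
        bad = GameSolution(profile=ProductionProfile(bad_f1, sol.profile.f2),
                           steady=perturbed, scenario=sol.scenario)
        assert not verify_nash(bad, 0.5, example_params, grid_step=0.01)

    def test_no_diffusion_symmetric_isolated_optimum_is_nash(self):
        params = trade_params(1.0, 1.0, D=0.0)
        sol = nash_equilibrium(0.5, params)
        assert sol.profile.f1 == pytest.approx(0.5, abs=1e-9)
        assert sol.profile.f2 == pytest.approx(0.5, abs=1e-9)
        assert verify_nash(sol, 0.5, params, grid_step=0.01)


class TestControlledProfile:
    def test_control_beats_competition_for_the_controller(self, example_params):
        for n1 in (0.3, 0.6):
            nash = nash_equilibrium(n1, example_params)
            ctrl = controlled_profile(1, n1, example_params)
            assert ctrl.steady.g1 >= nash.steady.g1 - 1e-9

    def test_controlled_curve_dominates_pointwise(self, example_params):
        for n1 in np.linspace(0.1, 0.9, 5):
            nash = nash_equilibrium(float(n1), example_params)
            ctrl = controlled_profile(1, float(n1), example_params)
            assert ctrl.steady.g1 >= nash.steady.g1 - 1e-9

    def test_symmetric_controllers_are_mirror_images(self, symmetric_params):
        c1 = controlled_profile(1, 0.5, symmetric_params)
        c2 = controlled_profile(2, 0.5, symmetric_params)
        assert c1.profile.f1 == pytest.approx(1.0 - c2.profile.f2, abs=1e-6)
        assert c1.profile.f2 == pytest.approx(1.0 - c2.profile.f1, abs=1e-6)
        assert c1.steady.g1 == pytest.approx(c2.steady.g2, abs=1e-8)

    def test_joint_grid_oracle(self, example_params):
        # no point of a fine joint grid may beat the optimizer
        ctrl = controlled_profile(1, 0.5, example_params)
        grid = np.linspace(0, 1, 101)
        F1, F2 = np.meshgrid(grid, grid, indexing="ij")
        g1, _ = _growths(F1.ravel(), F2.ravel(), 0.5, example_params)
        assert np.nanmax(g1) <= ctrl.steady.g1 + 1e-8


class TestCoordination:
    def test_full_specialization_profile_convention(self, example_params):
        prof = full_specialization_profile(example_params)
        assert (prof.f1, prof.f2) == (1.0, 0.0)
        p_A1, p_B1, p_A2, p_B2 = prof.rates(example_params)
        assert p_B1 == 0.0 and p_A2 == 0.0
        assert p_A1 == pytest.approx(example_params.type1.a_A)
        assert p_B2 == pytest.approx(example_params.type2.a_B)

    def test_optimum_fully_specializes(self, example_params):
        n1_star, profile, g_star = max_sustainable_growth(example_params)
        assert (profile.f1, profile.f2) == (1.0, 0.0)
        assert 0.0 < n1_star < 1.0

    def test_dominates_competitive_equilibrium(self, example_params, example_competitive_eq):
        _, _, g_star = max_sustainable_growth(example_params)
        assert g_star >= example_competitive_eq.g_star - 1e-9

    def test_coarse_grid_oracle(self, example_params):
        # exhaustive scan over (n1, f1, f2) cannot beat the optimizer
        _, profile, g_star = max_sustainable_growth(example_params)
        fs = np.linspace(0, 1, 21)
        n1s = np.linspace(0.01, 0.99, 21)
        F1, F2 = np.meshgrid(fs, fs, indexing="ij")
        best, best_profile = -np.inf, None
        prev = None
        for n1 in n1s:
            g1, g2 = _growths(F1.ravel(), F2.ravel(), float(n1), example_params)
            gap = g1 - g2
            mean = 0.5 * (g1 + g2)
            if prev is not None:
                for j in np.flatnonzero(np.sign(prev[0]) != np.sign(gap)):
                    w = abs(prev[0][j]) / (abs(prev[0][j]) + abs(gap[j]))
                    est = (1 - w) * prev[1][j] + w * mean[j]
                    if est > best:
                        best = float(est)
                        best_profile = (float(F1.ravel()[j]), float(F2.ravel()[j]))
            prev = (gap, mean)
        assert best_profile == (profile.f1, profile.f2)
        assert g_star == pytest.approx(best, abs=5e-3)
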
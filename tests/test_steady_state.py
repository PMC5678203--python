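"""Quasi-steady-state solver: closed forms, algebraic path, integration oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leakytrade import (
    CellTypeParams,
    ProductionProfile,
    TradeParams,
    integrate_to_steady,
    isolated_optimal_growth,
    solve_isolated,
    solve_steady_state,
    steady_state_batch,
)
from leakytrade.fixtures import trade_params


def quadratic_oracle(p_A, p_B, mu):
    """Independent closed form: A-B=(p_A-p_B)/mu, B from the quadratic."""
    u = (p_A - p_B) / mu
    roots = np.roots([1.0, mu + u, -p_B])
    B = float(max(roots))
    return B + u, B


class TestSolveIsolated:
    @pytest.mark.parametrize("p_A,p_B", [
        (0.5, 0.5), (0.75, 0.25), (0.9, 0.1), (0.2, 1.3),
    ])
    def test_matches_quadratic_oracle(self, p_A, p_B):
        A, B = solve_isolated(p_A, p_B, 0.05)
        A_ref, B_ref = quadratic_oracle(p_A, p_B, 0.05)
        assert (A, B) == pytest.approx((A_ref, B_ref), abs=1e-12)

    def test_balanced_production_reference_point(self):
        A, B = solve_isolated(0.5, 0.5, 0.05)
        assert A == pytest.approx(B)
        assert A == pytest.approx(0.68255, abs=1e-5)

    def test_no_A_production_forces_A_to_zero(self):
        A, B = solve_isolated(0.0, 1.0, 0.05)
        assert A == pytest.approx(0.0, abs=1e-12)
        assert B == pytest.approx(20.0)

    def test_lopsided_production(self):
        A, B = solve_isolated(0.75, 0.25, 0.05)
        assert A == pytest.approx(10.0248, abs=1e-4)
        assert B == pytest.approx(0.02482, abs=1e-5)
        assert A * B == pytest.approx(0.2488, abs=1e-4)

    @given(p_A=st.floats(0, 2), p_B=st.floats(0, 2),
           mu=st.floats(0.001, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_defining_equations_vanish(self, p_A, p_B, mu):
        A, B = solve_isolated(p_A, p_B, mu)
        g = A * B
        scale = 1.0 + max(abs(A), abs(B))  # amounts reach p/mu
        assert p_A - mu * A - g == pytest.approx(0.0, abs=1e-12 * scale)
        assert p_B - mu * B - g == pytest.approx(0.0, abs=1e-12 * scale)


class TestSolveSteadyState:
    def test_decoupled_type_matches_isolated_form(self, example_params):
        # at n1=1 type 1 receives no diffusive flux regardless of type 2
        res = solve_steady_state(ProductionProfile(0.5, 0.3), 1.0, example_params)
        assert res.converged
        assert res.conc.A1 == pytest.approx(0.68255, abs=1e-5)
        assert res.conc.B1 == pytest.approx(0.68255, abs=1e-5)
        assert res.g1 == pytest.approx(0.46588, abs=1e-5)

    def test_symmetric_types_give_symmetric_concentrations(self, symmetric_params):
        res = solve_steady_state(ProductionProfile(0.4, 0.4), 0.5, symmetric_params)
        assert res.conc.A1 == pytest.approx(res.conc.A2, abs=1e-10)
        assert res.conc.B1 == pytest.approx(res.conc.B2, abs=1e-10)

    def test_no_A_source_anywhere_means_no_growth(self):
        params = trade_params(0.67, 1.49, D=0.0)
        res = solve_steady_state(ProductionProfile(0.0, 0.0), 0.5, params)
        assert res.conc.A1 == pytest.approx(0.0, abs=1e-10)
        assert res.conc.A2 == pytest.approx(0.0, abs=1e-10)
        assert res.g1 == pytest.approx(0.0, abs=1e-10)
        assert res.g2 == pytest.approx(0.0, abs=1e-10)

    def test_residuals_below_tolerance(self, example_params):
        res = solve_steady_state(ProductionProfile(0.8, 0.1), 0.37, example_params)
        assert res.converged
        assert res.residual < 1e-10

    @pytest.mark.parametrize("seed", range(4))
    def test_algebraic_path_matches_time_integration(self, seed):
        # the integration from empty cells is the independent oracle for the
        # quartic-elimination fast path
        rng = np.random.default_rng(seed)
        f1, f2, n1 = rng.random(3)
        a_A2 = rng.uniform(0.1, 1.0)
        a_B2 = rng.uniform(1.0, 3.0)
        params = trade_params(a_A2, a_B2)
        profile = ProductionProfile(f1, f2)
        fast = solve_steady_state(profile, n1, params)
        slow = integrate_to_steady(profile, n1, params)
        assert fast.conc.as_tuple() == pytest.approx(slow.conc.as_tuple(),
                                                     abs=1e-6)

    def test_general_stoichiometry_falls_back_to_integration(self):
        cell = CellTypeParams(a_A=1.0, a_B=1.0, s_A=1.0, s_B=2.0)
        params = TradeParams(type1=cell, type2=cell)
        res = solve_steady_state(ProductionProfile(0.5, 0.5), 0.5, params)
        assert res.converged

    def test_batch_agrees_with_scalar_calls(self, example_params):
        f1 = np.linspace(0.0, 1.0, 11)
        batch = steady_state_batch(f1 * 1.0, (1 - f1) * 1.0,
                                   0.3 * 0.67, 0.7 * 1.49, 0.6, example_params)
        for i, f in enumerate(f1):
            res = solve_steady_state(ProductionProfile(float(f), 0.3), 0.6, example_params)
            assert batch[i] == pytest.approx(res.conc.as_tuple(), abs=1e-9)


class TestIsolatedOptimalGrowth:
    def test_symmetric_efficiencies_split_evenly(self):
        f_star, g_star = isolated_optimal_growth(CellTypeParams(1.0, 1.0), 0.05)
        assert f_star == pytest.approx(0.5, abs=1e-9)
        assert g_star == pytest.approx(0.46588, abs=1e-5)

    def test_starved_type_grows_slowly(self):
        _, g_small = isolated_optimal_growth(CellTypeParams(1e-4, 1.0), 0.05)
        _, g_ref = isolated_optimal_growth(CellTypeParams(1.0, 1.0), 0.05)
        assert g_small < 0.05 * g_ref

    def test_growth_increases_with_efficiency(self):
        _, g1 = isolated_optimal_growth(CellTypeParams(1.0, 1.0), 0.05)
        _, g2 = isolated_optimal_growth(CellTypeParams(2.0, 2.0), 0.05)
        assert g2 > g1

    @pytest.mark.parametrize("a_A,a_B", [(0.67, 1.49), (2.0, 0.4), (1.0, 3.0)])
    def test_invariant_under_metabolite_relabeling(self, a_A, a_B):
        f1, g1 = isolated_optimal_growth(CellTypeParams(a_A, a_B), 0.05)
        f2, g2 = isolated_optimal_growth(CellTypeParams(a_B, a_A), 0.05)
        assert f1 == pytest.approx(1.0 - f2, abs=1e-8)
        assert g1 == pytest.approx(g2, abs=1e-10)

    def test_grid_search_oracle(self):
        # brute force over the budget line confirms the bracketing solve
        cell = CellTypeParams(0.67, 1.49)
        f_star, g_star = isolated_optimal_growth(cell, 0.05)
        fs = np.linspace(0, 1, 2001)
        gs = [np.prod(solve_isolated(f * cell.a_A, (1 - f) * cell.a_B, 0.05))
              for f in fs]
        assert g_star >= max(gs) - 1e-12  # never below the brute force
        assert g_star == pytest.approx(max(gs), abs=1e-5)
        assert abs(f_star - fs[int(np.argmax(gs))]) < 1e-3
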
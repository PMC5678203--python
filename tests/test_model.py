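"""Domain types, growth law, budget constraint and the concentration ODEs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leakytrade import (
    CellTypeParams,
    ConcentrationState,
    DomainError,
    PopulationState,
    ProductionProfile,
    TradeParams,
    budget_value,
    growth_rate,
    ode_rhs,
    production_from_fraction,
)

CELL = CellTypeParams(a_A=1.0, a_B=1.0)


class TestGrowthRate:
    @pytest.mark.parametrize("A,B,expected", [
        (1.0, 1.0, 1.0),          # unit inputs under mass action
        (0.0, 5.0, 0.0),          # zero factor kills growth
        (2.0, 0.5, 1.0),
    ])
    def test_mass_action_values(self, A, B, expected):
        assert growth_rate(A, B, CELL) == pytest.approx(expected)

    def test_isolated_balanced_production_level(self):
        # positive root of A^2 + mu*A - 0.5 = 0 at mu=0.05 gives the
        # steady concentration when p_A = p_B = 0.5; quadratic-formula oracle
        mu = 0.05
        A = (-mu + np.sqrt(mu * mu + 2.0)) / 2.0
        assert growth_rate(A, A, CELL) == pytest.approx(0.46588, abs=1e-5)

    def test_negative_amount_rejected(self):
        with pytest.raises(DomainError):
            growth_rate(-0.1, 1.0, CELL)

    @given(A=st.floats(0.01, 50), B=st.floats(0.01, 50),
           dA=st.floats(0.01, 5))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_each_argument(self, A, B, dA):
        assert growth_rate(A + dA, B, CELL) > growth_rate(A, B, CELL)
        assert growth_rate(A, B + dA, CELL) > growth_rate(A, B, CELL)


class TestBudget:
    @pytest.mark.parametrize("f,a_A,a_B,expected", [
        (1.0, 1.0, 2.0, (1.0, 0.0)),
        (0.0, 1.0, 2.0, (0.0, 2.0)),
        (0.5, 0.67, 1.49, (0.335, 0.745)),
    ])
    def test_production_from_fraction(self, f, a_A, a_B, expected):
        cell = CellTypeParams(a_A=a_A, a_B=a_B)
        p_A, p_B = production_from_fraction(f, cell)
        assert (p_A, p_B) == pytest.approx(expected)

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(DomainError):
            production_from_fraction(1.2, CELL)

    @pytest.mark.parametrize("p_A,p_B,a,expected", [
        (0.5, 0.5, (1.0, 1.0), 1.0),
        (0.0, 0.0, (3.0, 0.2), 0.0),
        (1.0, 2.0, (1.0, 2.0), 2.0),  # over budget: caller must reject
    ])
    def test_budget_value(self, p_A, p_B, a, expected):
        cell = CellTypeParams(a_A=a[0], a_B=a[1])
        assert budget_value(p_A, p_B, cell) == pytest.approx(expected)

    @given(f=st.floats(0, 1), a_A=st.floats(0.05, 20), a_B=st.floats(0.05, 20))
    @settings(max_examples=100, deadline=None)
    def test_boundary_profiles_spend_exactly_the_budget(self, f, a_A, a_B):
        cell = CellTypeParams(a_A=a_A, a_B=a_B)
        p_A, p_B = production_from_fraction(f, cell)
        assert budget_value(p_A, p_B, cell) == pytest.approx(1.0, abs=1e-12)


class TestOdeRhs:
    def params(self, a2=(1.0, 1.0), D=3.0, mu=0.05):
        return TradeParams(type1=CELL, type2=CellTypeParams(*a2), D=D, mu=mu)

    def test_empty_cells_see_only_production(self):
        conc = ConcentrationState(0, 0, 0, 0)
        prof = ProductionProfile(0.5, 0.5)
        rhs = ode_rhs(conc, prof, PopulationState(0.5), self.params())
        assert rhs == pytest.approx((0.5, 0.5, 0.5, 0.5))

    def test_zero_gradient_means_zero_diffusive_flux(self):
        conc = ConcentrationState(1.3, 0.4, 1.3, 0.4)
        prof = ProductionProfile(0.5, 0.5)
        for D in (0.0, 3.0):
            rhs = ode_rhs(conc, prof, PopulationState(0.3), self.params(D=D))
            # identical concentrations: D must drop out entirely
            ref = ode_rhs(conc, prof, PopulationState(0.3), self.params(D=0.0))
            assert rhs == pytest.approx(ref)

    def test_single_type_steady_state_is_fixed_point(self):
        from leakytrade import solve_isolated
        mu = 0.05
        A, B = solve_isolated(0.7, 0.3, mu)
        conc = ConcentrationState(A, B, 0.0, 0.0)
        prof = ProductionProfile(0.7, 1.0)  # p_A2 = a_A2, but n2 = 0
        rhs = ode_rhs(conc, prof, PopulationState(1.0), self.params())
        assert rhs[0] == pytest.approx(0.0, abs=1e-12)
        assert rhs[1] == pytest.approx(0.0, abs=1e-12)

    @given(f1=st.floats(0, 1), f2=st.floats(0, 1), n1=st.floats(0, 1),
           vals=st.tuples(*[st.floats(0, 10)] * 4))
    @settings(max_examples=50, deadline=None)
    def test_label_swap_symmetry(self, f1, f2, n1, vals):
        # exchanging (type1<->type2, A<->B, f<->1-f) permutes the derivatives
        a2 = (0.67, 1.49)
        params = self.params(a2=a2)
        swapped = TradeParams(
            type1=CellTypeParams(a_A=a2[1], a_B=a2[0]),
            type2=CellTypeParams(a_A=CELL.a_B, a_B=CELL.a_A),
            D=params.D, mu=params.mu)
        A1, B1, A2, B2 = vals
        rhs = ode_rhs(ConcentrationState(A1, B1, A2, B2),
                      ProductionProfile(f1, f2), PopulationState(n1), params)
        rhs_swapped = ode_rhs(ConcentrationState(B2, A2, B1, A1),
                              ProductionProfile(1 - f2, 1 - f1),
                              PopulationState(1 - n1), swapped)
        assert rhs_swapped == pytest.approx((rhs[3], rhs[2], rhs[1], rhs[0]))


class TestInvariants:
    def test_population_state_count_consistency(self):
        st_ok = PopulationState.from_counts(3.0, 1.0)
        assert st_ok.n1 == pytest.approx(0.75)
        with pytest.raises(DomainError):
            PopulationState(n1=0.2, N1=3.0, N2=1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(DomainError):
            CellTypeParams(a_A=-1.0, a_B=1.0)
        with pytest.raises(DomainError):
            TradeParams(type1=CELL, type2=CELL, D=-0.1)
        with pytest.raises(DomainError):
            TradeParams(type1=CELL, type2=CELL, mu=0.0)
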
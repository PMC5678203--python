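import pytest

from leakytrade import (
    CellTypeParams,
    RegulationScenario,
    TradeParams,
    population_equilibrium,
)
from leakytrade.fixtures import scenario_example_params, trade_params


@pytest.fixture(scope="session")
def reference_cell() -> CellTypeParams:
    return CellTypeParams(a_A=1.0, a_B=1.0)


@pytest.fixture(scope="session")
def example_params() -> TradeParams:
    """The four-scenario example parameter set (a_A2=0.67, a_B2=1.49)."""
    return scenario_example_params()


@pytest.fixture(scope="session")
def example_competitive_eq(example_params):
    return population_equilibrium(RegulationScenario.COMPETITIVE_NASH, example_params)


@pytest.fixture(scope="session")
def symmetric_params() -> TradeParams:
    return trade_params(1.0, 1.0)
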
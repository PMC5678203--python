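"""Named parameter sets: the studied presets plus regime-spanning draws.

The reference type always has a_A,1 = a_B,1 = 1; presets fix type 2's
efficiencies to the studied values for each phenomenon, and
``generate_fixtures`` adds deterministic random draws from the comparative-
advantage quadrant (a_A,2 <= 1 <= a_B,2) for property tests.
"""

from __future__ import annotations

import numpy as np

from .metapopulation import MetapopConfig
from .model import CellTypeParams, TradeParams

REFERENCE_TYPE = CellTypeParams(a_A=1.0, a_B=1.0)


def trade_params(a_A2: float, a_B2: float, D: float = 3.0,
                 mu: float = 0.05) -> TradeParams:
    """Reference type 1 against a type 2 with the given efficiencies."""
    return TradeParams(type1=REFERENCE_TYPE,
                       type2=CellTypeParams(a_A=a_A2, a_B=a_B2), D=D, mu=mu)


def scenario_example_params() -> TradeParams:
    """The four-scenario example: a_A,2 = 0.67, a_B,2 = 1.49."""
    return trade_params(0.67, 1.49)


def efficiency_curse_params(a_B2: float = 3.0) -> TradeParams:
    """Efficiency-curse cross-section: a_A,2 fixed at 0.67."""
    return trade_params(0.67, a_B2)


def inefficiency_curse_params(a_A2: float = 0.5) -> TradeParams:
    """Inefficiency-curse cross-section: a_B,2 fixed at 1.82."""
    return trade_params(a_A2, 1.82)


def serial_b_mutant_config(**overrides) -> MetapopConfig:
    """Serial B-efficiency mutants: a_B,2 = 2, 4, 10, 20 at a_A,2 = 0.67."""
    variants = (REFERENCE_TYPE,) + tuple(
        CellTypeParams(a_A=0.67, a_B=a_B) for a_B in (2.0, 4.0, 10.0, 20.0))
    return MetapopConfig(variants=variants, **overrides)


def serial_a_mutant_config(**overrides) -> MetapopConfig:
    """Serial A-efficiency mutants: a_A,2 = 0.2, 0.57, 0.625, 0.71 at a_B,2 = 1.82."""
    variants = (REFERENCE_TYPE,) + tuple(
        CellTypeParams(a_A=a_A, a_B=1.82) for a_A in (0.2, 0.57, 0.625, 0.71))
    return MetapopConfig(variants=variants, **overrides)


def manipulator_config(**overrides) -> MetapopConfig:
    """Type 1, ancestral type 2 and a manipulator type-2 strain (same efficiencies)."""
    variants = (REFERENCE_TYPE,
                CellTypeParams(a_A=0.67, a_B=1.49),
                CellTypeParams(a_A=0.67, a_B=1.49, manipulator=True))
    return MetapopConfig(variants=variants, **overrides)


PRESETS = {
    "efficiency_curse": efficiency_curse_params,
    "inefficiency_curse": inefficiency_curse_params,
    "scenario_example": scenario_example_params,
    "serial_b_mutants": serial_b_mutant_config,
    "serial_a_mutants": serial_a_mutant_config,
    "manipulator": manipulator_config,
}


def generate_fixtures(seed: int = 0) -> dict[str, TradeParams]:
    """Deterministic parameter sets spanning all regimes and patterns.

    Named cases cover coexistence, either type fixing, neutrality and the
    specialization patterns; ``random_i`` draws come from the comparative-
    advantage quadrant.
    """
    rng = np.random.default_rng(seed)
    fixtures: dict[str, TradeParams] = {
        "neutral": trade_params(1.0, 1.0),
        "coexist_example": scenario_example_params(),
        "type2_fixes": trade_params(1.2, 1.2),
        "type1_fixes": trade_params(0.8, 0.8),
        "spec_both": trade_params(0.4, 2.5),
        "spec_type1_only": trade_params(0.67, 10.0),
        "spec_neither": trade_params(0.95, 1.05),
        "no_diffusion": trade_params(0.67, 1.49, D=0.0),
    }
    for i in range(8):
        a_A2 = float(rng.uniform(0.1, 1.0))
        a_B2 = float(rng.uniform(1.0, 3.0))
        fixtures[f"random_{i}"] = trade_params(round(a_A2, 4), round(a_B2, 4))
    return fixtures
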
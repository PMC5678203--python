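"""Frequency dynamics over the production game.

Frequencies evolve by replicator dynamics dN_i/dt = zeta*g_i*N_i with the
chemistry and the production regulation both quasi-static: at every frequency
the concentrations are at steady state and the allocations follow the active
regulation scenario.  A coexistence equilibrium is a root of the growth gap
g1*(n1) - g2*(n1); the gap changing sign from positive to negative makes the
root stable.  Count trajectories are integrated in log space (fold changes of
order 10^3 are routine).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from scipy.special import expit

from .game import (
    EquilibriumError,
    GameSolution,
    RegulationScenario,
    solve_scenario,
)
from .model import PopulationState, TradeParams

EXTINCTION_EPS = 1e-6  # frequency threshold for boundary classification
_NEUTRAL_TOL = 1e-9
_SPECIAL_TOL = 1e-6


class Regime(str, Enum):
    COEXIST = "coexist"
    TYPE1_FIXES = "type1_fixes"
    TYPE2_FIXES = "type2_fixes"
    NEUTRAL = "neutral"


class Specialization(str, Enum):
    BOTH = "both"
    TYPE1_ONLY = "type1_only"
    TYPE2_ONLY = "type2_only"
    NEITHER = "neither"


@dataclass(frozen=True)
class EquilibriumResult:
    n1_star: float
    solution: GameSolution
    g_star: float
    regime: Regime
    specialization: Specialization
    stable: bool


@dataclass(frozen=True)
class Trajectory:
    times: np.ndarray
    n1: np.ndarray
    lnN1: np.ndarray
    lnN2: np.ndarray
    g1: np.ndarray
    g2: np.ndarray


@dataclass(frozen=True)
class OvertakeResult:
    crossed: bool
    t_cross: float | None
    fold_growth: float | None


def growth_gap(n1: float, scenario: RegulationScenario,
               params: TradeParams) -> float:
    """g1*(n1) - g2*(n1) under the scenario's production rule."""
    sol = solve_scenario(scenario, n1, params)
    return sol.steady.g1 - sol.steady.g2


class ScenarioCurves:
    """Steady-state growth rates of both types across frequencies.

    Precomputes the scenario's (g1*, g2*) on an n1 grid (warm-starting the
    joint optimizer for control scenarios) and interpolates with monotone
    cubics, giving a cheap smooth right-hand side for replicator integration.
    """

    def __init__(self, scenario: RegulationScenario, params: TradeParams,
                 points: int = 201, eps: float = EXTINCTION_EPS):
        self.scenario = scenario
        self.params = params
        self.n1_grid = np.linspace(eps, 1.0 - eps, points)
        g1s = np.empty(points)
        g2s = np.empty(points)
        f1s = np.empty(points)
        f2s = np.empty(points)
        start = None
        for i, n1 in enumerate(self.n1_grid):
            sol = solve_scenario(scenario, n1, params, start=start)
            g1s[i], g2s[i] = sol.steady.g1, sol.steady.g2
            f1s[i], f2s[i] = sol.profile.f1, sol.profile.f2
            start = (f1s[i], f2s[i])
        self.g1_grid, self.g2_grid = g1s, g2s
        self.f1_grid, self.f2_grid = f1s, f2s
        self._g1 = PchipInterpolator(self.n1_grid, g1s)
        self._g2 = PchipInterpolator(self.n1_grid, g2s)

    def g1(self, n1):
        return self._g1(np.clip(n1, self.n1_grid[0], self.n1_grid[-1]))

    def g2(self, n1):
        return self._g2(np.clip(n1, self.n1_grid[0], self.n1_grid[-1]))

    def gap(self, n1):
        return self.g1(n1) - self.g2(n1)


def population_equilibrium(scenario: RegulationScenario, params: TradeParams,
                           scan_points: int = 41,
                           eps: float = EXTINCTION_EPS) -> EquilibriumResult:
    """Stable frequency equilibrium of the replicator dynamics.

    Scans the growth gap on [eps, 1-eps], refines each downward sign change
    by bisection, and classifies the regime.  Several stable roots violate
    the model's uniqueness claim and raise :class:`EquilibriumError` rather
    than being silently resolved.
    """
    grid = np.linspace(eps, 1.0 - eps, scan_points)
    start = None
    gaps = np.empty(scan_points)
    for i, n1 in enumerate(grid):
        sol = solve_scenario(scenario, n1, params, start=start)
        gaps[i] = sol.steady.g1 - sol.steady.g2
        start = (sol.profile.f1, sol.profile.f2)

    if np.max(np.abs(gaps)) < _NEUTRAL_TOL:
        sol = solve_scenario(scenario, 0.5, params)
        return EquilibriumResult(0.5, sol, sol.steady.g1, Regime.NEUTRAL,
                                 _specialization(sol), True)

    gap_fn = lambda n1: growth_gap(n1, scenario, params)
    stable_roots = []
    for i in np.flatnonzero(np.diff(np.sign(gaps)) != 0):
        root = brentq(gap_fn, grid[i], grid[i + 1], xtol=1e-9)
        if gaps[i] > 0 > gaps[i + 1]:
            stable_roots.append(root)
    if len(stable_roots) > 1:
        raise EquilibriumError(
            f"multiple stable coexistence equilibria: {stable_roots}")
    if len(stable_roots) == 1:
        n1_star = stable_roots[0]
        sol = solve_scenario(scenario, n1_star, params)
        return EquilibriumResult(n1_star, sol, 0.5 * (sol.steady.g1 + sol.steady.g2),
                                 Regime.COEXIST, _specialization(sol), True)
    # no stable interior root: boundary regime from the gap's prevailing sign
    if gaps[0] < 0 and gaps[-1] > 0:
        raise EquilibriumError(
            "bistable boundary equilibria (gap < 0 at low n1, > 0 at high n1)")
    if gaps[-1] > 0:
        n1_star, which = 1.0, 1
    else:
        n1_star, which = 0.0, 2
    sol = solve_scenario(scenario, n1_star, params)
    regime = Regime.TYPE1_FIXES if which == 1 else Regime.TYPE2_FIXES
    g_star = sol.steady.g1 if which == 1 else sol.steady.g2
    return EquilibriumResult(n1_star, sol, g_star, regime,
                             _specialization(sol), True)


def _specialization(sol: GameSolution) -> Specialization:
    s1 = sol.profile.f1 <= _SPECIAL_TOL or sol.profile.f1 >= 1.0 - _SPECIAL_TOL
    s2 = sol.profile.f2 <= _SPECIAL_TOL or sol.profile.f2 >= 1.0 - _SPECIAL_TOL
    if s1 and s2:
        return Specialization.BOTH
    if s1:
        return Specialization.TYPE1_ONLY
    if s2:
        return Specialization.TYPE2_ONLY
    return Specialization.NEITHER


def replicator_trajectory(initial: PopulationState,
                          scenario: RegulationScenario,
                          params: TradeParams,
                          t_max: float,
                          curves: ScenarioCurves | None = None,
                          curve_points: int = 201,
                          n_out: int = 400) -> Trajectory:
    """Integrate dN_i/dt = zeta*g_i*N_i with quasi-static chemistry and game.

    Counts are carried in log space; the scenario's growth curves are
    precomputed over frequency unless supplied.
    """
    if initial.N1 is not None:
        if initial.N1 <= 0 or initial.N2 <= 0:
            raise ValueError("initial counts must be positive")
        ln0 = np.log([initial.N1, initial.N2])
    else:
        if not 0.0 < initial.n1 < 1.0:
            raise ValueError("initial frequency must be interior without counts")
        ln0 = np.log([initial.n1, 1.0 - initial.n1])
    if curves is None:
        curves = ScenarioCurves(scenario, params, points=curve_points)
    zeta = initial.zeta

    def rhs(t, y):
        n1 = expit(y[0] - y[1])
        return [zeta * curves.g1(n1), zeta * curves.g2(n1)]

    sol = solve_ivp(rhs, (0.0, t_max), ln0, method="RK45", rtol=1e-10,
                    atol=1e-12, dense_output=True)
    if not sol.success:
        raise RuntimeError(f"replicator integration failed: {sol.message}")
    times = np.linspace(0.0, t_max, n_out)
    y = sol.sol(times)
    n1 = expit(y[0] - y[1])
    return Trajectory(times=times, n1=n1, lnN1=y[0], lnN2=y[1],
                      g1=np.asarray(curves.g1(n1)), g2=np.asarray(curves.g2(n1)))


def overtake_time(params: TradeParams,
                  scenario_a: RegulationScenario,
                  scenario_b: RegulationScenario,
                  initial: PopulationState,
                  focal_type: int = 1,
                  horizon: float = 100.0,
                  curve_points: int = 301,
                  curves_a: ScenarioCurves | None = None,
                  curves_b: ScenarioCurves | None = None) -> OvertakeResult:
    """First time the focal type's count under scenario A exceeds scenario B.

    Both copies start from the same state; times are in 1/zeta units.  The
    log-count difference is integrated jointly and the upward zero crossing
    located by the integrator's event detection.  Identical dynamics yield an
    explicit no-crossing result.
    """
    if focal_type not in (1, 2):
        raise ValueError("focal_type must be 1 or 2")
    if curves_a is None:
        curves_a = ScenarioCurves(scenario_a, params, points=curve_points)
    if curves_b is None:
        curves_b = ScenarioCurves(scenario_b, params, points=curve_points)
    if initial.N1 is not None:
        ln0 = np.log([initial.N1, initial.N2])
    else:
        ln0 = np.log([initial.n1, 1.0 - initial.n1])
    zeta = initial.zeta
    idx = 0 if focal_type == 1 else 1

    def rhs(t, y):
        na = expit(y[0] - y[1])
        nb = expit(y[2] - y[3])
        return [zeta * curves_a.g1(na), zeta * curves_a.g2(na),
                zeta * curves_b.g1(nb), zeta * curves_b.g2(nb)]

    sol = solve_ivp(rhs, (0.0, horizon / zeta), np.concatenate([ln0, ln0]),
                    method="RK45", rtol=1e-10, atol=1e-12,
                    dense_output=True, max_step=0.5 / zeta)
    if not sol.success:
        raise RuntimeError(f"paired integration failed: {sol.message}")

    # locate the first genuine upward zero crossing of the log-count deficit;
    # identical dynamics keep the difference at rounding level (no crossing)
    times = np.linspace(0.0, horizon / zeta, 4001)
    diff = sol.sol(times)[idx] - sol.sol(times)[idx + 2]
    deficit = np.flatnonzero(diff < -1e-9)
    if len(deficit) == 0:
        return OvertakeResult(crossed=False, t_cross=None, fold_growth=None)
    after = np.flatnonzero(diff[deficit[0]:] >= 0.0)
    if len(after) == 0:
        return OvertakeResult(crossed=False, t_cross=None, fold_growth=None)
    i = deficit[0] + after[0]
    t_cross = brentq(lambda t: sol.sol(t)[idx] - sol.sol(t)[idx + 2],
                     times[i - 1], times[i], xtol=1e-12)
    y = sol.sol(t_cross)
    fold = float(np.exp(y[idx] - ln0[idx]))
    return OvertakeResult(crossed=True, t_cross=float(t_cross) * zeta,
                          fold_growth=fold)
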
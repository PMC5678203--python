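"""Production regulation: best responses, Nash equilibrium, control, coordination.

Each cell is an infinitesimal price-taker with respect to the population-mean
metabolite pool Abar = n1*A1 + n2*A2 (and likewise Bbar): in the concentration
dynamics every cell exchanges with that pool at rate D, so a single cell's
allocation choice cannot move the pool.  A type's best response maximizes its
own steady-state growth against the pool; at an interior optimum the marginal
value of budget spent on either metabolite is equal, which reduces to

    a_A,i * B_i = a_B,i * A_i

evaluated at the cell's own steady state (the growth derivative along the
budget line has this sign and is strictly decreasing in f).  A competitive
Nash equilibrium is a profile where both complementarity conditions hold
simultaneously on the full steady state; it is found by nested bracketing
bisection, then certified by a brute-force no-deviation scan.

Control scenarios instead pick both allocations jointly to maximize one
type's fully re-equilibrated growth (the controller internalizes every
feedback), and the coordination benchmark maximizes the common growth rate
over allocations and frequency subject to equal growth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import brentq, minimize, minimize_scalar

from .model import CellTypeParams, ProductionProfile, TradeParams
from .steady_state import (
    SteadyStateResult,
    solve_steady_state,
    steady_state_batch,
)

logger = logging.getLogger(__name__)

NASH_FTOL = 1e-10
DEVIATION_SLACK = 1e-8


class EquilibriumError(RuntimeError):
    """Equilibrium computation failed; message carries the trace."""


class RegulationScenario(str, Enum):
    """How production is regulated while frequencies evolve."""

    COMPETITIVE_NASH = "competitive_nash"
    CONTROL_BY_1 = "control_by_1"
    CONTROL_BY_2 = "control_by_2"
    FULL_SPECIALIZATION = "full_specialization"


@dataclass(frozen=True)
class GameSolution:
    profile: ProductionProfile
    steady: SteadyStateResult
    scenario: RegulationScenario

    def growth(self, which: int) -> float:
        return self.steady.g1 if which == 1 else self.steady.g2


def _states(f1, f2, n1, params):
    """Batch steady states for arrays of allocation fractions."""
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    c1, c2 = params.type1, params.type2
    b = params.budget
    return steady_state_batch(b * f1 * c1.a_A, b * (1.0 - f1) * c1.a_B,
                              b * f2 * c2.a_A, b * (1.0 - f2) * c2.a_B,
                              n1, params)


def _growths(f1, f2, n1, params):
    st = _states(f1, f2, n1, params)
    return (params.type1.k * st[:, 0] * st[:, 1],
            params.type2.k * st[:, 2] * st[:, 3])


def _psi(which: int, f1: float, f2: float, n1: float, params: TradeParams) -> float:
    """Marginal-value imbalance a_A*B - a_B*A of one type at the full steady state."""
    st = _states(f1, f2, n1, params)[0]
    if which == 1:
        return params.type1.a_A * st[1] - params.type1.a_B * st[0]
    return params.type2.a_A * st[3] - params.type2.a_B * st[2]


def pool_concentrations(steady: SteadyStateResult, n1: float) -> tuple[float, float]:
    """Population-mean metabolite pool (Abar, Bbar)."""
    c = steady.conc
    return (n1 * c.A1 + (1 - n1) * c.A2, n1 * c.B1 + (1 - n1) * c.B2)


def deviation_growth(f, cell: CellTypeParams, pool: tuple[float, float],
                     params: TradeParams):
    """Growth of a lone deviant cell allocating ``f`` against a fixed pool.

    The deviant's internal steady state sees effective supplies
    sA = p_A + D*Abar, sB = p_B + D*Bbar with effective loss lambda = D + mu;
    its growth is the smaller root of
    s^2*k*g^2 - (s*k*(sA+sB) + lambda^2)*g + k*sA*sB = 0.
    Vectorized over ``f``.
    """
    if cell.s_A != cell.s_B:
        raise EquilibriumError("deviation payoff requires s_A == s_B")
    f = np.asarray(f, dtype=float)
    Abar, Bbar = pool
    lam = params.D + params.mu
    sA = params.budget * f * cell.a_A + params.D * Abar
    sB = params.budget * (1.0 - f) * cell.a_B + params.D * Bbar
    s, k = cell.s_A, cell.k
    if s == 0.0:
        return k * sA * sB / (lam * lam)
    a = s * s * k
    b = -(s * k * (sA + sB) + lam * lam)
    c = k * sA * sB
    disc = np.sqrt(np.maximum(b * b - 4.0 * a * c, 0.0))
    return 2.0 * c / (-b + disc)  # smaller root, cancellation-safe


def best_response(which: int, opponent_f: float, n1: float,
                  params: TradeParams) -> float:
    """Allocation fraction maximizing one type's growth against the pool.

    Self-consistent: the responder's own contribution to the pool moves with
    its choice, so the condition is solved on the full steady state with the
    opponent's profile fixed.  Boundary optima are returned exactly.
    """
    if not 0.0 <= opponent_f <= 1.0:
        raise ValueError(f"opponent fraction must lie in [0,1], got {opponent_f}")

    if which == 1:
        phi = lambda f: _psi(1, f, opponent_f, n1, params)
    elif which == 2:
        phi = lambda f: _psi(2, opponent_f, f, n1, params)
    else:
        raise ValueError(f"type index must be 1 or 2, got {which}")
    if phi(1.0) >= 0.0:
        return 1.0
    if phi(0.0) <= 0.0:
        return 0.0
    return brentq(phi, 0.0, 1.0, xtol=1e-12)


def nash_equilibrium(n1: float, params: TradeParams,
                     seed_profile: ProductionProfile | None = None,
                     check: bool = True) -> GameSolution:
    """Competitive equilibrium: both types' allocations are mutual best responses.

    Solved as a nested complementarity problem — the inner level finds type
    1's best response to f2, the outer level zeroes type 2's marginal
    imbalance along that curve — and certified by :func:`verify_nash`.  The
    ``seed_profile`` is accepted for interface compatibility with warm-started
    sweeps; the bracketing solve is deterministic and does not need it.
    """

    c1, c2 = params.type1, params.type2
    if (c1.a_A, c1.a_B, c1.k, c1.s_A, c1.s_B) == (c2.a_A, c2.a_B, c2.k, c2.s_A, c2.s_B):
        # identical types: the symmetric branch is canonical — an iteration
        # started from equal allocations preserves the symmetry, and it keeps
        # identical strains exactly neutral.  Asymmetric labor-split
        # equilibria coexist but need a symmetry-breaking perturbation.
        sym = _symmetric_nash(n1, params)
        if sym is not None:
            return sym

    def outer(f2: float) -> float:
        return _psi(2, best_response(1, f2, n1, params), f2, n1, params)

    if outer(0.0) <= 0.0:
        f2 = 0.0
    elif outer(1.0) >= 0.0:
        f2 = 1.0
    else:
        f2 = brentq(outer, 0.0, 1.0, xtol=1e-12)
    f1 = best_response(1, f2, n1, params)
    sol = _solution(f1, f2, n1, params, RegulationScenario.COMPETITIVE_NASH)
    if check and not verify_nash(sol, n1, params, grid_step=0.01):
        sol = _nash_by_scan(n1, params)
    return sol


def _symmetric_nash(n1: float, params: TradeParams) -> GameSolution | None:
    """Equal-allocation equilibrium of two identical types (or None)."""

    def phi(f: float) -> float:
        return _psi(1, f, f, n1, params)

    if phi(1.0) >= 0.0:
        f = 1.0
    elif phi(0.0) <= 0.0:
        f = 0.0
    else:
        f = brentq(phi, 0.0, 1.0, xtol=1e-12)
    sol = _solution(f, f, n1, params, RegulationScenario.COMPETITIVE_NASH)
    return sol if verify_nash(sol, n1, params, grid_step=0.01) else None


def _nash_by_scan(n1: float, params: TradeParams) -> GameSolution:
    """Fallback: scan f2 for all outer sign changes (non-monotone safeguard)."""
    grid = np.linspace(0.0, 1.0, 101)
    vals = np.array([_psi(2, best_response(1, f2, n1, params), f2, n1, params)
                     for f2 in grid])
    candidates = []
    if vals[0] <= 0.0:
        candidates.append(0.0)
    if vals[-1] >= 0.0:
        candidates.append(1.0)
    for i in np.flatnonzero(np.diff(np.sign(vals)) != 0):
        candidates.append(brentq(
            lambda f2: _psi(2, best_response(1, f2, n1, params), f2, n1, params),
            grid[i], grid[i + 1], xtol=1e-12))
    verified = []
    for f2 in candidates:
        f1 = best_response(1, f2, n1, params)
        sol = _solution(f1, f2, n1, params, RegulationScenario.COMPETITIVE_NASH)
        if verify_nash(sol, n1, params, grid_step=0.01):
            verified.append(sol)
    if not verified:
        raise EquilibriumError(
            f"no verified Nash equilibrium at n1={n1}; outer residuals "
            f"ranged over [{vals.min():.3g}, {vals.max():.3g}]")
    if len(verified) > 1:
        logger.warning("multiple Nash equilibria at n1=%s: %s", n1,
                       [(s.profile.f1, s.profile.f2) for s in verified])
    return verified[0]


def _solution(f1, f2, n1, params, scenario) -> GameSolution:
    profile = ProductionProfile(f1=float(f1), f2=float(f2))
    return GameSolution(profile=profile,
                        steady=solve_steady_state(profile, n1, params),
                        scenario=scenario)


def verify_nash(sol: GameSolution, n1: float, params: TradeParams,
                grid_step: float = 0.01) -> bool:
    """Brute-force no-deviation check against the equilibrium pool.

    True iff no allocation on the deviation grid raises either type's
    price-taking growth above its equilibrium value (plus slack).
    """
    if not sol.steady.converged:
        return False
    pool = pool_concentrations(sol.steady, n1)
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    g1_dev = deviation_growth(grid, params.type1, pool, params)
    g2_dev = deviation_growth(grid, params.type2, pool, params)
    g1_eq = deviation_growth(sol.profile.f1, params.type1, pool, params)
    g2_eq = deviation_growth(sol.profile.f2, params.type2, pool, params)
    return bool(np.max(g1_dev) <= g1_eq + DEVIATION_SLACK
                and np.max(g2_dev) <= g2_eq + DEVIATION_SLACK)


def controlled_profile(controller: int, n1: float, params: TradeParams,
                       start: tuple[float, float] | None = None) -> GameSolution:
    """Both allocations chosen to maximize the controller's growth.

    Joint optimization over [0,1]^2 of the controller's fully re-equilibrated
    steady-state growth: vectorized coarse grid plus Nelder-Mead refinement
    from the best coarse cell (and the optional warm start), with boundary
    snapping — specialization optima sit on the boundary.
    """
    if controller not in (1, 2):
        raise ValueError(f"controller must be 1 or 2, got {controller}")

    def obj(f1, f2):
        g1, g2 = _growths(f1, f2, n1, params)
        return g1 if controller == 1 else g2

    line = np.linspace(0.0, 1.0, 21)

    def line_max(coord: int, other: float) -> tuple[float, float]:
        """Global scan + golden refinement of one coordinate, full [0,1] line."""
        vals = obj(line, other) if coord == 0 else obj(other, line)
        i = int(np.nanargmax(vals))
        lo, hi = line[max(i - 1, 0)], line[min(i + 1, len(line) - 1)]

        def neg(f):
            v = obj(f, other) if coord == 0 else obj(other, f)
            return -float(v[0])

        res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-9})
        cands = [(float(-vals[0]), 0.0), (float(-vals[-1]), 1.0),
                 (float(res.fun), float(res.x))]
        val, f = min(cands)
        if f < 1e-8:
            f = 0.0
        elif f > 1.0 - 1e-8:
            f = 1.0
        return f, -val

    # starts: coarse grid best, plus the sweep warm start if provided
    F1, F2 = np.meshgrid(line, line, indexing="ij")
    g_grid = obj(F1.ravel(), F2.ravel())
    i_best = int(np.nanargmax(g_grid))
    starts = [(float(F1.ravel()[i_best]), float(F2.ravel()[i_best]))]
    if start is not None:
        starts.insert(0, (float(np.clip(start[0], 0, 1)),
                          float(np.clip(start[1], 0, 1))))

    best = None  # (g, f1, f2)
    for f1, f2 in starts:
        if best is not None and abs(f1 - best[1]) < 1e-6 and abs(f2 - best[2]) < 1e-6:
            continue
        g_prev, g_cur = -np.inf, -np.inf
        for _ in range(50):
            f1, _ = line_max(0, f2)
            f2, g_cur = line_max(1, f1)
            if g_cur - g_prev < 1e-12:
                break
            g_prev = g_cur
        if best is None or g_cur > best[0]:
            best = (g_cur, f1, f2)
    if best is None or not np.isfinite(best[0]):
        raise EquilibriumError(f"controlled-profile optimization failed at n1={n1}")
    scenario = (RegulationScenario.CONTROL_BY_1 if controller == 1
                else RegulationScenario.CONTROL_BY_2)
    return _solution(best[1], best[2], n1, params, scenario)


def verify_controlled(sol: GameSolution, n1: float, params: TradeParams,
                      grid_step: float = 0.01) -> bool:
    """Joint-deviation grid check for a controlled solution."""
    controller = 1 if sol.scenario == RegulationScenario.CONTROL_BY_1 else 2
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    F1, F2 = np.meshgrid(grid, grid, indexing="ij")
    g1, g2 = _growths(F1.ravel(), F2.ravel(), n1, params)
    g = g1 if controller == 1 else g2
    return bool(np.nanmax(g) <= sol.growth(controller) + DEVIATION_SLACK)


def full_specialization_profile(params: TradeParams) -> ProductionProfile:
    """Perfect-coordination convention: type 1 makes only A, type 2 only B."""
    return ProductionProfile(f1=1.0, f2=0.0)


def max_sustainable_growth(
    params: TradeParams, coarse: int = 21,
) -> tuple[float, ProductionProfile, float]:
    """Largest common growth over (n1, f1, f2) subject to g1* = g2*.

    Returns (n1, profile, g).  For each allocation pair the equal-growth
    frequency is bracketed along n1 and refined by bisection; the outer
    problem is a coarse vectorized scan refined by Nelder-Mead.
    """
    eps = 1e-6
    n1_grid = np.linspace(eps, 1.0 - eps, 41)
    f_grid = np.linspace(0.0, 1.0, coarse)
    F1, F2 = np.meshgrid(f_grid, f_grid, indexing="ij")
    f1f, f2f = F1.ravel(), F2.ravel()
    gaps = np.empty((len(n1_grid), len(f1f)))
    gmean = np.empty_like(gaps)
    for i, n1 in enumerate(n1_grid):
        g1, g2 = _growths(f1f, f2f, n1, params)
        gaps[i] = g1 - g2
        gmean[i] = 0.5 * (g1 + g2)

    def common_growth(f1: float, f2: float) -> tuple[float, float] | None:
        def gap(n1):
            g1, g2 = _growths(f1, f2, n1, params)
            return float(g1[0] - g2[0])
        lo, hi = eps, 1.0 - eps
        glo, ghi = gap(lo), gap(hi)
        if np.sign(glo) == np.sign(ghi):
            return None
        n1c = brentq(gap, lo, hi, xtol=1e-12)
        g1, _ = _growths(f1, f2, n1c, params)
        return n1c, float(g1[0])

    best = None  # (g, n1, f1, f2)
    sign_change = np.diff(np.sign(gaps), axis=0) != 0
    for j in range(len(f1f)):
        rows = np.flatnonzero(sign_change[:, j])
        if len(rows) == 0:
            continue
        i = rows[0]
        w = abs(gaps[i, j]) / (abs(gaps[i, j]) + abs(gaps[i + 1, j]) + 1e-300)
        g_est = (1 - w) * gmean[i, j] + w * gmean[i + 1, j]
        if best is None or g_est > best[0]:
            best = (g_est, n1_grid[i], f1f[j], f2f[j])
    if best is None:
        raise EquilibriumError("no allocation admits an equal-growth frequency")

    def neg(x):
        x = np.clip(x, 0.0, 1.0)
        res = common_growth(x[0], x[1])
        return np.inf if res is None else -res[1]

    starts = [np.array(best[2:]), np.array([1.0, 0.0])]
    best_x, best_val = None, np.inf
    for x0 in starts:
        r = minimize(neg, x0, method="Nelder-Mead",
                     options={"xatol": 1e-9, "fatol": 1e-13})
        if r.fun < best_val:
            best_val, best_x = r.fun, np.clip(r.x, 0.0, 1.0)
    best_x[best_x < 1e-7] = 0.0
    best_x[best_x > 1.0 - 1e-7] = 1.0
    if neg(best_x) > best_val + 1e-10:
        best_x = np.clip(best_x, 1e-7, 1.0 - 1e-7)
    res = common_growth(best_x[0], best_x[1])
    if res is None:
        raise EquilibriumError("equal-growth manifold lost during refinement")
    n1_star, g_star = res
    return n1_star, ProductionProfile(f1=float(best_x[0]), f2=float(best_x[1])), g_star


def solve_scenario(scenario: RegulationScenario, n1: float, params: TradeParams,
                   start: tuple[float, float] | None = None) -> GameSolution:
    """Scenario-dispatched production choice at a fixed frequency."""
    if scenario == RegulationScenario.COMPETITIVE_NASH:
        return nash_equilibrium(n1, params)
    if scenario == RegulationScenario.CONTROL_BY_1:
        return controlled_profile(1, n1, params, start=start)
    if scenario == RegulationScenario.CONTROL_BY_2:
        return controlled_profile(2, n1, params, start=start)
    if scenario == RegulationScenario.FULL_SPECIALIZATION:
        profile = full_specialization_profile(params)
        return _solution(profile.f1, profile.f2, n1, params, scenario)
    raise ValueError(f"unknown scenario {scenario!r}")
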
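"""Patch-structured evolutionary dynamics: pairs of founders, growth, dispersal.

Each round, patches are founded by two cells drawn from the global pool,
grow for a fixed time T with the within-patch trade dynamics (competitive
Nash regulation, or controlled regulation when a manipulator founder is
present), and release their cells into a common pool that founds the next
round's patches.  The default "expectation" pairing weighs each unordered
founder pair by its sampling probability (an infinite-patch limit), making
runs fully deterministic; the "stochastic" mode samples a finite number of
patches multinomially from a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .game import RegulationScenario
from .model import CellTypeParams, PopulationState, TradeParams
from .population import ScenarioCurves, replicator_trajectory
from .steady_state import isolated_optimal_growth

PairKey = tuple[int, int]

# pair-growth curves depend only on (variants, D, mu, scenario, resolution),
# all hashable and immutable, so they are shared across runs
_CURVES_CACHE: dict = {}


class ExtinctionError(RuntimeError):
    """Every patch yielded zero cells."""


@dataclass(frozen=True)
class MetapopConfig:
    """Settings of the patch-structured simulation.

    ``patch_growth_time`` is in the same nondimensional time units as the
    chemistry (within-patch zeta = 1); the default 12.5 is long enough for a
    well-mixed pair to produce on the order of a thousand cells.
    """

    variants: tuple[CellTypeParams, ...]
    D: float = 3.0
    mu: float = 0.05
    patch_growth_time: float = 12.5
    rounds_max: int = 500
    freq_tol: float = 1e-10
    pairing: str = "expectation"
    n_patches: int = 100_000
    seed: int | None = None
    initial_freqs: tuple[float, ...] | None = None
    curve_points: int = 81

    def __post_init__(self) -> None:
        if len(self.variants) < 1:
            raise ValueError("need at least one variant")
        if self.patch_growth_time <= 0:
            raise ValueError("patch growth time must be positive")
        if self.pairing not in ("expectation", "stochastic"):
            raise ValueError(f"pairing must be expectation|stochastic, got {self.pairing}")
        if self.initial_freqs is not None:
            q = np.asarray(self.initial_freqs, dtype=float)
            if len(q) != len(self.variants):
                raise ValueError("initial_freqs length must match variants")
            if np.any(q < 0) or abs(q.sum() - 1.0) > 1e-9:
                raise ValueError("initial_freqs must be a probability vector")


@dataclass(frozen=True)
class MetapopState:
    """Snapshot after one round: variant frequencies and mean patch yield."""

    round: int
    frequencies: tuple[float, ...]
    total_size: float


@dataclass(frozen=True)
class MetapopRun:
    states: tuple[MetapopState, ...]
    converged: bool
    pair_yields: dict[PairKey, tuple[float, float]] = field(default_factory=dict)

    @property
    def final(self) -> MetapopState:
        return self.states[-1]


def found_patches(frequencies: Sequence[float], config: MetapopConfig,
                  rng: np.random.Generator | None = None
                  ) -> dict[PairKey, float]:
    """Weight of each unordered founder pair (i <= j).

    Expectation mode: exact sampling probabilities 2*q_i*q_j (i != j) and
    q_i**2.  Stochastic mode: multinomial sample of ``n_patches`` patches,
    returned as realized proportions.
    """
    q = np.asarray(frequencies, dtype=float)
    if np.any(q < 0) or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must be a probability vector")
    nv = len(q)
    pairs: list[PairKey] = [(i, j) for i in range(nv) for j in range(i, nv)]
    probs = np.array([q[i] * q[j] if i == j else 2.0 * q[i] * q[j]
                      for i, j in pairs])
    if config.pairing == "stochastic":
        if rng is None:
            rng = np.random.default_rng(config.seed)
        counts = rng.multinomial(config.n_patches, probs / probs.sum())
        probs = counts / config.n_patches
    return {pair: float(w) for pair, w in zip(pairs, probs) if w > 0.0}


def _trade_params(config: MetapopConfig, i: int, j: int) -> TradeParams:
    return TradeParams(type1=config.variants[i], type2=config.variants[j],
                       D=config.D, mu=config.mu)


def _patch_scenario(vi: CellTypeParams, vj: CellTypeParams) -> RegulationScenario:
    # a manipulator founder rewires both types' regulation in its favor;
    # two manipulators neutralize each other and compete
    if vi.manipulator and not vj.manipulator:
        return RegulationScenario.CONTROL_BY_1
    if vj.manipulator and not vi.manipulator:
        return RegulationScenario.CONTROL_BY_2
    return RegulationScenario.COMPETITIVE_NASH


def grow_patch(pair: PairKey, config: MetapopConfig,
               curves_cache: dict | None = None) -> tuple[float, float]:
    """Final count of each founder lineage after time T in one patch.

    Homotypic patches grow exponentially at the lone type's optimal isolated
    rate; heterotypic patches integrate the two-type replicator dynamics from
    one cell of each founder under the patch's regulation scenario.
    """
    i, j = pair
    T = config.patch_growth_time
    if i == j:
        _, g_iso = isolated_optimal_growth(config.variants[i], config.mu)
        n = float(np.exp(g_iso * T))
        return n, n
    vi, vj = config.variants[i], config.variants[j]
    params = _trade_params(config, i, j)
    scenario = _patch_scenario(vi, vj)
    key = (vi, vj, config.D, config.mu, scenario, config.curve_points)
    if curves_cache is None:
        curves_cache = _CURVES_CACHE
    curves = curves_cache.get(key)
    if curves is None:
        curves = ScenarioCurves(scenario, params, points=config.curve_points)
        curves_cache[key] = curves
    traj = replicator_trajectory(
        PopulationState.from_counts(1.0, 1.0), scenario, params,
        t_max=T, curves=curves, n_out=2)
    return float(np.exp(traj.lnN1[-1])), float(np.exp(traj.lnN2[-1]))


def metapop_round(state: MetapopState, config: MetapopConfig,
                  rng: np.random.Generator | None = None,
                  curves_cache: dict | None = None,
                  yields_out: dict[PairKey, tuple[float, float]] | None = None,
                  ) -> MetapopState:
    """One colonize-grow-disperse cycle; returns the pooled next state."""
    weights = found_patches(state.frequencies, config, rng=rng)
    nv = len(config.variants)
    counts = np.zeros(nv)
    total = 0.0
    for (i, j), w in weights.items():
        Ni, Nj = grow_patch((i, j), config, curves_cache=curves_cache)
        if yields_out is not None:
            yields_out[(i, j)] = (Ni, Nj)
        counts[i] += w * Ni
        counts[j] += w * Nj
        total += w * (Ni + Nj)
    if counts.sum() <= 0.0:
        raise ExtinctionError(f"all patches empty at round {state.round + 1}")
    freqs = counts / counts.sum()
    return MetapopState(round=state.round + 1,
                        frequencies=tuple(float(x) for x in freqs),
                        total_size=total)


def run_to_steady(config: MetapopConfig,
                  initial_freqs: Sequence[float] | None = None) -> MetapopRun:
    """Iterate rounds until frequencies settle (or the round cap is hit)."""
    if initial_freqs is None:
        if config.initial_freqs is not None:
            q0 = np.asarray(config.initial_freqs, dtype=float)
        else:
            q0 = np.full(len(config.variants), 1.0 / len(config.variants))
    else:
        q0 = np.asarray(initial_freqs, dtype=float)
    rng = (np.random.default_rng(config.seed)
           if config.pairing == "stochastic" else None)
    curves_cache: dict = {}
    yields: dict[PairKey, tuple[float, float]] = {}
    state = MetapopState(round=0, frequencies=tuple(float(x) for x in q0),
                         total_size=float("nan"))
    states = [state]
    converged = False
    for _ in range(config.rounds_max):
        new = metapop_round(state, config, rng=rng, curves_cache=curves_cache,
                            yields_out=yields)
        delta = np.max(np.abs(np.subtract(new.frequencies, state.frequencies)))
        states.append(new)
        state = new
        if delta < config.freq_tol:
            converged = True
            break
    return MetapopRun(states=tuple(states), converged=converged,
                      pair_yields=yields)


def invasion_experiment(resident_freqs: Sequence[float], invader: int,
                        invader_freq: float, config: MetapopConfig,
                        ) -> tuple[bool, MetapopRun]:
    """Introduce one variant at a given frequency into a resident mixture.

    ``resident_freqs`` spans all variants (the invader's entry is ignored and
    replaced by ``invader_freq``; residents are rescaled to the remainder).
    Success means the invader's final frequency exceeds its introduction
    frequency.
    """
    if not 0.0 < invader_freq < 1.0:
        raise ValueError("invader frequency must lie in (0,1)")
    q = np.asarray(resident_freqs, dtype=float).copy()
    if len(q) != len(config.variants):
        raise ValueError("resident_freqs length must match variants")
    q[invader] = 0.0
    if q.sum() <= 0:
        raise ValueError("no resident population")
    q = q / q.sum() * (1.0 - invader_freq)
    q[invader] = invader_freq
    run = run_to_steady(config, initial_freqs=q)
    success = run.final.frequencies[invader] > invader_freq
    return success, run
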
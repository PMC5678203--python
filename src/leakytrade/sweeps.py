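"""Parameter sweeps over type-2 efficiencies: maps, cross-sections, curves.

The reference type is held at a_A,1 = a_B,1 = 1 and type 2's efficiencies are
swept; each grid cell (or section point) is an independent frequency-
equilibrium computation.  Results come back as tidy DataFrames wrapped with
full provenance metadata, serialized by :mod:`leakytrade.resultsio`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Any

import numpy as np
import pandas as pd

from .game import EquilibriumError, RegulationScenario, solve_scenario
from .model import TradeParams
from .population import EXTINCTION_EPS, population_equilibrium
from .steady_state import isolated_optimal_growth

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SweepAxis:
    """One swept parameter: name ('a_A2' or 'a_B2'), range and count."""

    name: str
    start: float
    stop: float
    count: int

    def __post_init__(self) -> None:
        if self.name not in ("a_A2", "a_B2"):
            raise ValueError(f"sweepable parameters are a_A2, a_B2; got {self.name}")
        if self.count < 2:
            raise ValueError("axis needs at least 2 points")
        if self.start <= 0 or self.stop <= 0:
            raise ValueError("efficiency ranges must be positive")

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.count)


@dataclass(frozen=True)
class SweepGrid:
    """One or two swept efficiency axes around a fixed reference type."""

    axes: tuple[SweepAxis, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.axes) <= 2:
            raise ValueError("a sweep has one or two axes")
        names = [ax.name for ax in self.axes]
        if len(set(names)) != len(names):
            raise ValueError("axes must sweep distinct parameters")

    @classmethod
    def default_quadrant(cls, count: int = 61) -> "SweepGrid":
        """The studied quadrant: a_A2 in [0.05, 1], a_B2 in [1, 3]."""
        return cls(axes=(SweepAxis("a_A2", 0.05, 1.0, count),
                         SweepAxis("a_B2", 1.0, 3.0, count)))


@dataclass
class MapResult:
    """Per-cell equilibrium summaries plus provenance metadata."""

    table: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)


def _cell_params(params: TradeParams, a_A2: float, a_B2: float) -> TradeParams:
    type2 = _dc_replace(params.type2, a_A=a_A2, a_B=a_B2)
    return TradeParams(type1=params.type1, type2=type2, D=params.D,
                       mu=params.mu, budget=params.budget)


def _grid_frame(grid: SweepGrid, params: TradeParams) -> pd.DataFrame:
    if len(grid.axes) == 2:
        ax0, ax1 = grid.axes
        v0, v1 = np.meshgrid(ax0.values, ax1.values, indexing="ij")
        df = pd.DataFrame({ax0.name: v0.ravel(), ax1.name: v1.ravel()})
    else:
        ax0 = grid.axes[0]
        df = pd.DataFrame({ax0.name: ax0.values})
    if "a_A2" not in df:
        df.insert(0, "a_A2", params.type2.a_A)
    if "a_B2" not in df:
        df.insert(1, "a_B2", params.type2.a_B)
    return df


def _equilibrium_rows(grid: SweepGrid, params: TradeParams,
                      scenario: RegulationScenario,
                      scan_points: int) -> pd.DataFrame:
    df = _grid_frame(grid, params)
    records = []
    for a_A2, a_B2 in zip(df["a_A2"], df["a_B2"]):
        cell = _cell_params(params, float(a_A2), float(a_B2))
        try:
            eq = population_equilibrium(scenario, cell, scan_points=scan_points)
            sol = eq.solution
            records.append({
                "regime": eq.regime.value,
                "specialization": eq.specialization.value,
                "n1_star": eq.n1_star,
                "g_star": eq.g_star,
                "f1": sol.profile.f1,
                "f2": sol.profile.f2,
                "p_A1": sol.profile.f1 * cell.type1.a_A,
                "p_B1": (1 - sol.profile.f1) * cell.type1.a_B,
                "p_A2": sol.profile.f2 * cell.type2.a_A,
                "p_B2": (1 - sol.profile.f2) * cell.type2.a_B,
                "error": "",
            })
        except EquilibriumError as exc:  # recorded per cell, not fatal
            logger.warning("equilibrium failed at a_A2=%s a_B2=%s: %s",
                           a_A2, a_B2, exc)
            records.append({k: np.nan for k in
                            ("n1_star", "g_star", "f1", "f2", "p_A1", "p_B1",
                             "p_A2", "p_B2")} |
                           {"regime": "error", "specialization": "error",
                            "error": str(exc)})
    return pd.concat([df, pd.DataFrame.from_records(records)], axis=1)


def _metadata(kind: str, grid: SweepGrid | None, params: TradeParams,
              **extra: Any) -> dict[str, Any]:
    meta: dict[str, Any] = {"kind": kind, "params": params.to_dict()}
    if grid is not None:
        meta["grid"] = [
            {"name": ax.name, "start": ax.start, "stop": ax.stop, "count": ax.count}
            for ax in grid.axes
        ]
    meta.update(extra)
    return meta


def regime_map(grid: SweepGrid, params: TradeParams,
               scan_points: int = 21) -> MapResult:
    """Coexistence / winner classification over the efficiency grid."""
    table = _equilibrium_rows(grid, params, RegulationScenario.COMPETITIVE_NASH,
                              scan_points)
    return MapResult(table, _metadata("regime_map", grid, params,
                                      scan_points=scan_points))


def specialization_map(grid: SweepGrid, params: TradeParams,
                       scan_points: int = 21) -> MapResult:
    """Four-way specialization pattern of the Nash profile at equilibrium."""
    table = _equilibrium_rows(grid, params, RegulationScenario.COMPETITIVE_NASH,
                              scan_points)
    return MapResult(table, _metadata("specialization_map", grid, params,
                                      scan_points=scan_points))


def growth_advantage_map(grid: SweepGrid, params: TradeParams,
                         scan_points: int = 21) -> MapResult:
    """Equilibrium growth minus the clonal growth of the no-diffusion winner.

    The baseline is the larger of the two types' isolated optimal growth
    rates (the type that would fix without exchange).  Positive everywhere
    coexistence holds; at exactly symmetric efficiencies the pair is neutral
    and the difference is zero by construction.
    """
    table = _equilibrium_rows(grid, params, RegulationScenario.COMPETITIVE_NASH,
                              scan_points)
    _, g_iso1 = isolated_optimal_growth(params.type1, params.mu)
    g_iso2 = np.empty(len(table))
    for i, (a_A2, a_B2) in enumerate(zip(table["a_A2"], table["a_B2"])):
        cell2 = _dc_replace(params.type2, a_A=float(a_A2), a_B=float(a_B2))
        _, g_iso2[i] = isolated_optimal_growth(cell2, params.mu)
    table = table.assign(g_isolated_winner=np.maximum(g_iso1, g_iso2),
                         growth_advantage=table["g_star"].to_numpy()
                         - np.maximum(g_iso1, g_iso2))
    return MapResult(table, _metadata("growth_advantage_map", grid, params,
                                      scan_points=scan_points))


def cross_section(axis: SweepAxis, params: TradeParams,
                  scenario: RegulationScenario = RegulationScenario.COMPETITIVE_NASH,
                  scan_points: int = 41) -> MapResult:
    """Equilibrium quantities along one efficiency axis (other held fixed)."""
    table = _equilibrium_rows(SweepGrid(axes=(axis,)), params, scenario,
                              scan_points)
    table = table.assign(n2_star=1.0 - table["n1_star"])
    return MapResult(table, _metadata("cross_section", SweepGrid(axes=(axis,)),
                                      params, scenario=scenario.value,
                                      scan_points=scan_points))


def scenario_curves(params: TradeParams,
                    n1_grid: np.ndarray | None = None) -> MapResult:
    """Both types' growth across frequency for all four regulation scenarios.

    Each scenario's population equilibrium (the g1 = g2 crossing) is marked
    in the ``is_equilibrium`` column at the nearest grid point.
    """
    if n1_grid is None:
        n1_grid = np.linspace(EXTINCTION_EPS, 1.0 - EXTINCTION_EPS, 201)
    n1_grid = np.asarray(n1_grid, dtype=float)
    frames = []
    for scenario in RegulationScenario:
        start = None
        rows = []
        for n1 in n1_grid:
            sol = solve_scenario(scenario, float(n1), params, start=start)
            start = (sol.profile.f1, sol.profile.f2)
            rows.append({"scenario": scenario.value, "n1": float(n1),
                         "g1": sol.steady.g1, "g2": sol.steady.g2,
                         "f1": sol.profile.f1, "f2": sol.profile.f2})
        df = pd.DataFrame(rows)
        gap = df["g1"].to_numpy() - df["g2"].to_numpy()
        df["is_equilibrium"] = False
        try:
            eq = population_equilibrium(scenario, params)
            i_near = int(np.argmin(np.abs(n1_grid - eq.n1_star)))
            df.loc[i_near, "is_equilibrium"] = True
            df["n1_star"] = eq.n1_star
            df["g_star"] = eq.g_star
        except EquilibriumError:
            df["n1_star"] = np.nan
            df["g_star"] = np.nan
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    return MapResult(table, _metadata("scenario_curves", None, params,
                                      n1_points=len(n1_grid)))


def detect_paradox_intervals(x: np.ndarray, y: np.ndarray,
                             min_run: int = 3) -> list[tuple[float, float]]:
    """Intervals where y decreases as x increases (finite differences).

    Runs shorter than ``min_run`` grid steps are treated as numerical noise.
    """
    dy = np.diff(np.asarray(y, dtype=float))
    falling = dy < 0
    intervals: list[tuple[float, float]] = []
    i = 0
    while i < len(falling):
        if falling[i]:
            j = i
            while j + 1 < len(falling) and falling[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                intervals.append((float(x[i]), float(x[j + 1])))
            i = j + 1
        else:
            i += 1
    return intervals
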
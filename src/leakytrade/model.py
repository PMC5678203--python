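"""Core model: domain types, growth law, budget constraint and concentration ODEs.

Two self-sufficient cell types exchange two essential metabolites, A and B,
by passive leakage.  Each cell type ``i`` produces A at rate ``p_A,i`` and B at
rate ``p_B,i`` under a linear budget

    p_A,i / a_A,i + p_B,i / a_B,i <= 1,

where the efficiency ``a_X,i`` is the inverse production cost (the largest
rate achievable when the whole budget goes to metabolite X).  Intracellular
amounts follow mass-action dynamics with cross-cell diffusion at rate ``D``
weighted by the partner's population frequency, first-order loss ``mu``, and
consumption by growth ``g_i = k_i * A_i * B_i``:

    dA1/dt = p_A1 + D*n2*(A2 - A1) - mu*A1 - s_A1*g1
    dB1/dt = p_B1 + D*n2*(B2 - B1) - mu*B1 - s_B1*g1
    dA2/dt = p_A2 + D*n1*(A1 - A2) - mu*A2 - s_A2*g2
    dB2/dt = p_B2 + D*n1*(B1 - B2) - mu*B2 - s_B2*g2

Because the diffusive flux felt by a cell of type 1 is D*n2*(A2-A1)
= D*(Abar - A1) with Abar = n1*A1 + n2*A2, every cell effectively exchanges
with the population-mean pool at rate D.  All quantities are nondimensional.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass


class DomainError(ValueError):
    """An argument violates a model-domain constraint."""


@dataclass(frozen=True)
class CellTypeParams:
    """Production efficiencies, growth constant and stoichiometry of one type.

    Parameters
    ----------
    a_A, a_B:
        Maximum production rates (inverse costs) for metabolites A and B.
    k:
        Growth constant of the mass-action growth law ``g = k*A*B``.
    s_A, s_B:
        Stoichiometric consumption coefficients (amount of metabolite consumed
        per unit growth).
    manipulator:
        Marks a strain that, when present in a patch, sets every founder's
        production so as to maximize its own growth (metapopulation only).
    """

    a_A: float
    a_B: float
    k: float = 1.0
    s_A: float = 1.0
    s_B: float = 1.0
    manipulator: bool = False

    def __post_init__(self) -> None:
        if not (self.a_A > 0 and self.a_B > 0):
            raise DomainError(f"efficiencies must be positive, got a_A={self.a_A}, a_B={self.a_B}")
        if not self.k > 0:
            raise DomainError(f"growth constant must be positive, got k={self.k}")
        if self.s_A < 0 or self.s_B < 0:
            raise DomainError("stoichiometric coefficients must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TradeParams:
    """The full well-mixed two-type system.

    ``D`` is the cell-to-cell diffusion coefficient, ``mu`` the metabolite
    loss rate, and ``budget`` the common production budget cap.  Defaults
    are the reference parameter set (D=3, mu=0.05).
    """

    type1: CellTypeParams
    type2: CellTypeParams
    D: float = 3.0
    mu: float = 0.05
    budget: float = 1.0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise DomainError(f"diffusion coefficient must be nonnegative, got D={self.D}")
        if not self.mu > 0:
            raise DomainError(f"loss rate must be positive, got mu={self.mu}")
        if not self.budget > 0:
            raise DomainError(f"budget must be positive, got {self.budget}")

    def cell(self, index: int) -> CellTypeParams:
        if index == 1:
            return self.type1
        if index == 2:
            return self.type2
        raise DomainError(f"cell type index must be 1 or 2, got {index}")

    def to_dict(self) -> dict:
        return {
            "type1": self.type1.to_dict(),
            "type2": self.type2.to_dict(),
            "D": self.D,
            "mu": self.mu,
            "budget": self.budget,
        }


@dataclass(frozen=True)
class ProductionProfile:
    """Both types' production allocations on the budget boundary.

    ``f_i`` is the fraction of type i's budget spent on metabolite A, so
    ``p_A,i = f_i * a_A,i`` and ``p_B,i = (1 - f_i) * a_B,i``; the budget
    identity then holds exactly.  Growth is strictly increasing in both
    metabolites, so an optimizing cell always spends the full budget;
    interior (wasteful) allocations are representable only through
    :func:`budget_value` for validation.
    """

    f1: float
    f2: float

    def __post_init__(self) -> None:
        for f in (self.f1, self.f2):
            if not 0.0 <= f <= 1.0:
                raise DomainError(f"specialization fraction must lie in [0,1], got {f}")

    def rates(self, params: TradeParams) -> tuple[float, float, float, float]:
        """(p_A1, p_B1, p_A2, p_B2) for the given system parameters.

        A non-unit budget cap scales all rates uniformly (equivalent to
        rescaling both efficiencies), so c_A*p_A + c_B*p_B = budget.
        """
        p_A1, p_B1 = production_from_fraction(self.f1, params.type1)
        p_A2, p_B2 = production_from_fraction(self.f2, params.type2)
        b = params.budget
        return b * p_A1, b * p_B1, b * p_A2, b * p_B2

    def to_dict(self) -> dict:
        return {"f1": self.f1, "f2": self.f2}


@dataclass(frozen=True)
class ConcentrationState:
    """Intracellular metabolite amounts of both types."""

    A1: float
    B1: float
    A2: float
    B2: float

    def __post_init__(self) -> None:
        for name in ("A1", "B1", "A2", "B2"):
            if getattr(self, name) < 0:
                raise DomainError(f"concentration {name} must be nonnegative")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.A1, self.B1, self.A2, self.B2)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PopulationState:
    """Relative frequency of type 1 (and optionally absolute counts).

    ``zeta`` is the population time scale: counts evolve as
    dN_i/dt = zeta * g_i * N_i, slow relative to the chemistry.
    """

    n1: float
    N1: float | None = None
    N2: float | None = None
    zeta: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.n1 <= 1.0:
            raise DomainError(f"n1 must lie in [0,1], got {self.n1}")
        if not self.zeta > 0:
            raise DomainError(f"zeta must be positive, got {self.zeta}")
        if (self.N1 is None) != (self.N2 is None):
            raise DomainError("provide both N1 and N2 or neither")
        if self.N1 is not None:
            if self.N1 < 0 or self.N2 < 0:
                raise DomainError("counts must be nonnegative")
            tot = self.N1 + self.N2
            if tot > 0 and abs(self.n1 - self.N1 / tot) > 1e-9:
                raise DomainError("n1 inconsistent with N1/(N1+N2)")

    @property
    def n2(self) -> float:
        return 1.0 - self.n1

    @classmethod
    def from_counts(cls, N1: float, N2: float, zeta: float = 1.0) -> "PopulationState":
        tot = N1 + N2
        if tot <= 0:
            raise DomainError("total count must be positive")
        return cls(n1=N1 / tot, N1=N1, N2=N2, zeta=zeta)


def growth_rate(A: float, B: float, cell: CellTypeParams) -> float:
    """Mass-action growth law g = k*A*B (requires both metabolites)."""
    if A < 0 or B < 0:
        raise DomainError("metabolite amounts must be nonnegative")
    return cell.k * A * B


def production_from_fraction(f: float, cell: CellTypeParams) -> tuple[float, float]:
    """Production rates (p_A, p_B) on the budget boundary at fraction ``f``."""
    if not 0.0 <= f <= 1.0:
        raise DomainError(f"fraction must lie in [0,1], got {f}")
    return f * cell.a_A, (1.0 - f) * cell.a_B


def budget_value(p_A: float, p_B: float, cell: CellTypeParams) -> float:
    """Budget expenditure c_A*p_A + c_B*p_B = p_A/a_A + p_B/a_B."""
    if p_A < 0 or p_B < 0:
        raise DomainError("production rates must be nonnegative")
    return p_A / cell.a_A + p_B / cell.a_B


def ode_rhs(
    conc: ConcentrationState,
    profile: ProductionProfile,
    pop: PopulationState,
    params: TradeParams,
) -> tuple[float, float, float, float]:
    """Time derivatives (dA1, dB1, dA2, dB2) of the concentration dynamics.

    Note the asymmetric weighting: type 1's diffusive flux is proportional to
    the partner frequency n2, and type 2's to n1.
    """
    A1, B1, A2, B2 = conc.as_tuple()
    p_A1, p_B1, p_A2, p_B2 = profile.rates(params)
    n1, n2 = pop.n1, pop.n2
    D, mu = params.D, params.mu
    c1, c2 = params.type1, params.type2
    g1 = growth_rate(A1, B1, c1)
    g2 = growth_rate(A2, B2, c2)
    return (
        p_A1 + D * n2 * (A2 - A1) - mu * A1 - c1.s_A * g1,
        p_B1 + D * n2 * (B2 - B1) - mu * B1 - c1.s_B * g1,
        p_A2 + D * n1 * (A1 - A2) - mu * A2 - c2.s_A * g2,
        p_B2 + D * n1 * (B1 - B2) - mu * B2 - c2.s_B * g2,
    )
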
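"""Quasi-steady-state concentrations of the trade ODEs.

The chemistry is assumed fast relative to population change, so for a given
production profile and frequency the four concentration derivatives vanish.
Setting u_i = A_i - B_i decouples (when each type's two stoichiometric
coefficients are equal) into a 2x2 linear system for (u1, u2) plus two coupled
quadratics in (A1, A2); eliminating A2 leaves a single quartic in A1.  The
solver takes the quartic roots as candidates, Newton-polishes them, filters by
nonnegativity, residual and linear stability, and falls back to
time-integration from the all-zero state (cells start empty — this defines the
canonical root whenever the algebra admits several).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model import (
    CellTypeParams,
    ConcentrationState,
    ProductionProfile,
    TradeParams,
)

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-10
_STABILITY_MARGIN = 1e-7
_INTEGRATION_TIME_CAP = 1e5


class SolverError(RuntimeError):
    """Steady-state solver failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class SteadyStateResult:
    """Steady-state concentrations with the resulting growth rates."""

    conc: ConcentrationState
    g1: float
    g2: float
    residual: float
    converged: bool


def _rhs_raw(y, pA1, pB1, pA2, pB2, n1, D, mu, k1, k2, s1A, s1B, s2A, s2B):
    A1, B1, A2, B2 = y
    n2 = 1.0 - n1
    g1 = k1 * A1 * B1
    g2 = k2 * A2 * B2
    return np.array([
        pA1 + D * n2 * (A2 - A1) - mu * A1 - s1A * g1,
        pB1 + D * n2 * (B2 - B1) - mu * B1 - s1B * g1,
        pA2 + D * n1 * (A1 - A2) - mu * A2 - s2A * g2,
        pB2 + D * n1 * (B1 - B2) - mu * B2 - s2B * g2,
    ])


def _jacobian(y, n1, D, mu, k1, k2, s1A, s1B, s2A, s2B):
    A1, B1, A2, B2 = y
    n2 = 1.0 - n1
    return np.array([
        [-D * n2 - mu - s1A * k1 * B1, -s1A * k1 * A1, D * n2, 0.0],
        [-s1B * k1 * B1, -D * n2 - mu - s1B * k1 * A1, 0.0, D * n2],
        [D * n1, 0.0, -D * n1 - mu - s2A * k2 * B2, -s2A * k2 * A2],
        [0.0, D * n1, -s2B * k2 * B2, -D * n1 - mu - s2B * k2 * A2],
    ])


def _rhs_vec(Y, pA1, pB1, pA2, pB2, n1, D, mu, k1, k2, s1, s2):
    """Vectorized RHS for (M, 4) states with symmetric stoichiometry."""
    A1, B1, A2, B2 = Y[:, 0], Y[:, 1], Y[:, 2], Y[:, 3]
    n2 = 1.0 - n1
    g1 = k1 * A1 * B1
    g2 = k2 * A2 * B2
    return np.stack([
        pA1 + D * n2 * (A2 - A1) - mu * A1 - s1 * g1,
        pB1 + D * n2 * (B2 - B1) - mu * B1 - s1 * g1,
        pA2 + D * n1 * (A1 - A2) - mu * A2 - s2 * g2,
        pB2 + D * n1 * (B1 - B2) - mu * B2 - s2 * g2,
    ], axis=-1)


def _jac_vec(Y, n1, D, mu, k1, k2, s1, s2):
    """Vectorized Jacobians (M, 4, 4) of the concentration dynamics."""
    A1, B1, A2, B2 = Y[:, 0], Y[:, 1], Y[:, 2], Y[:, 3]
    n2 = 1.0 - n1
    M = Y.shape[0]
    J = np.zeros((M, 4, 4))
    J[:, 0, 0] = -D * n2 - mu - s1 * k1 * B1
    J[:, 0, 1] = -s1 * k1 * A1
    J[:, 0, 2] = D * n2
    J[:, 1, 0] = -s1 * k1 * B1
    J[:, 1, 1] = -D * n2 - mu - s1 * k1 * A1
    J[:, 1, 3] = D * n2
    J[:, 2, 0] = D * n1
    J[:, 2, 2] = -D * n1 - mu - s2 * k2 * B2
    J[:, 2, 3] = -s2 * k2 * A2
    J[:, 3, 1] = D * n1
    J[:, 3, 2] = -s2 * k2 * B2
    J[:, 3, 3] = -D * n1 - mu - s2 * k2 * A2
    return J


def _newton_polish(y, args, max_iter=30):
    """Polish a candidate root; returns None on divergence."""
    y = np.asarray(y, dtype=float).copy()
    for _ in range(max_iter):
        f = _rhs_raw(y, *args)
        if np.max(np.abs(f)) < 1e-13:
            return y
        try:
            step = np.linalg.solve(_jacobian(y, *args[4:]), f)
        except np.linalg.LinAlgError:
            return None
        y = y - step
        if not np.all(np.isfinite(y)) or np.max(np.abs(y)) > 1e10:
            return None
    return y if np.max(np.abs(_rhs_raw(y, *args))) < 1e-9 else None


def _positive_quad_root(a, b, c):
    """Nonnegative root of a*x^2 + b*x + c = 0 with a > 0, c <= 0."""
    disc = np.sqrt(np.maximum(b * b - 4.0 * a * c, 0.0))
    return (-b + disc) / (2.0 * a)


def solve_isolated(p_A: float, p_B: float, mu: float, k: float = 1.0,
                   s: float = 1.0) -> tuple[float, float]:
    """Closed-form steady state of a single type with no diffusive partner.

    A - B = (p_A - p_B)/mu and B is the nonnegative root of
    s*k*B**2 + (mu + s*k*(p_A-p_B)/mu)*B - p_B = 0.
    """
    if p_A < 0 or p_B < 0:
        raise ValueError("production rates must be nonnegative")
    if mu <= 0:
        raise ValueError("loss rate must be positive")
    u = (p_A - p_B) / mu
    sk = s * k
    if sk == 0.0:
        B = p_B / mu
    else:
        B = _positive_quad_root(sk, mu + sk * u, -p_B)
    return B + u, B


def _decoupled_candidate(pA1, pB1, pA2, pB2, n1, D, mu, k1, k2, s1, s2):
    """Candidate state for D*n2 == 0: type 1 isolated, type 2 slaved to it."""
    A1, B1 = solve_isolated(pA1, pB1, mu, k1, s1)
    lam = D * n1 + mu
    if lam == mu:  # D == 0 entirely
        A2, B2 = solve_isolated(pA2, pB2, mu, k2, s2)
    else:
        u2 = (pA2 - pB2 + D * n1 * (A1 - B1)) / lam
        sk = s2 * k2
        if sk == 0.0:
            B2 = (pB2 + D * n1 * B1) / lam
        else:
            B2 = _positive_quad_root(sk, lam + sk * u2, -(pB2 + D * n1 * B1))
        A2 = B2 + u2
    return np.array([A1, B1, A2, B2])


def steady_state_batch(pA1, pB1, pA2, pB2, n1: float, params: TradeParams):
    """Vectorized steady-state solve over arrays of production rates.

    All four rate arguments broadcast against each other; ``n1`` is scalar.
    Returns an (N, 4) array of concentrations [A1, B1, A2, B2].  Requires
    s_A == s_B within each type (the symmetric-stoichiometry fast path); use
    :func:`integrate_to_steady` otherwise.
    """
    c1, c2 = params.type1, params.type2
    if c1.s_A != c1.s_B or c2.s_A != c2.s_B:
        raise SolverError("fast path requires s_A == s_B per type")
    D, mu = params.D, params.mu
    k1, k2 = c1.k, c2.k
    s1, s2 = c1.s_A, c2.s_A
    kap1, kap2 = s1 * k1, s2 * k2
    pA1, pB1, pA2, pB2 = np.broadcast_arrays(
        np.atleast_1d(np.asarray(pA1, dtype=float)), pB1, pA2, pB2)
    pA1 = np.ascontiguousarray(pA1, dtype=float)
    pB1 = np.asarray(pB1, dtype=float)
    pA2 = np.asarray(pA2, dtype=float)
    pB2 = np.asarray(pB2, dtype=float)
    n2 = 1.0 - n1

    # swap labels so the elimination divides by the larger diffusion weight
    if D * n2 < D * n1:
        swapped = steady_state_batch(pA2, pB2, pA1, pB1, 1.0 - n1,
                                     _swap_params(params))
        return swapped[:, [2, 3, 0, 1]]

    N = pA1.shape[0]
    out = np.empty((N, 4))
    d1 = pA1 - pB1
    d2 = pA2 - pB2
    det = mu * mu + mu * D
    u1 = ((mu + D * n1) * d1 + D * n2 * d2) / det
    u2 = (D * n1 * d1 + (mu + D * n2) * d2) / det

    roots = None
    if D * n2 > 0.0:
        Dn2, Dn1 = D * n2, D * n1
        alpha = np.full(N, kap1 / Dn2)
        beta = (mu + Dn2 - kap1 * u1) / Dn2
        gam = -pA1 / Dn2
        c = kap2 * u2 - mu - Dn1
        q4 = alpha * alpha
        q3 = 2.0 * alpha * beta
        q2 = beta * beta + 2.0 * alpha * gam
        q1 = 2.0 * beta * gam
        q0 = gam * gam
        P = np.empty((N, 5))
        P[:, 0] = -kap2 * q4
        P[:, 1] = -kap2 * q3
        P[:, 2] = -kap2 * q2 + c * alpha
        P[:, 3] = -kap2 * q1 + c * beta + Dn1
        P[:, 4] = -kap2 * q0 + c * gam + pA2
        Pn = P / P[:, :1]
        comp = np.zeros((N, 4, 4))
        comp[:, 0, :] = -Pn[:, 1:]
        comp[:, 1, 0] = comp[:, 2, 1] = comp[:, 3, 2] = 1.0
        roots = np.linalg.eigvals(comp)

    # assemble candidate states (N, C, 4)
    cand_list = []
    valid_list = []
    if roots is not None:
        A1c = roots.real
        valid_list.append(np.abs(roots.imag) <= 1e-6 * (1.0 + np.abs(roots.real)))
        A2c = alpha[:, None] * A1c * A1c + beta[:, None] * A1c + gam[:, None]
        cand_list.append(np.stack(
            [A1c, A1c - u1[:, None], A2c, A2c - u2[:, None]], axis=-1))
    if roots is None or D * n2 < 1e-3:
        # near-decoupled seed rescues the ill-conditioned elimination
        dec = np.stack([_decoupled_candidate(
            pA1[idx], pB1[idx], pA2[idx], pB2[idx], n1, D, mu, k1, k2, s1, s2)
            for idx in range(N)])
        cand_list.append(dec[:, None, :])
        valid_list.append(np.ones((N, 1), dtype=bool))
    cand = np.concatenate(cand_list, axis=1)
    valid = np.concatenate(valid_list, axis=1)
    C = cand.shape[1]

    # vectorized Newton polish of all valid candidates
    M = N * C
    Y = cand.reshape(M, 4).copy()
    vflat = valid.reshape(M).copy()
    pr = [np.repeat(p, C) for p in (pA1, pB1, pA2, pB2)]
    scal = (n1, D, mu, k1, k2, s1, s2)
    for _ in range(12):
        act = vflat & np.all(np.isfinite(Y), axis=1) & (np.max(np.abs(Y), axis=1) < 1e9)
        if not np.any(act):
            break
        F = _rhs_vec(Y[act], *(p[act] for p in pr), *scal)
        if np.max(np.abs(F)) < 1e-13:
            break
        J = _jac_vec(Y[act], *scal)
        try:
            step = np.linalg.solve(J, F[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack([np.linalg.lstsq(j, f, rcond=None)[0]
                             for j, f in zip(J, F)])
        Y[act] -= step
    ok = vflat & np.all(np.isfinite(Y), axis=1) & np.all(Y >= -1e-7, axis=1)
    if np.any(ok):
        res = np.max(np.abs(_rhs_vec(Y[ok], *(p[ok] for p in pr), *scal)), axis=1)
        ok[np.flatnonzero(ok)[res > 1e-8]] = False
    if np.any(ok):
        eig = np.linalg.eigvals(_jac_vec(Y[ok], *scal))
        ok[np.flatnonzero(ok)[np.max(eig.real, axis=1) > _STABILITY_MARGIN]] = False
    Yc = np.clip(Y, 0.0, None).reshape(N, C, 4)
    ok = ok.reshape(N, C)

    jac_args = (n1, D, mu, k1, k2, s1, s1, s2, s2)
    for idx in range(N):
        good = Yc[idx][ok[idx]]
        if len(good) >= 1:
            distinct = np.max(np.abs(good - good[0]), axis=1) > 1e-6
            if not np.any(distinct):
                out[idx] = good[0]
                continue
        # none admissible, or several distinct stable roots: slow path decides
        args = (pA1[idx], pB1[idx], pA2[idx], pB2[idx]) + jac_args
        out[idx] = _select_root([c for c in cand[idx]], args, jac_args)
    return out


def _swap_params(params: TradeParams) -> TradeParams:
    return TradeParams(type1=params.type2, type2=params.type1,
                       D=params.D, mu=params.mu, budget=params.budget)


def _select_root(candidates, args, jac_args):
    """Polish candidates, keep admissible stable ones, fall back to integration."""
    admissible = []
    for cand in candidates:
        y = _newton_polish(cand, args)
        if y is None or np.any(y < -1e-7):
            continue
        y = np.clip(y, 0.0, None)
        if np.max(np.abs(_rhs_raw(y, *args))) > 1e-8:
            continue
        eig = np.linalg.eigvals(_jacobian(y, *jac_args))
        if np.max(eig.real) > _STABILITY_MARGIN:
            continue
        if not any(np.max(np.abs(y - z)) < 1e-6 for z in admissible):
            admissible.append(y)
    if len(admissible) == 1:
        return admissible[0]
    if len(admissible) > 1:
        logger.warning(
            "multiple stable steady states at p=%s; selecting the one reached "
            "from empty cells", args[:4])
    return _integrate_raw(args)


def _integrate_raw(args, tol=DEFAULT_TOL):
    """Integrate the concentration ODEs from the all-zero state to steady state."""
    y = np.zeros(4)
    t_total = 0.0
    span = 50.0
    while t_total < _INTEGRATION_TIME_CAP:
        sol = solve_ivp(lambda t, y: _rhs_raw(y, *args), (0.0, span), y,
                        method="LSODA", rtol=1e-11, atol=1e-13)
        y = sol.y[:, -1]
        t_total += span
        res = np.max(np.abs(_rhs_raw(y, *args)))
        if res < tol:
            polished = _newton_polish(y, args)
            return polished if polished is not None else y
        span *= 2.0
    raise SolverError(
        f"no steady state within {_INTEGRATION_TIME_CAP} time units",
        residual=float(np.max(np.abs(_rhs_raw(y, *args)))))


def solve_steady_state(
    profile: ProductionProfile,
    n1: float,
    params: TradeParams,
    tol: float = DEFAULT_TOL,
) -> SteadyStateResult:
    """Steady state attracting from empty cells for one profile and frequency."""
    if not 0.0 <= n1 <= 1.0:
        raise ValueError(f"n1 must lie in [0,1], got {n1}")
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    pA1, pB1, pA2, pB2 = profile.rates(params)
    c1, c2 = params.type1, params.type2
    args = (pA1, pB1, pA2, pB2, n1, params.D, params.mu, c1.k, c2.k,
            c1.s_A, c1.s_B, c2.s_A, c2.s_B)
    if c1.s_A == c1.s_B and c2.s_A == c2.s_B:
        y = steady_state_batch(pA1, pB1, pA2, pB2, n1, params)[0]
    else:
        y = _integrate_raw(args, tol=tol)
    residual = float(np.max(np.abs(_rhs_raw(y, *args))))
    conc = ConcentrationState(*np.clip(y, 0.0, None))
    return SteadyStateResult(
        conc=conc,
        g1=c1.k * conc.A1 * conc.B1,
        g2=c2.k * conc.A2 * conc.B2,
        residual=residual,
        converged=residual < tol,
    )


def integrate_to_steady(
    profile: ProductionProfile,
    n1: float,
    params: TradeParams,
    tol: float = DEFAULT_TOL,
) -> SteadyStateResult:
    """Reference path: time-integrate Eq.-style dynamics from empty cells.

    Independent of the algebraic fast path; used as an oracle in tests and as
    the canonical tie-break when the algebra admits several stable roots.
    """
    pA1, pB1, pA2, pB2 = profile.rates(params)
    c1, c2 = params.type1, params.type2
    args = (pA1, pB1, pA2, pB2, n1, params.D, params.mu, c1.k, c2.k,
            c1.s_A, c1.s_B, c2.s_A, c2.s_B)
    y = _integrate_raw(args, tol=tol)
    residual = float(np.max(np.abs(_rhs_raw(y, *args))))
    conc = ConcentrationState(*np.clip(y, 0.0, None))
    return SteadyStateResult(conc, c1.k * conc.A1 * conc.B1,
                             c2.k * conc.A2 * conc.B2, residual, residual < tol)


def isolated_optimal_growth(cell: CellTypeParams, mu: float) -> tuple[float, float]:
    """Budget split maximizing a lone type's steady-state growth.

    The growth derivative along the budget line has the sign of
    a_A*B - a_B*A, which decreases strictly in f, so the optimum is the unique
    sign change (or the boundary where no change occurs).
    """
    if mu <= 0:
        raise ValueError("loss rate must be positive")

    def phi(f: float) -> float:
        A, B = solve_isolated(f * cell.a_A, (1.0 - f) * cell.a_B, mu,
                              cell.k, cell.s_A)
        return cell.a_A * B - cell.a_B * A

    if phi(1.0) >= 0.0:
        f_star = 1.0
    elif phi(0.0) <= 0.0:
        f_star = 0.0
    else:
        f_star = brentq(phi, 0.0, 1.0, xtol=1e-12)
    A, B = solve_isolated(f_star * cell.a_A, (1.0 - f_star) * cell.a_B, mu,
                          cell.k, cell.s_A)
    return f_star, cell.k * A * B
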
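# Methods

## Model

Two microbial cell types, at relative frequencies `n1` and `n2 = 1 - n1`,
each produce two essential metabolites A and B.  Metabolites leak between
cells by passive diffusion, are lost at rate `mu`, and are consumed by
growth.  Intracellular amounts follow

    dA1/dt = p_A1 + D*n2*(A2 - A1) - mu*A1 - s_A1*g1
    dB1/dt = p_B1 + D*n2*(B2 - B1) - mu*B1 - s_B1*g1
    dA2/dt = p_A2 + D*n1*(A1 - A2) - mu*A2 - s_A2*g2
    dB2/dt = p_B2 + D*n1*(B1 - B2) - mu*B2 - s_B2*g2

with mass-action growth `g_i = k_i * A_i * B_i`.  Production is limited by a
linear budget `p_A,i/a_A,i + p_B,i/a_B,i <= 1`; the efficiency `a_X,i` is the
inverse production cost.  Because growth is strictly increasing in both
metabolites and production enters additively, an optimizing cell always
spends its full budget, so allocations live on the boundary simplex
parameterized by the fraction `f_i` of budget spent on A:
`p_A,i = f_i * a_A,i`, `p_B,i = (1 - f_i) * a_B,i`.

Diffusion is cell-to-cell: there is no explicit extracellular compartment.
The flux into a type-1 cell, `D*n2*(A2 - A1)`, equals `D*(Abar - A1)` with
`Abar = n1*A1 + n2*A2`, so every cell effectively exchanges with the
population-mean pool at rate `D`.  This identity drives the game-theoretic
layer below.

### Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `a_A,i`, `a_B,i` | production efficiencies (1/cost) | — | the swept quantities |
| `D` | diffusion coefficient | 3 | smaller `D` favors self-sufficiency |
| `mu` | metabolite loss rate | 0.05 | the analytic frequency limit is exact as `mu -> 0` |
| `k_i` | growth constant | 1 | |
| `s_A,i`, `s_B,i` | stoichiometric consumption | 1 | the algebraic fast path needs `s_A = s_B` per type |
| `zeta` | population time scale | 1 | counts obey `dN_i/dt = zeta*g_i*N_i` |
| `T` | patch growth time (metapopulation) | 12.5 | within-patch `zeta = 1` |

All quantities are nondimensional; no unit-conversion layer exists.

## Quasi-steady-state chemistry

Frequencies change much more slowly than the chemistry, so at any frequency
and allocation the concentrations sit at the steady state of the four ODEs.
With `s_A = s_B` within each type, subtracting each type's two equations
cancels the growth term, leaving a 2x2 *linear* system for the differences
`u_i = A_i - B_i`.  Substituting `B_i = A_i - u_i` reduces the remaining two
equations to coupled quadratics in `(A1, A2)`; eliminating `A2` gives a
single quartic in `A1`.  The solver:

1. computes the quartic's roots as eigenvalues of its companion matrix
   (batched over many allocation vectors at once);
2. labels types so the elimination divides by the larger diffusion weight
   `D*max(n1, n2)` (conditioning); if `D*n2 = 0` the system decouples into
   closed-form quadratics, and for `D*n2 < 1e-3` that decoupled solution is
   added as an extra candidate;
3. Newton-polishes every candidate (vectorized, machine-precision residuals);
4. filters by nonnegativity (tolerance `1e-7`, then clipped), residual
   (`< 1e-8` before the final polish report), and linear stability (largest
   Jacobian eigenvalue real part `< 1e-7`);
5. if no candidate survives, or several *distinct* stable states survive,
   falls back to time integration of the ODEs from the all-zero state.

The all-zero initial state — cells start empty — defines the canonical
branch whenever the algebra admits several stable roots; multiplicity is
logged, never silently resolved.  The integration path
(`integrate_to_steady`) is retained as an independent oracle: the test suite
checks the algebraic and integrated solutions agree to `1e-6` on random
parameter draws.  General stoichiometry (`s_A != s_B`) skips the fast path
and uses the integration solver directly.

An isolated type (no partner flux) has the closed form `A - B = (p_A-p_B)/mu`
with `B` the positive root of `s*k*B^2 + (mu + s*k*u)*B - p_B = 0`.

## Production regulation as a game

Each cell regulates its allocation to maximize its own steady-state growth
"subject to the perceived external conditions": a single cell is
infinitesimal, so it takes the mean pool `(Abar, Bbar)` as given.  A deviant
cell allocating `f` sees effective supplies `sA = f*a_A + D*Abar`,
`sB = (1-f)*a_B + D*Bbar` and effective loss `lambda = D + mu`; its growth is
the smaller root of

    s^2*k*g^2 - (s*k*(sA+sB) + lambda^2)*g + k*sA*sB = 0,

a closed form used for all deviation payoffs.  Differentiating along the
budget line shows `dg/df` has the sign of `a_A*B - a_B*A` evaluated at the
cell's own steady state, and that expression decreases strictly in `f`.  Two
consequences:

* the best response to any pool is unique — the sign change of
  `a_A*B - a_B*A`, or a boundary when no change occurs (boundary optima are
  returned exactly, because specialization optima are boundary optima);
* a competitive Nash equilibrium is a pair `(f1, f2)` at which both types'
  marginal conditions hold simultaneously *on the full steady state* (at the
  fixed point the deviant's internal state coincides with the resident's).

The equilibrium is found as a nested complementarity problem: an inner
bracketing bisection gives type 1's self-consistent best response to any
`f2`, and an outer bisection zeroes type 2's marginal imbalance along that
curve.  Every returned equilibrium is certified by a brute-force
no-deviation scan (`verify_nash`, grid step 0.01, slack `1e-8`) against the
closed-form deviation payoff; if certification fails (non-monotone outer
residual), a 101-point scan collects all sign changes, verifies each, and
reports multiplicity.  A worked consequence of the price-taking structure:
naive alternating best response oscillates (far from equilibrium the best
response is bang-bang, because the surplus metabolite accumulates in the
pool at the `1/mu` scale), which is why the complementarity formulation is
used instead of fixed-point iteration.

**Identical types.** Two identical strains admit asymmetric "labor-split"
equilibria alongside the symmetric one.  The symmetric branch is canonical
(an iteration started from equal allocations preserves the symmetry), and it
keeps identical strains exactly neutral in every downstream computation; the
solver special-cases this.

**Control scenarios.** A controller sets *both* allocations to maximize its
own fully re-equilibrated growth `g_c*(f1, f2, n1)` — here there is no
price-taking: the controller internalizes every feedback.  The joint
optimization uses a coarse vectorized grid plus coordinate-wise line
maximization (global 21-point scan per line, golden refinement, explicit
endpoint candidates).  Coordinate search was chosen over simplex methods
because optima routinely sit on the boundary of `[0,1]^2`, where a clipped
Nelder-Mead simplex degenerates and can track a spurious branch across the
kink where the optimum leaves the boundary.

**Maximum sustainable growth.** The coordination benchmark maximizes the
common growth over `(n1, f1, f2)` subject to `g1* = g2*`.  For fixed
allocations the equal-growth frequency is bracketed on a 41-point scan and
refined by bisection (equality enforced to the bisection tolerance,
`xtol = 1e-12`); the outer problem runs Nelder-Mead from the best coarse
cell and from the full-specialization corner `(1, 0)`.

## Frequency dynamics

Counts evolve as `dN_i/dt = zeta*g_i*N_i` with both the chemistry and the
regulation quasi-static.  The quasi-static approximation is exact by
construction (no fast–slow coupling integrator is used).  Equilibria are
roots of the growth gap `g1*(n1) - g2*(n1)` on `[eps, 1-eps]` with
`eps = 1e-6` the boundary-classification threshold: a 41-point sign scan
(configurable; maps use 15–21 points) plus bisection, classifying the result
as coexistence (downward crossing), fixation (one-signed gap), or neutrality
(`|gap| < 1e-9` everywhere).  Several stable roots would contradict the
model's uniqueness claim and raise an error listing them.  Specialization
labels use `|f - {0,1}| <= 1e-6`.

Trajectories integrate `ln N_i` (fold changes of order `10^3` are routine)
with the scenario's growth curves precomputed on an `n1` grid (201 points by
default; 301 for the overtake computation) and interpolated with monotone
cubics (PCHIP — kinks at specialization onsets are handled without
overshoot).  Control-scenario curves warm-start the joint optimizer from the
neighboring grid point, and the test suite re-checks random curve points
cold.

The overtake computation integrates two copies of the system — one per
regulation scenario — from identical initial states, and locates the first
upward zero crossing of the log-count deficit of the focal type on the dense
solver output (bisection between bracketing samples).  Identical dynamics
leave the deficit at rounding level and report an explicit no-crossing
result rather than an error.  Times are reported in `1/zeta` units.

## Parameter sweeps

The reference type is fixed at `a_A,1 = a_B,1 = 1`; maps sweep type 2's
efficiencies over the comparative-advantage quadrant (default 61x61 over
`[0.05, 1] x [1, 3]`, configurable), cross-sections use 100–201 points.
Cells are independent; results are emitted sorted by grid index, and
identical inputs produce byte-identical CSV output (no timestamps in files,
for exactly that reason).  Decreasing-growth intervals are detected by
finite-difference sign with a minimum run of 3 grid points to suppress
noise.  Per-cell equilibrium failures are recorded in an `error` column, not
raised.

## Metapopulation

Patches are founded by two cells, grow for time `T = 12.5` (within-patch
`zeta = 1`), and disperse into a common pool that founds the next round.
The default *expectation* mode weighs each unordered founder pair `(i, j)`
by its exact sampling probability (`2*q_i*q_j`, or `q_i^2` homotypic) — an
infinite-patch limit that makes every run deterministic; a *stochastic* mode
samples `n_patches` pairs multinomially from a seeded generator for
robustness checks.

* Homotypic patches grow exponentially at the lone type's optimal isolated
  rate: per-founder yield `exp(g_iso * T)`.
* Heterotypic patches integrate the two-type replicator dynamics from one
  cell of each founder under competitive Nash regulation — unless exactly
  one founder is a manipulator strain, in which case both types' production
  is controlled to maximize the manipulator's growth throughout.  Two
  manipulator founders neutralize each other and compete.
* Pair yields depend only on the pair, not on global frequencies, so they
  are computed once (growth curves on an 81-point frequency grid) and
  cached; rounds are then closed-form bookkeeping.
* `total_size` is the pair-weighted mean patch yield, proportional to the
  community growth rate; only ratios and monotonicity of this quantity are
  asserted anywhere.

Rounds iterate until the largest frequency change drops below `freq_tol`
(`1e-10`) or `rounds_max` is hit; which one stopped the run is reported.
Invasion experiments introduce one variant at a configurable frequency
(default 0.01; the manipulator's high-frequency experiments use 0.5),
rescale residents to the remainder, and declare success when the invader's
final frequency exceeds its introduction frequency.

## Numerical choices, in one place

* steady-state residual tolerance `1e-10`; integration fallback budget `1e5`
  time units (doubling spans, LSODA, rtol `1e-11`);
* bisection tolerances: best response and Nash `xtol 1e-12`; frequency
  equilibria `1e-9`; overtake crossing `1e-12`;
* deviation slack `1e-8` in all no-deviation certificates;
* replicator integration RK45 with rtol `1e-10`, atol `1e-12`;
* tie-breaks: identical types take the symmetric equilibrium branch;
  degenerate (equal-value) line-search candidates resolve toward the
  boundary by the candidate ordering.

## Scope and limitations

* Two metabolites, two types per well-mixed compartment; more variants
  coexist only through the patch structure (pairs of founders).
* No returns-to-scale or nonlinear budgets; no alternative growth laws
  beyond configurable `k` and `s`; no punitive or mixed strategies; no
  mutation inside the well-mixed model; no stochastic drift at small counts.
* The iterative frequency-update *path* is not an object of study — only
  its fixed points are; trajectory shapes between equilibria depend on the
  quasi-static assumption.
* Steady-state uniqueness is assumed (and asserted) rather than proven;
  violations raise or log rather than picking silently.
* The expectation-mode metapopulation is an infinite-patch idealization:
  real finite-patch sampling noise (available in stochastic mode) can delay
  or rescue marginal invasions.
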
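# leakytrade

Microbial communities constantly exchange metabolites that leak out of
cells.  When two self-sufficient cell types each produce two essential
metabolites under a finite budget, regulate their production to maximize
their own growth, and reproduce in proportion to that growth, the coupled
system behaves in deeply counterintuitive ways: a strain that gets *better*
at producing a metabolite can end up *rarer*; a population can grow *slower*
after one member becomes *more* efficient; and a strain that seizes control
of its partner's production ends up *outgrown* by populations that stayed
competitive.  `leakytrade` implements this model end to end — quasi-steady-
state chemistry, game-theoretic production regulation, replicator frequency
dynamics, parameter-sweep drivers and a patch-structured metapopulation —
for theoretical ecologists and systems biologists studying cross-feeding,
division of labor and the evolution of metabolic specialization.

## Model

Intracellular metabolite amounts of the two types obey

    dA1/dt = p_A1 + D·n2·(A2 − A1) − μ·A1 − g1
    dB1/dt = p_B1 + D·n2·(B2 − B1) − μ·B1 − g1

(and symmetrically for type 2), with mass-action growth g_i = k_i·A_i·B_i
and a linear production budget p_A,i/a_A,i + p_B,i/a_B,i ≤ 1, where the
efficiency a_X,i is the inverse production cost.  Chemistry is fast:
concentrations sit at steady state for the current allocations and
frequencies (solved exactly via a quartic reduction, with time-integration
from empty cells as the independent oracle).  Regulation is fast too: each
cell allocates its budget to maximize its own steady-state growth given the
pooled metabolite concentrations it perceives, which makes the resident
allocations a Nash equilibrium; at an interior optimum a_A,i·B_i = a_B,i·A_i.
Frequencies then drift by replicator dynamics dN_i/dt = ζ·g_i·N_i until the
steady-state growth rates equalize (coexistence) or one type fixes.
Alternative regulation regimes — both types controlled to maximize one
type's growth, or forced complete specialization — plug into the same
frequency dynamics, and a patch-structured metapopulation (pairs of
founders, fixed growth time, pooled dispersal) tests which behaviors can
actually evolve.

## Worked example

The reference setting: type 1 with a_A,1 = a_B,1 = 1 against a type 2 that
is worse at A and better at B (a_A,2 = 0.67, a_B,2 = 1.49), with D = 3 and
μ = 0.05.

```
$ leakytrade equilibrium --a-a2 0.67 --a-b2 1.49 -o results
regime=coexist n1*=0.622573 g*=0.530311
```

The two types coexist with type 1 at 62.3% of the population, both growing
at 0.5303 — faster than either could alone (0.4659 for type 1 in isolation,
0.4318 for type 2), the benefit of trade.  Now let type 1 seize control of
both types' production to maximize its own growth:

```
$ leakytrade overtake --a-a2 0.67 --a-b2 1.49 -o results
t_cross=13.5613 (1/zeta), fold_growth=1447.4
```

Controlling helps type 1 instantly but erodes its partner and settles at a
slower-growing equilibrium (growth 0.4717 vs 0.5303): a competitive
population started from the same state catches up in type-1 cell count
after 13.56 ζ⁻¹, by which time both have grown about 1447-fold — the curse
of control.

The same library calls are available in Python:

```python
from leakytrade import RegulationScenario, population_equilibrium
from leakytrade.fixtures import scenario_example_params

eq = population_equilibrium(RegulationScenario.COMPETITIVE_NASH, scenario_example_params())
print(eq.n1_star, eq.g_star)   # 0.6225733169160056 0.5303108206934516
```

Other subcommands: `sweep` (regime / specialization / growth-advantage maps
over the efficiency quadrant), `section` (one-dimensional equilibrium
cross-sections), `scenarios` (growth curves of all four regulation regimes
across frequency), `metapop` (patch-structured runs, with presets for the
serial-mutant and manipulator invasion experiments) and `fixtures` (named
parameter sets).  All accept a YAML/JSON config file
(schema: `docs/config_schema.json`); flags override file values.

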
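# sexalloc

Adaptive dynamics of primary sex ratios in frequency-dependent, two-sex,
stage-structured matrix population models.

The core model has five stages — juvenile males `m1`, single adult males
`m2`, juvenile females `f1`, single adult females `f2`, and mated unions
`u` — with union formation driven by a harmonic-mean mating function. The
projection matrix is the average of three continuous-time rate matrices
(union formation `U(p)`, births `B(s1)`, transitions `T`), is homogeneous
of degree zero in abundances, and is integrated on the stage-frequency
simplex to its equilibrium distribution. Evolution of the primary sex
ratio `s1` (the proportion of offspring born male) is analysed with
adaptive dynamics: invasion fitness is the dominant-eigenvalue advantage
of a rare mutant in the resident's equilibrium environment, singular
strategies are roots of the analytic selection gradient, and their
evolutionary/convergence stability is classified from analytic second
derivatives of the dominant eigenvalue obtained via vec/Kronecker matrix
calculus (cross-validated against finite differences in the test suite).

Five offspring-cost interpretations are provided:

| case | interpretation |
|------|----------------|
| 0 | identical sexes |
| 1 | fixed per-birth resource costs `Cm`, `Cf` |
| 2 | mortality during parental investment (costs derived from investment rate `I`) |
| 3 | mortality after parental investment (unit costs) |
| 4 | parental mortality costs `Dm`, `Df` scaled by `c` |

plus a 4-stage no-union contrast model (`--case four-stage`) in which
adults reproduce directly and biased mortality cannot move the singular
sex ratio off one half. Closed-form baselines (equal-investment principle
and its parental-mortality analogue) and the reproductive-value-ratio
identities at singular strategies are implemented alongside.

## CLI

The `sexalloc` entry point exposes six subcommands. Scenarios are
specified either with flags or a YAML config (`--config`); the presets
`productive` (R = 20, d = 0) and `poor` (R = 10, d = 1) fill in the
life-cycle rates, with `--param key=value` overrides.

```bash
# equilibrium stage distribution and growth rate at a fixed sex ratio
sexalloc equilibrium --case 1 --preset productive --cm 0.5 --cf 0.5 --s1 0.5

# locate and classify the singular strategy
sexalloc find-ss --case 1 --preset poor --cm 0.6 --cf 0.4

# stability conditions at a given singular point
sexalloc classify --case 0 --preset productive --s1 0.5

# pairwise invasion plot (long-format CSV + metadata JSON)
sexalloc pip --case 1 --preset poor --cm 0.6 --cf 0.4 --n-grid 41 --out pip.csv

# singular-strategy summaries across a cost grid (Cf = 1 - Cm by default)
sexalloc sweep --case 1 --preset poor --swept-param Cm --grid 0.1:0.9:9 --out sweep.csv

# random valid scenario configs for property testing
sexalloc fixtures --seed 1 --count 5 --out fixtures/
```

## Package layout

- `sexalloc.params` — life-cycle parameters, stage distributions, presets
- `sexalloc.costs` — cost models and closed-form baselines
- `sexalloc.demography` — rate matrices, frequency dynamics, equilibrium
  solver, dominant eigen-triples
- `sexalloc.model` — 5-stage and 4-stage model specifications with
  analytic trait-derivatives of the projection matrix
- `sexalloc.matcalc` — vec/Kronecker utilities, eigenvalue and
  eigenvector derivatives, second-derivative stability conditions
- `sexalloc.dynamics` — invasion fitness, selection gradients, singular
  strategies, classification, pairwise invasion plots
- `sexalloc.cases` — case wiring, reproductive-value identities, sweeps
- `sexalloc.config` / `sexalloc.cli` — validated configs, fixtures, CLI
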
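# coexdd

Models of competing species whose mortality declines with conspecific
density (positive density dependence acting on mortality), and the
consequences for coexistence.

The package implements, in rescaled dimensionless variables:

- **`coexdd.mortality`** — the family of mortality multipliers `D(n)`
  (hyperbolic `1/(1+s·n)` by default; exponential, linear and a
  density-independent control kind behind the same interface) and their
  sensitivities in density and in the decline factor `s`.
- **`coexdd.models`** — right-hand sides of three two-species competition
  models (asymmetric competition, basal-mortality difference, asymmetric
  reproductive interference) and the N-species generalization with
  interaction matrices; plus the exact two-species embedding.
- **`coexdd.equilibria`** — equilibrium location (closed-form where
  available, multi-start root finding otherwise), feasibility, local
  stability via finite-difference Jacobians, rare-invader growth rates, and
  the tristate classification of coexistence (`none` / `local_attractor` /
  `global_attractor`) using invasion analysis plus a probe grid of
  trajectories. Borderline cases raise `InconclusiveClassification` rather
  than guessing.
- **`coexdd.scan`** — (asymmetry, s) parameter-plane sweeps of the
  classification and bisection of the s values at which the class changes.
- **`coexdd.community_gen`** — seeded random species pools for four
  scenarios of asymmetry (competition only / interference only / mortality
  differences only / all), drawn from configurable uniform ranges.
- **`coexdd.simulate`** — windowed ODE integration with an extinction
  threshold (default `1e-3`), the simultaneous-start richness experiment
  and the sequential-introduction assembly experiment.
- **`coexdd.io`**, **`coexdd.cli`** — CSV/JSON outputs with metadata
  sidecars and the `coexdd` command-line interface.

## CLI

```sh
# classify a single parameter point
coexdd classify --model asym-competition --d 0.9 --alpha1 0.5 --s 0.01

# sweep the (alpha1, s) plane and write a CSV class map
coexdd scan --model asym-competition --d 0.9 --x-num 21 --out scan.csv

# bisect the s values where the class changes
coexdd threshold --model asym-competition --d 0.9 --alpha1 0.5 --x-value 0.5

# multispecies richness and assembly experiments
coexdd richness --scenario 3 --species 30 --pools 50 --seed 1 \
    --s 0 --s 10 --s 10000 --out richness.csv
coexdd assembly --scenario 4 --species 20 --pools 20 --seed 1 \
    --s 10000 --intro-density 0.01 --out assembly.csv
```

Defaults for any flag can come from a YAML file via `coexdd --config
cfg.yaml <command> ...`; explicit flags win. Every CSV output gets a
`.meta.json` sidecar echoing the fully resolved configuration.

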
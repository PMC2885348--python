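# androscape

Multi-scale simulator of androgen-regulated prostate epithelium:

1. **Receptor kinetics** (`androscape.kinetics`) — a five-variable mass-action
   ODE of intracellular free androgen receptor (AR), free testosterone (T),
   free DHT, and the two ligand:receptor complexes.  Testosterone enters at an
   empirical influx rate driven by serum testosterone, is converted to DHT by
   5α-reductase (Michaelis–Menten, competitively inhibitable by finasteride),
   and AR production is homeostatic around a total-AR set point `R_t`.
   Steady states are solved in closed form and polished by root-finding;
   long integrations serve as an independent oracle in the tests.
2. **Tissue growth** (`androscape.growth`) — the effective androgen signal
   `C_t = C_TR + 2.4·C_DR` drives a U-shaped oxidative-stress level `S` and
   Hill-type per-capita proliferation/death rates; crowding gives a finite
   equilibrium cell count and a per-capita turnover rate.
3. **Strain evolution** (`androscape.evolution`) — deterministic
   mutation–selection dynamics over `Q` strains differing in `R_t`
   (default 100 states, 15–114 nM), each strain seeing its own kinetic
   steady-state environment, with nearest-neighbour mutation at rate `γ`
   and crowding shared across the whole population.
4. **Calibration** (`androscape.calibration`) — unit conversions,
   binding-equilibrium inversion, influx inference from inhibited-arm
   steady-state data, `(α, β_D)` least-squares fitting, and a synthetic
   two-arm dataset generator for parameter-recovery validation.
5. **Interface** (`androscape.cli`, `androscape.config`) — YAML config,
   validated parameter overrides, and CSV/manifest-producing commands.

Concentrations are in nM and time in hours throughout.

## CLI

```sh
androscape <command> --config cfg.yaml --out outdir [--seed N]
```

Commands:

- `kinetics` — time series + steady states for each configured serum-T level.
- `growth-sweep` — equilibrium cell count over the (T_S, R_t, η) grid.
- `turnover-sweep` — equilibrium per-capita turnover over the same grid.
- `evolve` — mutation–selection runs for every (T_S, η) scenario pair,
  reporting per-state populations and the average AR expression over time.
- `fixtures` — synthetic two-arm tissue dataset from the configured kinetics.
- `calibrate --data tissue.csv` — influx table + saturating-influx fit +
  `(α, β_D)` fit from a tissue dataset CSV.

Each command writes RFC-4180 CSVs plus a `manifest.json` (parameter hash,
seed, versions, wall time).  Identical config + seed gives byte-identical
outputs.  An empty or absent config uses the baseline parameter set.

Example config:

```yaml
kinetics:
  R_t: 45.0
  eta: 10        # effective-K_M multiplier (maps to an inhibitor level)
growth:
  theta1: 30.0
evolution:
  gamma: 1.0e-5
  t_end: 175200  # 20 years, hours
sweep:
  T_S: [1.0, 5.0, 10.0]
  eta: [1.0]
seed: 0
```

## Modelling notes

- The exact printed forms of the proliferation/death signal combinations and
  of the algebraic influx fit are reconstructed: signals combine additively
  with a 1/2 normalisation (the only additive form consistent with the stated
  maximum rates), and the influx uses a two-parameter saturating form
  calibrated once so the baseline steady state lands total intraprostatic DHT
  at 50 nM.  Both reconstructions are isolated behind single functions.
- The mutation rate γ, initial strain distribution, and evolution horizon are
  not externally constrained; defaults are γ = 1e-5 h⁻¹, the whole population
  starting at the state nearest R_t = 45 nM, and a 20-year horizon.  The
  qualitative selection orderings asserted in the tests hold across
  γ ∈ {1e-6, 1e-5, 1e-4} and ±25% growth-parameter perturbations.
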
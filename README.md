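# doppelsim

Stochastic Brownian-dynamics simulations of intracellular nanoparticle
diffusion that replicate an experiment's track statistics particle-for-particle
("Doppelgänger" simulations), together with the downstream analysis used to
quantify intra- and inter-cellular heterogeneity of cytoplasmic viscosity:
MSD power-law fitting, nested variance decomposition, log-space spread
statistics, and ergodicity-breaking analysis.

## What it does

- **`trajectory_model`** — trajectory data model and plain-text tabular I/O
  (canonical nm/ms track tables plus a MOSAIC-ParticleTracker-style dialect),
  minimum-length filtering, and extraction of the *experiment ledger*: per-cell
  lengths and per-track durations that simulations replicate one-to-one.
- **`msd_analysis`** — time-averaged MSD with nonoverlapping windows, ensemble
  averaging, power-law fits `MSD = A (τ/τ₀)^α` with apparent diffusivity
  `D_app = A/(2·n·τ₀)`, velocity autocorrelation, and percentile-bootstrap CIs.
- **`doppelganger_sim`** — fixed-timestep Brownian dynamics in a rectangular
  reflecting cell under four viscosity models (uniform / spatial domains /
  cellular / combined), Stokes–Einstein physical-constants layer, and model
  calibration against target median and variances of log₁₀ diffusivity.
- **`heterogeneity_stats`** — log-space summaries and fold ranges
  (`10^(5σ_log)`), nested ANOVA variance fractions (day/session/cell/track),
  Levene and Wilcoxon rank-sum comparisons, within-cell pair correlations,
  per-cell CV diagnostics.
- **`ergodicity`** — ensemble-averaged vs time-ensemble-averaged MSD, percent
  difference `(EA−TEA)·100/EA`, exponential-plus-plateau decay fits, and
  domain-size scans.
- **`synthetic_experiment`** — synthetic ledgers and hierarchical log-normal
  reference diffusivity distributions matching published summary statistics,
  so every module is testable without external data.

## CLI

```bash
doppelsim synth-stats --n-cells 145 --seed 1 --out ledger.tsv
doppelsim synth-reference --stats ledger.tsv --seed 2 --out reference.tsv
doppelsim simulate --stats ledger.tsv --model combined --lambda-nm 1000 \
    --seed 17 --out tracks.tsv
doppelsim analyze --tracks tracks.tsv --seed 3 --out fits.tsv
doppelsim variance --fits fits.tsv --seed 4 --out variance.json
doppelsim ergodicity --tracks tracks.tsv --seed 5 --out ergodicity.tsv
doppelsim scan-domains --stats ledger.tsv --sizes 100,300,1000 --seed 6 \
    --n-replicates 50 --out scan.tsv
doppelsim calibrate --stats ledger.tsv --reference reference.tsv \
    --lambda-nm 1000 --seed 7 --out calibration.json
```

All outputs are plain-text tables with a JSON provenance header recording the
full configuration and seed; reruns with identical flags are byte-identical.

## Units

Canonical units are nanometers, milliseconds, Kelvin, and piconewtons
everywhere (so viscosity is pN·ms/nm², diffusivity nm²/ms = 10⁻³ µm²/s);
conversions happen only at I/O boundaries.
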
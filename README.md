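# crnode

Hybrid mechanistic/neural modeling of chemical reaction network (CRN)
kinetics: mass-action ODE systems for batch and flow (CSTR) reactors,
augmented with a trainable neural correction term fitted to noisy
concentration time series. The learned correction is decomposed into
per-species contribution series (for diagnosing hidden or misspecified
reactions) and transferred unchanged between experimental settings to
predict oscillation periods and phase diagrams.

## Layout

| module | purpose |
| --- | --- |
| `crnode.crn_model` | declarative reaction networks, mass-action RHS builder, CSTR balance, reaction ablation, conserved moieties, network YAML I/O |
| `crnode.node_core` | neural correction term (stateless LSTM cell + zero-initialized affine readout), augmented RHS, stiff adaptive solving, contribution extraction, checkpoints |
| `crnode.sensitivity` | differentiable fixed-step RK4 integration with a hand-derived discrete adjoint (exact gradients w.r.t. network parameters and rate constants) |
| `crnode.training` | replicate-statistics sampling, masked MSE, AdaBelief optimizer, two-phase curriculum, best-validation checkpointing |
| `crnode.synthetic_data` | ground-truth simulation, replicate Gaussian noise, hidden-interaction scenarios, frozen `toy_oscillator` fixture |
| `crnode.oscillation_analysis` | period estimation, sustained/damped classification, phase-space scans, diagram differencing, period tables |
| `crnode.cli_io` | `crnode` command-line interface, run configuration, lossless CSV round-tripping, JSON-lines run logs |

The built-in 7-species deprotection oscillator ships with two parameter
sets: `toy_oscillator` (fully self-contained, produces a sustained limit
cycle; provenance in `scripts/find_toy_oscillator.py`) and
`terharmsel2023` (a placeholder whose experimentally fitted values must be
supplied by the user via `config/terharmsel2023.yaml`).

## CLI

All subcommands read a single YAML run configuration and write CSV
artifacts plus a JSON-lines log (config hash + seed embedded in every
artifact, so runs are byte-reproducible):

```sh
crnode simulate       --config run.yaml           # ground-truth trajectory CSV
crnode generate-data  --config run.yaml           # + replicate measurement CSV
crnode train          --config run.yaml           # correction checkpoint + loss report
crnode contributions  --config run.yaml           # per-species contribution series
crnode scan           --config run.yaml           # inflow phase-diagram CSV
crnode period-table   --config run.yaml           # periods per (model, setting)
```

Minimal configuration:

```yaml
seed: 1
output_dir: out
scenario: {kind: single_pulse, noise_sd: 0.0005}   # or: oscillation
# optional hidden-interaction emulation (modeling side only):
#   scenario: {kind: single_pulse, ablate: {reaction: slow_inhibition, species: [7]}}
solver: {method: Radau, rtol: 1.0e-6, atol: 1.0e-8}
training: {n_train: 64, steps_per_phase: 200, batch_size: 16, curriculum_fraction: 1.0}
scan: {fmoc_grid: [0.095, 0.105, 0.115], pa_grid: [1.5, 1.8, 2.1], horizon: 240}
settings: [[0.08, 1.8], [0.1, 1.4], [0.1, 2.2]]
```

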
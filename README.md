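# drusenlab

Quantitative analysis of how an epithelial monolayer adapts to light-induced
substrate bulges ("artificial drusen"): monolayer-thickness profiling from
F-actin z-stacks, cell-scale morphometrics, radial Top/Edge/Outside region
statistics, swelling kinetics, spherical-contact (Hertz) indentation fitting,
and traction force microscopy (PIV + Fourier-space traction reconstruction).
A seeded synthetic-data module generates every input the pipeline consumes,
with ground truth, so the whole analysis is testable without any downloads.

## Modules

| module                      | what it does |
|-----------------------------|--------------|
| `drusenlab.geometry`        | drusen-centered radial coordinates; Top/Edge/Outside annuli (half-open, µm) |
| `drusenlab.synthetic`       | phantom generators: two-band monolayer stacks over a dome, cell mosaics, bead pairs, indentation curves, swelling series, focus stacks; presets `medium-drusen` / `large-drusen` |
| `drusenlab.thickness`       | reslice stack, vertical intensity line profiles, mean-threshold boundary detection, per-replicate normalization |
| `drusenlab.morphometrics`   | per-cell area, Crofton perimeter, shape factor P/√A, axial orientation, angle-to-origin, area distributions and modality (GMM/BIC) |
| `drusenlab.swelling`        | illumination dose arithmetic, min–max swelling normalization, focus-plane apex height |
| `drusenlab.hertz`           | F = (4/3)·E_eff·√R·δ^{3/2} fit with jointly fitted contact point and R² > 0.95 acceptance filter |
| `drusenlab.traction`        | block-matching PIV, regularized FTTC on the Boussinesq half-space kernel, region summaries |
| `drusenlab.pipeline` / `cli`| YAML-configured orchestration, result bundles, synthetic replay report |

## CLI

```bash
# generate a synthetic phantom bundle (stack, mask, ground truth, config stub)
drusenlab simulate --preset medium-drusen --seed 1 --out bundle/

# run stages against a config
drusenlab thickness      --config bundle/config.yaml
drusenlab morphometrics  --config bundle/config.yaml
drusenlab swelling       --config my_config.yaml
drusenlab indent         --config my_config.yaml
drusenlab tfm            --config my_config.yaml

# end-to-end recovery of the preset effect sizes
drusenlab replay -n 5 --seed 1 -o replay.csv
```

Exit codes: 0 ok, 1 validation error, 2 runtime error. Every output bundle
records the seed and a hash of the resolved configuration; seeded runs are
bit-reproducible.

A minimal config:

```yaml
stages: [thickness]
output_dir: results/
paths: {stack: bundle/stack.tif}
center_xy: [150.0, 150.0]
illumination_diameter: 100.0   # or 300.0
pixel_pitch_um: 1.0
z_step_um: 0.25
replicate: sample-1
seed: 1
```

## Conventions

- Coordinates: 0-based pixel indices; physical position = (index + 0.5) ×
  pitch, in µm; z index 0 is the substrate side.
- Region membership is half-open `[inner, outer)` on the distance to the
  drusen center; names are the fixed strings `Top`, `Edge`, `Outside`.
- The traction kernel assumes a flat half-space; no curvature correction is
  applied over the bulge (recorded in output caveats).
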
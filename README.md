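# hflpol

Toolkit for relating Henle-fiber-layer (HFL) thickness, as measured with
directional OCT, to macular phase retardation, as measured with scanning
laser polarimetry (SLP) — together with a polarization-optics forward
simulator that generates both kinds of input with known ground truth, so the
whole analysis chain can be validated without access to subject data.

## What's inside

| module | role |
|---|---|
| `hflpol.synthetic` | Forward simulator: radial HFL thickness model, Jones-calculus retarder composition, SLP map rendering (macular cross under fixed corneal compensation, annulus under variable compensation), directional-OCT boundary traces with side-dependent validity, cohort generation with between-subject variability. |
| `hflpol.oct` | OCT stage: QC (>20 dB), merging opposite-offset traces, boundary subtraction, fovea localization from the outer-segment band, sampling on the canonical 0.25°–3.00° grid, four-meridian averaging. |
| `hflpol.slp` | SLP stage: QC (≥8), sub-pixel macular-center localization (cross-harmonic score or annulus radial symmetry), ring/annulus intensity statistics, double-frequency sinusoid fits. |
| `hflpol.stats` | Per-subject Pearson R, Fisher-Z cohort averaging, coefficient of variation per eccentricity, Mann-Whitney rank-sum comparisons. |
| `hflpol.pipeline` / `hflpol.cli` | End-to-end orchestration with a YAML config, deterministic seeding, CSV/JSON outputs and a Markdown report. |

## CLI

```sh
# simulate a 25-subject variable-compensation cohort
hflpol simulate --n 25 --mode variable --seed 7 --out data/cohort2

# per-subject OCT thickness profiles from a cohort manifest
hflpol oct --manifest data/cohort2/manifest.json --out results/oct

# ring statistics for one retardation map
hflpol slp --image data/cohort2/sub000/slp.png --out results/sub000.csv

# full two-cohort pipeline
hflpol run --config examples/cohorts.yaml --out results/
```

A pipeline config looks like:

```yaml
seed: 1
statistic: ring_mean        # or cross_amplitude
sim: {noise_sd: 1.5}        # optional SimConfig overrides
cohorts:
  - {label: cohort1, mode: fixed, n_subjects: 11}
  - {label: cohort2, mode: variable, n_subjects: 25}
```

Cohorts can instead point at pre-existing data via
`{label: ..., manifest: path/to/manifest.json}` using the interchange
formats (8-bit PNG + JSON sidecar for maps; `column_px,depth_px,valid` CSVs
plus JSON metadata for boundary traces).

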
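# uapipe

A multimodal analysis pipeline for uncertainty-adjustment experiments:
synthetic session generation with planted effects, drift-diffusion
modeling of choices, EEG-derived decision and excitability signatures,
pupillometry, pseudo-trial bootstrap decoding, partial least squares,
and group-level inference on linear "target load" (uncertainty) effects.

The package is fully self-contained: the `task_synth` module generates
balanced session designs (4 binary stimulus features, cue-set sizes 1-4,
block structure), diffusion-model behavior, oscillatory + aperiodic
EEG-like epochs, pupil traces with blink artifacts, and BOLD-like voxel
patterns, each with configurable planted group x load effects — so every
downstream stage is testable without external data.

## Modules

| module        | contents |
|---------------|----------|
| `task_synth`  | session designs, stimulus evidence, behavior/EEG/pupil/BOLD simulators with planted effects |
| `ddm`         | first-passage density (small/large-time series), Euler + bridge simulator, per-subject ML fitting with a 5% uniform-outlier mixture, 4-variant model comparison (AIC/BIC) |
| `eeg_features`| 7-cycle Morlet power, pre-response ramp slope/threshold, contralateral 8-25 Hz slope, sideband-normalized 30 Hz entrained amplitude, time-resolved sample entropy over discontinuous trial segments, iterative peak-excluding aperiodic (1/f) fit |
| `pupil`       | blink/gaze-artifact cleaning with linear interpolation, first-derivative signature at 100 Hz with 300 ms moving median |
| `decoding`    | leave-one-trial-out pseudo-trial (3-fold-average) bootstrap linear decoding, condition-wise accuracy curves |
| `pls`         | task PLS (group-mean-removed condition means) and behavioral PLS (between-subject correlations), permutation p, bootstrap ratios with Procrustes alignment, brainscores |
| `group_stats` | per-subject linear load slopes, MAD winsorization, within-subject centering, cluster-based permutation tests (min-3-channel rule), random-intercept mixed models with a two-stage fallback |
| `bold_glm`    | boxcar x double-gamma HRF design matrices (temporal derivative, mean-centered parametric modulators), per-voxel OLS, run averaging |
| `pipeline`/`cli` | stage orchestration with config hashing, seeds, logging, and a JSON summary of group contrasts |

## CLI

```bash
uapipe run-all --config config.yaml --seed 1 --out runs/demo
uapipe synth   --out runs/synth-only          # just the generators
```

Each subcommand runs the pipeline through the named stage (`synth`,
`ddm`, `eeg`, `pupil`, `decode`, `pls`, `stats`, `run-all`); the run
directory receives tidy TSV tables, a `summary.json` with per-signature
load slopes by group and PLS statistics, a log, and a summary figure.
Reruns with identical configs produce byte-identical summaries; the
config hash and seed are embedded in every summary.

The YAML config mirrors `uapipe.pipeline.PipelineConfig`: cohort sizes,
design counts, stage toggles, and the `stimulus`/`effects` blocks
(evidence ratios, per-group effect intercepts and load slopes, noise
levels). Unknown keys are rejected.

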
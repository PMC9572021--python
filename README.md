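# eegid

EEG-based person identification under escalating cognitive load, as a
tested, reusable pipeline:

- **`eegid.synthetic`** — a cohort generator that emulates multichannel EEG
  recordings (8 channels F3/F4/C3/C4/P3/P4/O1/O2 at 1 kHz, µV scale) with
  per-subject spectral signatures: an individual alpha-peak frequency,
  per-band amplitudes, a four-region band-power topography, 1/f background
  noise, 50 Hz powerline interference, and slow drift. Task-load profiles
  modulate band powers (alpha suppression, beta/gamma enhancement with
  rising game difficulty); the hardest level may terminate early.
- **`eegid.preprocess`** — signal conditioning in a fixed order: 50 Hz
  notch → 0.5–95 Hz Butterworth band-pass (zero-phase) → task selection →
  sliding-window segmentation (1000-sample windows, 500-sample hop) →
  scalp-region selection → common average reference over the surviving
  channels → per-channel z-score fitted on training data only.
- **`eegid.model`** — two 1D-CNN variants: [conv(1×5) → batch norm → ReLU →
  max-pool(1×2)] blocks with 32/64/128 filters (variant A) or
  32/64/128/256 (variant B), global average pooling, and a softmax head;
  trained with Adam, cross-entropy, mini-batches of 64, learning rate 1e-3,
  per-epoch shuffling, and best-validation-loss checkpointing. Implemented
  directly on numpy (no deep-learning framework): explicit forward/backward
  passes validated by finite-difference gradient checks.
- **`eegid.evaluation`** — stratified 80/20 split, stratified 5-fold CV,
  one-vs-rest multiclass metrics (average accuracy, macro precision/recall,
  macro-F1 as the harmonic mean of the macros, plus plain trace accuracy),
  the 104-case (variant × scenario × channel-subset) channel-reduction
  study grid, and the final retrain-and-test protocol.
- **`eegid.io_manifest`** — EDF and per-channel CSV readers/writers plus a
  JSON cohort manifest.
- **`eegid.cli`** — `simulate / preprocess / train / study / report`
  subcommands driven by a YAML config, with JSON-line logs and config
  hashes on every artifact.

## CLI quick start

```sh
# generate a synthetic cohort (writes EDF files + manifest.json)
eegid simulate --out run/ --format edf

# run part of the study grid with 5-fold CV
eegid study --cohort run/cohort --out run/ --variant B --scenario rest --regions C+O

# everything, both variants, 104 cases (slow)
eegid study --cohort run/cohort --out run/

# summarize
eegid report --study-dir run/study
```

`--quick` shrinks cohort/epochs for smoke runs (not faithful to the full
protocol). A YAML config (`--config`) controls cohort size, separability
preset, filter parameters, segmentation, the study grid, and training
hyperparameters; see `eegid.config.RunConfig` for the schema and defaults.

## Reproducibility

Every stochastic step (cohort draw, recording synthesis, splits, weight
initialization, shuffling) is driven by explicit seeds; identical configs
and seeds produce byte-identical manifests and results tables.
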
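# rovebold

Simulation and analysis pipeline for a tri-modal roving-oddball fMRI
paradigm, exercised end to end on synthetic region-level BOLD data.

A single Markov chain over 8 states (one binary intensity per auditory,
somatosensory and visual stream) generates stimulus sequences in which at
most one modality changes per trial and the change probability depends on
whether the other two modalities are congruent. The package covers:

- **`rovebold.markov`** — condition-specific 8x8 transition matrices
  (C1: p(change|congruent)=0.15 / p(change|incongruent)=0.025, C2 mirrored,
  C3 flat at 0.0875), stationary distributions, TSV/JSON export.
- **`rovebold.sequences`** — constrained sampling (a modality that just
  changed must repeat at least once), empirical-statistics validation with
  resampling (±0.005 on conditionals, ±0.025 on overall change and intensity
  balance), catch-trial placement, session assembly, BIDS-style events TSV.
- **`rovebold.annotate`** — per-trial/per-modality deviant/standard roles,
  train lengths with the six bins (1, 2, 3, 4–5, 6–8, >8), cross-modal
  predictability labels, and the ±1 modulator codes.
- **`rovebold.bold`** — synthetic region-level BOLD: double-gamma HRF,
  configurable intensity/mismatch/train-slope/misprediction amplitudes per
  region, neural-level seed→target coupling for PPI ground truth, AR(1) +
  polynomial-drift noise (6 runs x 475 volumes at TR 1.5 s by default).
- **`rovebold.glm`** — first-level GLMs (modulator variant: all-trials onset
  + 9 mean-centred parametric modulators; train-bins variant: 18 deviant
  regressors + rest), AR(1) prewhitening with a design-calibrated
  coefficient, t contrasts, linear train-length contrast, one-sample and
  repeated-measures second level, minimum-statistic conjunction against the
  global null, Bonferroni / max-T permutation FWE.
- **`rovebold.ppi`** — psychophysiological interactions: seed extraction,
  ridge-deconvolved (default) or BOLD-product interaction regressors,
  per-target coupling estimates.
- **`rovebold.experiment` / `rovebold.cli`** — configured end-to-end
  experiments, the parameter-recovery study and the acceptance-target
  checks.

## CLI

```sh
rovebold simulate-sequences --condition C1 --runs 6 --trials 400 --seed 1 --out out/seq
rovebold annotate --events out/seq/events.tsv --out out/ann
rovebold simulate-bold --session out/ann --seed 1 --out out/bold
rovebold fit-glm --bold out/bold --session out/ann --variant modulator --out out/glm
rovebold ppi --bold out/bold --session out/ann --seed-region aud_l --modality A --out out/ppi
rovebold run-recovery --seed 1 --out out/recovery
rovebold reproduce-targets --seed 1
```

All verbs exit 0 on success and 2 on validation failure.

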
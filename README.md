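# gaitnarx

Continuous prediction of *future* ankle angle and ankle moment from
dorsiflexor/plantarflexor EMG linear envelopes during level walking and stair
ascent/descent (including terrain transitions), using a single
multiple-input multiple-output feedforward (open-loop) NARX network.

The package implements the complete workflow:

- **`gaitnarx.synthetic`** — seeded generator of multi-condition gait sessions
  (Gaussian-bump templates, lognormal burst jitter, monotone time warp,
  band-limited noise, and an EMG-coupled dynamics option so EMG
  informativeness is testable), plus a closed-loop *teacher* generator for
  exact parameter-recovery tests.
- **`gaitnarx.sigproc`** — EMG linear envelope (20–499.5 Hz band-pass,
  rectification, 5.5 Hz low-pass, decimation to 120 Hz), kinetic
  (15 Hz + 59–61 Hz notch) and kinematic (15 Hz) zero-phase filtering, trial
  truncation (225 ms pre-roll to terminal heel strike), common-length
  resampling (LW 145 / AS 430 / DS 400 samples).
- **`gaitnarx.narx`** — the NARX forward equations with tapped delay lines
  (exogenous window q = 0..d, feedback window q = 1..d with a minus sign),
  tanh hidden layer, linear output layer, [-1, 1] min-max normalization, and
  versioned JSON model serialization.
- **`gaitnarx.training`** — full-batch Levenberg–Marquardt with analytic
  Jacobian, validation-based early stopping, error-goal stopping (including
  the 1%-of-moment-variance rule), 10-restart selection, and trial-blocked
  leave-one-out folds (8 train / 2 validation / 1 test trials per condition).
- **`gaitnarx.sweep`** — the (prediction interval × sampling window × hidden
  units) characterization grid, marginal collapse + OLS trend tests, optimal
  (window, hidden) selection at a fixed 58 ms interval, and zero-error-goal
  re-training.
- **`gaitnarx.evaluation`** — RMSE, cross-correlation-peak R², instantaneous
  RMSE over common-length trials, the constant-EMG ablation, critical-point
  extraction with Shapiro–Wilk-gated paired-t / sign tests, and
  Benjamini–Hochberg FDR adjustment.
- **`gaitnarx.io` / `gaitnarx.cli`** — plain-text formats (CSV + JSON
  sidecars) and the command-line pipeline.

## CLI

```sh
gaitnarx simulate   --conditions LW,AS,DS --n-trials 11 --seed 42 --coupling 0.6 --out raw/
gaitnarx preprocess --session raw/ --out proc/
gaitnarx sweep      --session proc/ --grid reduced --folds 2 --seed 42 --out sweep.json
gaitnarx finalize   --session proc/ --sweep-result sweep.json --folds 3 --out models/
gaitnarx evaluate   --session proc/ --models models/ --folds 3 --out report/
gaitnarx pipeline   --seed 42 --out run/        # all of the above in one go
```

`--grid default` selects the full 432-cell grid (9 intervals × 6 windows ×
8 hidden-unit counts); `reduced` is the desk-scale 27-cell grid.

## Conventions

Working rate 120 Hz; raw EMG 1,200 Hz. Angle in degrees with dorsiflexion
positive; moment in N·m/kg with the plantarflexion (push-off) peak positive.
Every stochastic component is seeded and sessions regenerate bitwise
identically.
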
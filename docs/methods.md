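# Methods

## The mapping problem

Electrical stimulation mapping (ESM) labels subdural electrode sites
"eloquent" when stimulating them disrupts function; it is the clinical gold
standard before resective epilepsy surgery but is slow and can provoke
seizures or pain.  `ecogmap` implements a passive alternative: during a
delayed match-to-sample task (sound → letters → button-press), cortical
activation raises broadband gamma power (55–200 Hz) and suppresses alpha
(8–12 Hz) and beta (15–25 Hz) power, more strongly under eloquent electrodes
than under ESM-negative ones.  The pipeline quantifies each band's diagnostic
ability with the AUROC, combines bands with a binomial GLM, compares models
with a paired electrode bootstrap, and builds per-patient probabilistic
eloquence maps with leave-one-patient-out training.

## Pipeline and assumptions

1. **Epoching** — trials are cut from 1 s before sound onset to 1 s after
   the button-press, capped at 8 s; passive trials (sound only, no task) use
   a fixed post-sound window of 1.9 s.  Windows are half-open `[start, end)`
   in seconds; sample indices are 0-based.
2. **Line-noise removal** — zero-phase IIR notch cascade at 50/100/150 Hz,
   1 Hz bandwidth.  A high-Q notch rings for roughly `1/bandwidth` seconds,
   so epochs are reflect-padded that long before the two-pass filter;
   residual 50 Hz energy on an 8 s tone is < 3% RMS while tones 20 Hz away
   pass within 0.1%.
3. **Downsampling** — polyphase resampling 2048 → 500 Hz (exact ratio
   125/512; 8 s maps to exactly 4000 samples).
4. **Electrode exclusion** — electrodes whose log broadband RMS deviates
   from the cohort median by > 5 robust (scaled-MAD) deviations are flagged.
   The criterion is this package's own; the clinical procedure excluded
   "high-noise" electrodes without stating a rule.
5. **Common average reference** — each electrode minus the mean of all
   non-excluded electrodes; excluded electrodes are re-referenced but never
   contribute to the mean.
6. **Band power** — per trial: 4th-order Butterworth band-pass (two-pass,
   zero-phase) at the band edges, analytic-signal magnitude, then
   *normalized change* `(P − B)/B` against the −0.7…−0.1 s pre-sound
   baseline, computed per trial before any averaging.  A symmetric
   alternative `(P − B)/(P + B)` sits behind `PipelineConfig.normalization`.
   Epochs are mirror-padded 0.5 s before filtering and the Hilbert transform
   to suppress edge transients.
7. **Time-frequency maps** — sliding Hanning windows of 7 cycles per
   frequency, 6–250 Hz in 2 Hz steps, 10 ms hop; time points whose window
   is unsupported are masked (NaN), never zero-padded.
8. **Features** — trial-averaged normalized change per electrode and band,
   over the concatenated event-aligned windows (sound −0.5…1 s, letter
   −0.2…0.7 s, button −0.3…0.7 s), per event, over 100 ms / 50 ms sliding
   windows, or over 0–0.9 s post-sound (the only window shared by active
   and passive trials).
9. **AUROC** — Mann–Whitney rank formulation with ties counted 1/2 (equal
   to the trapezoidal ROC area).  For display, suppression-driven
   discriminability is shown below 0.5; model fitting always consumes raw
   features.  Two-sided permutation tests shuffle labels across the pooled
   electrode set and compare the observed value with the 2.5/97.5
   percentiles of (by default) 1000 shuffles, uncorrected across
   frequencies.
10. **Band combiner** — maximum-likelihood logistic regression (IRLS with
    step-halving) of the ESM label on band features, z-scored with
    training-fold statistics.  Under separation or non-convergence the fit
    falls back to a ridge penalty of 1e-4 on the slopes and flags it.
    Cross-validation is stratified 10-fold repeated 20 times; out-of-fold
    probabilities are averaged across repeats before a single AUROC is
    scored (per-repeat AUROC averaging is configurable).
11. **Model comparison** — 1000 electrode resamples (with replacement, same
    resamples for every model; resamples that lose a class or cannot host
    stratified folds are redrawn and counted).  Each model's 10-fold CV
    AUROC is computed per resample with 1 inner repeat (20 would be
    statistically preferable but multiplies cost by 20; configurable).  A
    model differs significantly from the reference when ≥ 95% of resamples
    agree in direction — the threshold implied by calling 98% consistency
    significant and 94% not.
12. **Eloquence map** — for each patient, a beta&gamma combiner is fitted on
    the other patients' electrodes and applied to the held-out patient.
    Per-patient summaries report mean ± SD predicted probability per ESM
    class, and an AUROC only where both classes have ≥ 2 electrodes.  The
    calibration curve uses 10 equal-width bins with 50% overlap spanning
    the observed prediction range; bins with < 3 electrodes are masked.
    The reported "GLM response" is the logistic probability (the linear
    predictor is available from the model object).

## Numerical choices

- **Intercept anchoring in CV.**  Pooled out-of-fold AUROC is
  pessimistically biased for weak models: a fold that happens to hold an
  extra positive was trained at a lower prevalence, so all its members get
  systematically lower predictions (we measured null CV AUROC near 0.35
  without correction).  Every fold model's intercept is therefore shifted by
  `logit(overall prevalence) − logit(training prevalence)` — one constant
  per fold, which cannot reorder electrodes within a fold and keeps
  intercept-only predictions at the prevalence.  Null CV AUROC is then
  centred on 0.5.
- **Ratio bias of the normalization.**  With a 0.6 s baseline, `E[(P−B)/B]`
  is slightly positive for stationary noise because `B` is a noisy mean
  (Jensen); the bias is largest for narrow bands and low TFR frequencies.
  It affects both ESM classes equally and therefore cancels in rank-based
  statistics; tests check stationarity of the normalized change rather than
  exact zero.
- Ties in bootstrap direction counts are split 1/2; percent changes are
  computed per resample and then averaged (change-of-means is configurable).
- All randomness flows from one seed through tagged, order-independent
  child-seed streams; identical seeds reproduce every distribution
  bit-for-bit.

## The synthetic cohort generator

No public ECoG cohort with ESM labels exists, so the generator is a
first-class module with known ground truth.  Each electrode's trace at
2048 Hz is 1/f² Gaussian background (RMS 40 µV), a 50 Hz line sinusoid
(5 µV), and one band-limited Gaussian carrier per band (alpha 10 µV, beta
8 µV, gamma 6 µV RMS) whose power envelope is `1 + s·E(t)`: `E` sums smooth
rise/decay kernels per trial event, and `s` is the electrode's signed peak
fractional power change (amplitude floored at 0.1× baseline).  Defaults
emulate the cohort's reported structure:

- prevalence of eloquence 129/572 ≈ 0.23; output (motor / mixed
  sensorimotor / Broca) share within eloquent 0.55; ESM categories drawn in
  the clinical label proportions, including rare "emotion" electrodes that
  are eloquent but excluded from the input/output analysis;
- gamma increases (strongest at input sites, prompt kernels at all three
  events), alpha/beta suppression (slow kernels; beta deepest at output
  sites around the button-press, with a substantial sound-onset component);
- passive trials attenuate every kernel by `passive_scale` (default 0.5);
- heterogeneity: a lognormal per-patient responsiveness multiplier
  (σ = 0.2) and lognormal per-electrode multipliers (σ = 0.45, scaled per
  band by `latent_sigma_scale`) whose band-to-band correlation is set by
  latent-factor loadings — alpha and gamma load 0.95 on a shared factor
  while beta loads 0.3, so beta carries genuinely independent information
  for a band combiner while alpha is largely redundant with gamma.  Gamma's
  latent spread is scaled to 0.35: its wide band averages trial noise away,
  so without a reduced responsiveness spread its class overlap would be
  purely effect-proportional and attentional attenuation (which scales
  effects and their spread together) would leave gamma's AUROC almost
  unchanged — contrary to the attenuation phenomenology the generator is
  meant to emulate;
- event schedule: letter at 1.5 ± 0.1 s (truncated ≥ 1.1 s) and button at
  2.5 ± 0.15 s (≥ letter + 0.4 s) after sound; inter-trial interval 3.5 s.
  The truncations keep letter/button responses out of the 0–0.9 s sound
  window and let kernel tails decay before the next baseline, so active and
  passive sound windows are generatively equivalent when
  `passive_scale = 1`.  No event-latency statistics were reported for the
  clinical task; these are package choices.
- defaults are study-scale (10 patients × 57 electrodes, 240 active + 80
  passive trials); tests and the acceptance script scale trials to
  24–48 per condition and calibrate on 200-electrode replicas (the
  per-patient multiplier has its own seed stream, so replicas share the
  full cohort's patient draws).

`calibrate_bands` bisects a multiplier on each band's eloquent effect sizes
until the realized single-band discriminability (full generation + feature
chain under a fixed evaluation seed) hits a target, by default 0.70 ± 0.02 —
the reported ideal-observer range.

**What the generator does not emulate:** spatial correlation between
neighbouring electrodes, epileptiform activity and artifacts, non-stationary
background spectra, reaction-time/accuracy coupling, or any biophysical
forward model.  Passing tests demonstrate that the *statistical machinery*
behaves as designed under a controlled data-generating process; they cannot
certify clinical performance.

## Attention-contrast null and its scoring

The paired electrode bootstrap treats electrodes as exchangeable units.  A
patient's electrodes share condition-level noise (reference and schedule
components), which electrode resampling cannot represent, and the ≥ 95%
directional-consistency rule is itself a nominal-10% two-sided test.  Under
a true null (`passive_scale = 1`) we therefore score the contrast one-sided,
in the direction the analysis claims ("significantly worse in passive"):
measured spurious worse-in-passive verdicts were 0/48 run × model checks,
while two-sided flags appeared at roughly the nominal rate.  A
patient-clustered bootstrap would be the principled extension and is out of
scope here.

## Problem sizes

The acceptance cohort is 10 patients × 60 electrodes (prevalence 0.23),
24 active + 24 passive trials per patient at 2048 Hz, with effect sizes
calibrated on the cohort spec itself under its own seed; the attention null
uses ten 5-patient × 30-electrode cohorts with 48 + 48 trials and B = 250.
These sizes are the package's choices for a reproducible desk-scale study;
all counts are configurable.

## Known limitations

- The bootstrap and the permutation test ignore patient clustering (as does
  the procedure they reproduce).
- Single-repeat inner CV inside the bootstrap adds partition noise to the
  resample distributions (slightly conservative comparisons).
- The normalized-change ratio bias shifts absolute power-change values for
  narrow bands; comparisons between classes and conditions are unaffected.
- The generator's calibration transfers between replica and full cohort up
  to electrode-sampling noise (±0.03–0.05 in realized AUROC at 130 eloquent
  electrodes).
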
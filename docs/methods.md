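# Methods

This note documents the analysis chain, its tunable parameters, the
synthetic tremor model, and the numerical and design choices made where more
than one defensible option existed. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The measurement chain

A recording (3×N acceleration in g/mg/m·s⁻², or a single velocity channel in
m/s; any sampling rate `fs ≥ 4·(f_c + 2)` Hz) passes through:

1. **Trend correction** — third-order Butterworth high-pass, 0.1 Hz corner,
   applied forward and backward (`sosfiltfilt`), so the net phase is zero
   and the effective magnitude response is the squared single-pass response.
   Edge handling: odd-symmetric extension, 3·(2·order+1) = 21 samples per
   end; the first and last 1 s of the recording are additionally excluded
   from all crossing analysis (`edge_margin_s`).
2. **Dominant axis** — projection of the mean-centred axes onto the leading
   eigenvector of the sample covariance (PC1), equivalent to a virtual
   rotation of the sensor. The eigenvector sign is canonicalised so the
   projected signal has non-negative third central moment. This matters:
   an arbitrary sign selects the opposite zero-crossing family
   (rising-through-zero on the other flank of an asymmetric waveform),
   which changes the Δf sample; with the canonical sign the whole chain is
   invariant to sensor-frame rotation and to a global sign flip, and the
   canonical flank has the steeper slope on harmonic-bearing waveforms,
   which reduces crossing-timing noise. Uniaxial (laser) input bypasses
   this stage.
3. **Peak frequency** — Welch periodogram (Hann, 8 s segments, 50 %
   overlap), maximum restricted to 2–9 Hz, parabolic interpolation of the
   peak bin so `f_c` is not quantised to the bin grid.
4. **Tremor band-pass** — separate zero-phase third-order Butterworth
   high-pass at `f_c − 2` and low-pass at `f_c + 2` Hz. When `f_c < 2.1`
   the high-pass corner would fall at or below the detrend corner and the
   stage is skipped (the 0.1 Hz detrend already removed that band). Note
   the zero-phase cascade's centre-band gain at `f_c` is
   (25/9)³/(1+(25/9)³) · 1/(1+(25/49)³) ≈ 0.854, not unity; crossing times,
   and hence the TSI, are invariant to this scalar gain.
5. **Cycle decomposition** — positive-gradient zero crossings, each refined
   by linear interpolation between the bracketing samples (removes the
   sampling-rate dependence of interval quantisation); `T_n`, `f_n = 1/T_n`,
   `Δf_n = f_n − f_{n+1}`.
   A plausibility guard protects against numerical artefacts: an interval
   implying `f > f_c + 2.5` Hz is merged with the following interval; one
   implying `f < f_c − 2.5` Hz (a missed cycle) is excluded, and Δf is never
   formed across the gap. Guard events are counted and logged.
6. **Scalar features** — TSI = IQR(Δf) with type-7 (linear-interpolation)
   quantiles; mean frequency, F_SD, F_cov, Δf_SD, Δf_cov (sample SD,
   n−1 denominator; coefficients of variation divide by |mean|, and Δf_cov
   is reported missing when |mean Δf| < 1e−12 Hz rather than blowing up);
   the Hilbert amplitude envelope smoothed by a centred 1 s moving average;
   SNR = 20·log10 of the smoothed envelope of the band-passed signal over
   the envelope of (detrended − band-passed), with the residual envelope
   floored at 1e−12 of the median signal envelope (ceiling 240 dB) so
   noiseless inputs are finite; and MHP = log10 of the mean Welch power at
   the nearest bins to `k·f_c`, k = 1..4, computed on acceleration converted
   to milligravities (exact constants, g = 9.80665 m/s²). The log base is
   10 (consistent with the dB conventions of the chain) and is exposed in
   the configuration; MHP is reported missing for velocity recordings and
   when `4·f_c` reaches Nyquist.

All printed-value parameters (0.1 Hz corner, order 3, 2–9 Hz search, ±2 Hz
band, 1 s smoothing, type-7 IQR, 1.05 Hz cutoff, 1000/10000 bootstrap
iterations) are locked while `paper_mode` is set in `AnalysisConfig`
(the default).

## Cohort-level evaluation

ET is the positive class throughout; a direction flag recomputes the
PD-positive columns. Conventions:

- **Fixed cutoff**: strict rule, score > threshold → ET, ≤ → PD.
- **ROC/AUC**: empirical curve over observed thresholds; AUC is the
  Mann–Whitney concordance with ties counted ½ (cross-checked in the tests
  against exhaustive pair enumeration). The 95 % CI is `AUC ± 1.96·SE`
  clipped to [0, 1], with the Hanley–McNeil asymptotic SE by default
  (matching SPSS-style "asymptotic" intervals) and DeLong as an option.
- **Threshold selection**: the observed value maximising Youden's
  J = sensitivity − (1 − specificity), ties broken toward higher
  specificity; both the observed cut and the midpoint to the next larger
  observed value are reported (a deployable threshold such as 1.05 lies
  between observations).
- **Logistic odds**: unpenalised maximum-likelihood fit of a single
  predictor; Exp(B) with a Wald 95 % CI. Perfect separation is flagged as
  non-converged rather than raising.
- **Cross-validation**: stratified k-fold (default 10); the threshold is
  re-chosen on each training portion (Youden midpoint) and applied to the
  held-out rows; pooled confusion counts are reported.
- **Duration bootstrap**: each recording is conditioned once; per iteration
  and duration a uniformly random contiguous window is drawn and the TSI is
  recomputed from the zero-crossing cycles inside it. Windowing the cycle
  series is equivalent to re-filtering the segment away from filter edges
  (the filters are zero-phase and time-invariant) and keeps 1000-iteration
  runs to seconds. Windows with fewer than 2 Δf values exclude that subject
  from that iteration's AUC. Durations default to 1–10 s in 1 s steps and
  20–100 s in 10 s steps.
- **Paired AUC comparison**: subjects resampled with replacement, stratified
  by class so every replicate contains both diagnoses; both features' AUC
  computed per replicate; the fraction of replicates with a positive
  difference is reported.
- **Randomness**: every stochastic operation takes an explicit integer seed
  (`numpy.random.default_rng`); the acceptance script derives per-operation
  seeds from its `--seed` by fixed offsets. Reruns are bit-identical.
- No multiple-testing correction is applied anywhere: the evaluation makes
  single pre-specified comparisons.

## Synthetic tremor model

`generate_recording` is a phase oscillator: per cycle `n` the frequency is

```
f*_n = f0 + drift(t_n) + eta(t_n)        (folded into 2.05–8.95 Hz)
```

and the phase advances 2π per cycle (piecewise-linear interpolation between
crossing knots). The waveform is `Σ_k a_k sin(k·φ)` (fundamental plus
configurable harmonics), amplitude-modulated by
`1 + depth·sin(2π·f_mod·t + φ0)` (waxing/waning), projected onto a unit
sensor direction, and contaminated with a constant per-axis gravity offset,
a sub-0.1 Hz sinusoidal baseline drift (to exercise the detrend stage) and
white Gaussian sensor noise. True crossing times and per-cycle frequencies
are returned as ground truth. Everything is deterministic given the seed.

**Drift** is a triangle wave with slope ±`drift_rate` bounded by
±`drift_bound` — slow wander over a broad range, the PD-like pattern.

**Cycle jitter** (`cycle_jitter_iqr`, the designed IQR of Δf) is, by
default, *narrowband frequency wander*: two random-phase tones at 0.7 and
1.3 times a centre modulation frequency. The tone amplitude is solved by
deterministic quadrature of the exact increment law — at midpoint phases
(u, v) the oscillator runs at `f = f0 + A(cos u + cos v)`, a tone at `f_m`
contributes an increment of amplitude `2A·sin(π f_m/f)` per cycle, and each
phase cell is weighted by the local frequency because crossings sample the
path at rate `f`. The centre modulation frequency is the slowest (floor
0.30 Hz) for which the path sd stays within a 1.2 Hz cap, and tones never
exceed 0.15·f0; beyond that point the path folds at the plausible-window
edges instead of speeding up further. White Laplace (heavy-tailed) and
white Gaussian per-cycle jitter are available as alternatives, their
increment IQRs likewise scaled in closed form.

The narrowband default exists because of a property of the measurement
chain itself, found empirically during development and reproducible with
the package: the zero-phase `f_c ± 2` Hz band-pass transduces frequency
modulation essentially unattenuated below ~0.8 Hz modulation frequency but
removes the FM sidebands of faster modulation, so *white* per-cycle jitter
reaches the Δf series at roughly half its designed size, whatever its
distribution. Concentrating the wander at low modulation frequencies makes
the designed jitter recoverable: across designed IQRs of 0.3–1.9 Hz the
pipeline's mean TSI is within ~10 % of the design, degrading to ~16 % low
at 2.5 Hz, where the frequency path already spans most of the analysis band
and the chain saturates (measured TSI plateaus around 2 Hz). Within-seed
realized ground-truth IQRs match the design to a few per cent up to 1.9 Hz.

**Cohort presets.** `paper-test-cohort` emulates a 16 PD / 20 ET cohort:
per-subject tremor frequency normal around 5.1 Hz (PD) and 5.75 Hz (ET),
truncated to 3–8 Hz; PD-like subjects get slow drift over a broad bound
(±1 Hz) and stronger harmonic content, ET-like subjects tight drift
(±0.3 Hz); amplitudes 10–40 mg with 1 mg sensor noise; random sensor
orientation per subject. Because the published group TSI values and the
1.05 Hz cutoff live on the *measured* scale, the preset is calibrated in
that space: PD designed jitter is lognormal with mean 0.7 Hz (transduction
is near unity there), while ET designed jitter is centred at 2.7 Hz with
log-sd 0.25 so that the measured ET group lands near the saturation region
(≈1.6–1.8 Hz mean) with roughly the published error rates at the 1.05 Hz
cutoff. A `paper-validation-cohort` preset (42/8, lower group separation,
faster ET) is included for experimentation.

## What the generator does and does not emulate

It emulates: a dominant 2–9 Hz oscillation with controllable
cycle-to-cycle frequency stability, slow frequency drift, harmonics,
amplitude waxing/waning, arbitrary sensor orientation, gravity offsets,
sub-0.1 Hz postural baseline drift, and wideband sensor noise, at any
sampling rate.

It does not emulate: amplitude intermittency deep enough to lose the tremor
in the noise floor (real ET recordings may owe part of their Δf spread to
exactly that), re-emergent tremor latency, EMG, biomechanical limb
resonances, device-specific noise spectra, or patient-calibrated harmonic
content. Consequently, synthetic cohort results are *performance floors
under the stated model*, not reproductions of patient statistics; in
particular the TSI-versus-MHP comparison on synthetic data reflects the
preset's arbitrary harmonic amplitudes, not the relative clinical merit of
the two measures.

## Numerical choices and degenerate inputs

- Quantiles: numpy `percentile` with linear interpolation (type 7), fixed
  so TSI values are bit-for-bit reproducible.
- Crossing refinement: linear interpolation between bracketing samples;
  at 32 Hz sampling this recovers a 5 Hz tone's crossings to ~1 ms.
- Recordings are parsed with round-trip float precision, so
  write → read reproduces samples exactly.
- A recording shorter than the filter padding (21 samples), with fewer than
  3 usable crossings, with all-zero variance, or with non-finite samples
  raises a typed error (`DataError`/`FormatError`/`ConfigurationError`/
  `BoundsError`/`UnitError`).
- Fewer than 4 Δf values: the TSI is refused (the duration bootstrap relaxes
  this to 2 for very short windows and otherwise marks the subject missing
  for that iteration).
- Problem sizes in the test suite (100 s recordings at 128 Hz, 20 replicates
  per jitter level, 200 bootstrap iterations at 10 s, 10 000 comparison
  iterations) were chosen to give stable means at interactive runtimes.

## Known limitations

- The TSI measured through the fixed `f_c ± 2` Hz chain saturates near
  2 Hz; differences between extremely unstable tremors compress.
- MHP requires calibrated acceleration; velocity (laser) recordings get no
  MHP, matching the definition.
- The segment convention "first 100 s of tremor" requires the operator to
  supply a tremor-containing start offset; no tremor-onset detector is
  included.
- Cross-validated thresholds on small cohorts (36 subjects) are noisy; the
  pooled cross-validation accuracy is typically below the resubstitution
  accuracy at the fixed cutoff, as expected.
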
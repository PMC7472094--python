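# Methods

## Problem and pipeline

`mechanohrv` quantifies how well heart rate variability (HRV) measured from
mechanical cardiac signals — the seismocardiogram (SCG, sternal
acceleration, dorso-ventral z-axis) and the gyrocardiogram (GCG, sternal
angular velocity, head-to-foot y-axis) — agrees with HRV from the ECG. The
unit of analysis is the NN series: inter-beat intervals in milliseconds,
each stamped with the time of its ending beat. Every agreement statistic
reduces to comparing NN-derived index panels between modalities.

The pipeline stages and their assumptions:

* **ECG beat detection (Pan–Tompkins).** Assumes a dominant, roughly
  periodic QRS complex. Stages: 2nd-order Butterworth 5–15 Hz band-pass
  applied forward–backward, five-point derivative, squaring, 150 ms
  moving-window integration, dual adaptive signal/noise thresholds with a
  200 ms refractory period, T-wave rejection by slope comparison for
  candidates within 360 ms, and search-back at half threshold when no beat
  arrives within 1.66× the running R-R average (last 8 intervals).
  Detections are refined to the largest |band-passed ECG| peak within
  ±100 ms, which makes the detector exactly invariant to positive
  amplitude scaling and keeps timing error at the one-sample level for
  symmetric R waves. The detector runs natively at the recording rate
  (800 Hz default); no resampling.
* **AO/gJ detection.** The aortic-valve-opening wave is assumed to be the
  dominant deflection of the processed mechanical signal within 100 ms
  after the R wave. Processing: 3rd-order Butterworth 4–50 Hz band-pass
  run forward–backward — zero phase, because a causal group delay would
  bias AO timing against the fixed window — then a 15 ms centered moving
  average (taps forced odd, nearest-edge padding). The search window is
  half-open, (t_R, t_R + 100 ms]: the R instant itself is excluded since
  the mechanical wave strictly follows electrical activation. Among
  interior local maxima (strictly greater than both neighbours) the
  largest wins, earliest first on ties; a window with no interior maximum
  falls back to its global maximum and flags the beat `fallback`; a window
  running past the end of the signal flags `missing` and the beat is
  excluded from NN construction (the interval spanning a skipped beat is
  flagged `spanning` and dropped by the NN filter).
* **NN filtering.** Intervals outside [300, 2000] ms, or deviating from
  the centered 11-point running median by more than 20 % of that median,
  are removed. These bounds are deliberately inert on healthy-range data;
  they exist to stop a rare missed/extra beat from contaminating the
  spectral and Poincaré indices.

## ECG cleanup

* **Leading spike.** Some acquisitions begin with a converter transient in
  the first ≤ 17 samples. A prefix sample is flagged when it deviates from
  the median of the rest of the record by more than 8 × the robust scale
  (1.4826·MAD); the flagged prefix is replaced by the first clean value.
  The factor 8 is configurable; it only needs to separate a transient that
  is orders of magnitude above physiology from signal.
* **Median filter.** 5-sample centered median with nearest-edge padding
  (length-preserving, no boundary spikes); removes impulsive noise without
  smearing QRS timing.
* **EMD detrending.** Classical empirical mode decomposition with PCHIP
  (piecewise-cubic-Hermite) envelopes through the local extrema, mirrored
  two extrema deep at each boundary. Sifting stops at 100 iterations or
  when the energy of the subtracted mean envelope falls below 0.2 of the
  current mode energy (Cauchy-type criterion). The decomposition stops at
  10 IMFs, when the signal-to-residual energy ratio exceeds 20 dB, or when
  the residual no longer supports valid envelopes. A candidate mode is
  accepted only if its envelope anchors span the record (largest gap
  between consecutive extrema, including the boundaries, below one third
  of the length): without this guard a near-monotone trend whose only
  extrema are boundary ripples would be "extracted" on an extrapolated
  envelope, moving the trend out of the residual and silently breaking
  residual-based detrending. Reconstruction (ΣIMF + residual = input) is
  exact by construction.

  Detrending recipes are per-recording configuration, not code branches:
  `drop_residual` (subtract the slow residual), `keep_imfs` (sum a 1-based
  IMF range), `crop_then_keep_imfs` (discard unusable leading samples
  first). `drop_residual` removes a wander component that is slower than
  the slowest extracted IMF (e.g. under one cycle per record); an
  oscillatory wander with several cycles becomes a legitimate slow IMF and
  needs a `keep_imfs` recipe instead. The numeric thresholds (0.2 sifting
  tolerance, 20 dB energy ratio) are this package's documented defaults
  for criteria whose names are standard but whose values vary between
  implementations.

## HRV indices

* Time domain: AVNN = mean NN; SDNN = sample standard deviation (N−1
  denominator); RMSSD = √(mean of squared successive differences); pNN50 =
  fraction of successive differences strictly exceeding 50 ms, with the
  number of differences (N−1) as denominator (configurable to N; the
  N−1 convention is the common one) — reported as a proportion in [0, 1].
* Frequency domain: Lomb–Scargle periodogram of the mean-removed NN values
  at their (uneven) beat times, evaluated at 1024 evenly spaced
  frequencies in (0, 0.4] Hz. The raw periodogram is scaled by 2·T/N
  (T the observed time span, N the interval count) so the rectangle-rule
  integral over the grid approximates the NN variance: a pure sinusoidal
  modulation of amplitude A produces a peak of height ≈ A²T/2 whose
  ≈ 1/T-wide main lobe integrates to its variance A²/2. On well-sampled
  modulated series the integral lands within a few percent of the
  variance. Band powers integrate [0.0033, 0.04), [0.04, 0.15) and
  [0.15, 0.4] Hz; TP integrates the entire grid, so TP ≥ VLF+LF+HF (power
  below 0.0033 Hz counts toward TP only). LF/HF is marked undefined (NaN)
  when HF is zero — undefined values are never reported as zeros and are
  excluded from cohort aggregation.
* Poincaré: SD1/SD2 are RMS distances of the scatter points
  (NN_i, NN_{i+1}) from the identity line and from its perpendicular
  through (N̄N, N̄N). The residuals are taken about the lines themselves
  (no mean removal), which yields the exact identity SD1 = RMSSD/√2; a
  flag switches to mean-removed residuals for comparison with toolboxes
  that center first. EA is the fitted-ellipse area π·SD1·SD2 — the
  conventional meaning of a Poincaré ellipse area. VAI uses the angle of
  each point as seen from the origin (atan2(NN_{i+1}, NN_i), degrees); VLI
  is the population (1/N) standard deviation of the point distances from
  the origin, following the index's published definition literally.

## Windowing and agreement

Windows are 179 s long and advance in 15 s steps — 179 s so that a 3-min
recording still contributes one full window. An interval belongs to the
window containing its onset (ending-beat) time, half-open [k·15,
k·15+179); only windows fully inside the record duration count, giving
floor((T−179)/15)+1 windows for duration T. Windows with fewer than 30
intervals are dropped, and cross-modality pairing is by window index so
both panels of a pair always cover the same time span.

Agreement per index: relative error |test − ref|/|ref| (undefined when the
reference is 0) plus the absolute difference, aggregated as mean and SD
over records (full variant) or pooled windows of all records (windowed
variant; a per-subject aggregation is a one-line change and the pooled
default is stated in the output). Correlation: Pearson ρ with the exact
two-sided t-transform p-value (n−2 df), computed by scipy; ρ > 0.7 is
flagged strong. A modality compared with itself returns exactly ρ = 1 and
zero error.

## Synthetic data: what it emulates, and what it does not

`generate_nn` imposes variability directly on interval durations:
NN_i = mean + VLF + LF + HF sinusoids (evaluated at the accumulated beat
time) + Gaussian jitter, rejecting any interval ≤ 200 ms. Direct
construction — rather than an integral-pulse-frequency-modulation model —
gives analytically known band structure, which is what the spectral
recovery tests need. The ECG renderer sums Gaussian P/Q/R/S/T deflections
(R the unique per-beat extremum); the mechanical channels carry a damped
20 Hz oscillation burst whose largest positive peak sits exactly at
R + AO-delay (snapped to the sample grid so stored truth matches the
waveform), plus a smaller secondary burst 300 ms later mimicking the
aortic-closure complex. `corrupt` adds the three artifact families the
cleanup chain targets: a leading spike (≤ 17 samples), sub-0.5 Hz
sinusoidal baseline wander and white noise scaled to an exact SNR.

The synthetic study cohort fixes the conditions once: 20 subjects, 600 s
records at 800 Hz, 10 dB broadband SNR on every channel; per-subject mean
NN uniform in 850–1060 ms, jitter 20–60 ms, LF (0.1 Hz) and HF (0.25 Hz)
amplitudes 15–40 and 15–35 ms, VLF 5–15 ms; SCG AO delay 40 ms with 3 ms
per-beat jitter, GCG 45 ms with 1 ms jitter — the smaller GCG jitter
encodes the gyrocardiogram's better tolerance to disturbances, so the
pipeline should (and does) reproduce ECG–GCG agreement ≥ ECG–SCG.

What the generator does *not* emulate: realistic PQRST morphology and its
inter-subject variation, respiration as a separate channel, motion
artifacts, ectopic beats (the emulated population is healthy), or the true
morphological variability of SCG between subjects. Passing tests therefore
demonstrate correctness of the algorithms under controlled conditions with
known truth — not detector performance on pathological or artifact-laden
clinical data. On real recordings the AO-wave SNR, not the machinery here,
is expected to dominate the error budget.

## Numerical choices and edge cases

* All filters used for timing (ECG band-pass, MCG band-pass, moving
  average) are zero-phase; event timing is never biased by group delay.
* Beat times are strictly increasing with ≥ 200 ms spacing enforced after
  R-peak refinement (larger peak wins on conflicts).
* Ties among equal-amplitude AO local maxima break toward the earlier
  peak.
* Degenerate inputs return marked values, not exceptions, wherever the
  quantity (not the input) is undefined: LF/HF with HF = 0, SD1/SD2 with
  SD2 = 0, relative error with a zero reference, Pearson ρ under zero
  variance — all NaN markers excluded from aggregation.
* Monotone signals decompose to zero IMFs with residual = input.
* The native CSV interchange format prints 17 significant digits so a
  write/read round-trip reproduces float64 samples bitwise
  (`float_precision="round_trip"` on the read side).

## Problem sizes

The shipped tests and the acceptance script run the cohort study at its
stated conditions (20 × 600 s × 800 Hz, three modalities ≈ 0.9 GB-sample
of synthesis and detection) in well under a minute on one CPU; identity
suites use 1000 random NN series; spectral recovery uses 300 s series
(≈ 375 beats); EMD checks use 3000–8000-sample signals.

## Known limitations

* AO detection is ECG-referenced by design; there is no standalone
  mechanical beat detector, so ECG dropout propagates to all modalities.
* Absolute Lomb band powers depend on the normalization convention;
  comparisons with other toolboxes should use ratios (LF/HF, band
  fractions) or rescale by the documented 2·T/N factor.
* EMD has no uniqueness guarantee; IMF indices in `keep_imfs` recipes are
  tied to this implementation's defaults.
* The windowed-variant correlation pools windows across subjects, which
  mixes within- and between-subject variance; per-subject correlation is
  available but not the default.
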
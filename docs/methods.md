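# Methods

## Signal model and representation

All computations operate on uniformly sampled traces represented by a value
array plus a sampling interval `dt` (0-based index time; absolute timestamps
are discarded, since every statistic in the pipeline is lag/index based).
The three channels are the IJV cross-sectional area (cm²), central venous
pressure (cmH₂O) and an ECG used purely as a timing anchor. Sampling
intervals vary by subject over 0.003–0.016 s with 10–15 s of recording, so a
trace holds roughly 600–5000 samples and 10–20 cardiac cycles.

Pressure units convert at 1 mmHg = 1.35951 cmH₂O. The constant is fixed to
reproduce the clinical normal-range bounds (2 → 2.72, 8 → 10.88 cmH₂O at two
decimals); 1.36 would do the same at that precision, but the physical
constant is kept at five significant figures so round trips are stable.

## Preprocessing

**Respiratory-band removal.** The thoracic pump modulates the vein's
cross-section at the respiratory rate (~0.15–0.4 Hz), well below the cardiac
fundamental (~1 Hz). The default filter is a zero-phase order-4 Butterworth
band-pass, 0.5–10 Hz, applied forward–backward (`sosfiltfilt`). 0.5 Hz
separates respiration from the slowest plausible cardiac fundamental; 10 Hz
retains every harmonic that survives the ultrasound segmentation. Two
non-obvious choices:

- *The trace mean is preserved.* The band-pass is applied to the demeaned
  fluctuation and the mean restored afterwards, because the mean CSA is
  itself a model predictor and a raw band-pass would annihilate it.
- *Edge handling.* Forward–backward filtering with a 0.5 Hz corner has
  multi-second transients; padding with 3·order samples leaves 6–8% passband
  deviation inside a 12 s trace. We pad with the odd (point-symmetric)
  extension over ~3 periods of the low cutoff, which keeps interior passband
  deviation under 1% while attenuating a 0.25 Hz tone by far more than 20 dB.

Whether the original analysis filtered both traces, one, or neither before
the correlation statistics is not documented; the pipeline applies the same
filter to both by default with a config switch (`apply_filter`) to disable.

**Synchronization.** In the study design the pressure monitor and the
ultrasound system each record their own ECG, so a subject record carries an
optional second ECG channel. R-peaks are local maxima above mean + 2·SD with
a 0.3 s refractory window — deliberately minimal, since the ECG is only a
time anchor, not a diagnostic signal — and the first common R-peak aligns the
traces. A cross-correlation alignment and a no-op mode are also provided.
After alignment both traces are truncated to the shorter common length from
the aligned origin.

**Resampling** is linear interpolation: traces are short and heavily
oversampled relative to the cardiac band, so spectral resampling would buy
nothing and risks ringing. It exists to support cross-subject comparisons on
a common grid but is off by default (see lag-grid note below).

## Feature extraction

The sample autocorrelation uses the classical biased normalization — one
full-series mean, lag-0 sum of squares as denominator — computed via a
zero-padded FFT (Wiener–Khinchin); a literal double-loop evaluation is kept
in the test suite as the independent oracle and the two agree to 1e-12.

Features are the r-values at lags 0, 20, …, 360 **samples** plus the mean
CSA. The grid is deliberately in samples, not seconds, even though `dt`
varies per subject: this mirrors the original per-subject extraction, which
did not resample. A consequence worth knowing: the same lag index spans
different physical times across subjects, so the features mix time scales;
an optional resampling step can put all subjects on one grid first.

The cross-correlation lag between CVP and CSA maximizes the signed
correlation of `x_{t+k}` against `y_t` over `|k| ≤ max_lag` (default: a
quarter of the trace), so a vein pulse trailing the pressure wave yields a
negative lag. The dominant frequency from an autocorrelogram is f = 1/(D·dt)
with D the mean spacing of positive-lag ACF peaks (local maxima with
prominence ≥ 0.05 and positive r, counting lag 0 as the first peak).
Periodogram peaks are 3-bin local maxima of the mean-removed, untapered
amplitude spectrum.

## Model fitting and selection

Mean CVP is regressed on a subset of {CSA_mean, lag20 … lag360} by OLS.
Subset selection is exhaustive: every admissible subset (at most n − 2
predictors) is scored by AIC = n·ln(RSS/n) + 2(k+1), the Gaussian
linear-model AIC with constant terms dropped (they cancel in comparison).
Each subset costs one small linear solve against precomputed Gram matrices
(Z′Z, Z′y), which makes the full 2²⁰ sweep feasible on one CPU in minutes;
subsets are visited in order of increasing size, then lexicographically, so
AIC ties resolve toward fewer predictors. A forward-stepwise greedy fallback
exists for candidate sets beyond 20.

Cross-validation refits the **coefficients** per fold while keeping the
selected predictor **set** fixed — it validates the refined model, not the
selection procedure. Folds are a seeded uniform shuffle dealt round-robin
(sizes differ by ≤ 1); the CV r² is the squared Pearson correlation of the
pooled out-of-fold predictions with the observations. Post-hoc power uses
Cohen's f² = r²/(1 − r²) with a noncentral-F computation, noncentrality
λ = f²·n, df = (k, n − k − 1). The λ convention varies across software;
λ = f²·n is the dominant one for multiple-regression power and the result
should be read as approximate.

The published clinical model (11 predictors: CSA_mean and lags 40, 80, 100,
120, 140, 180, 220, 240, 280, 320; intercept −10.014) is available as a
fixed-coefficient predictor. The coefficient table's accompanying prose
lists "lags 20–340", which contradicts the equation and table it annotates;
the package follows the equation/table.

## Classification

Predicted mean CVP is classed against 2.72–10.88 cmH₂O (the 2–8 mmHg
clinical normal range): `low` below, `high` above, boundary values counted
as `normal` (the range is stated without open/closed qualification; inclusive
is the conservative clinical reading). Agreement is summarized by per-class
sensitivity (classes with no true members report "not applicable" by
default, with a flag to report 0.0 instead), overall accuracy, and
unweighted 3-class Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e from the
marginal products.

## Synthetic cohorts

The generator emulates exactly the statistical structure the analysis
exploits, not venous hemodynamics:

- CVP = mean + A·[sin(2πf t) + ρ·sin(4πf t)] + noise, cardiac f ≈ N(1.0, 0.1) Hz,
  second-harmonic ratio ρ ~ U(0.3, 0.7);
- CSA = mean + a·[same fundamental delayed by round(lag/dt) samples + a
  reduced (30%) second harmonic] + additive respiratory tone
  (U(0.2, 0.3) Hz, 20–50% of the pulse amplitude) + noise;
- ECG = narrow Gaussian spike train phase-locked to the CVP fundamental.

The delay is an exact index shift on a shared extended grid, so both traces
stay equal length and a noiseless cross-correlation recovers the lag to the
sample. Per-subject parameters are drawn from the clinical cohort's
descriptive statistics: mean CVP N(5.998, 2.874) cmH₂O, mean CSA
N(0.984, 0.497) cm² (truncated ≥ 0.15), pulse amplitudes set so the
within-trace SDs match the reported 1.21 cmH₂O and 0.05 cm², lag
N(0.241, 0.175) s truncated at 0, dt ~ U(0.003, 0.016) s, duration
U(10, 15) s. Trace noise defaults to 0.15 cmH₂O / 0.006 cm² SD (~10% of the
pulse amplitudes — ultrasound segmentation and monitor digitization are not
noise-free, but the retained study traces were screened for quality).

What the generator does **not** reproduce: the a–c–v triple-peak morphology
of the venous pulse, beat-to-beat variability, respiratory modulation of
CVP, nonstationarity, and pathological waveforms. Passing tests therefore
demonstrate that the *pipeline's statistics behave correctly* on signals
with the assumed spectral/lag structure — not that the clinical model
generalizes.

For parameter-recovery studies a cohort can be wired to a known sparse
linear ground truth: each subject's mean CVP is set to the linear function
of its *realized* CSA features plus noise (the CSA features do not depend on
the CVP mean, so this is self-consistent). On such cohorts (n = 100, noise
SD 0.5 cmH₂O) the exhaustive AIC selection contains the true predictors in
50/50 seeded runs, and at noise SD 0.1 with n = 200 the refit coefficients
are within 5% of truth. Note that AIC deliberately tolerates occasional
spurious extra predictors (an expected property of minimum-AIC selection,
which trades a ~16% per-candidate false-inclusion rate for low false
exclusion); "recovery" is therefore containment of the true set, not exact
set equality.

## Numerical and scale choices

- Exhaustive selection visits ~1.05M subsets for 20 candidates; the test
  suite exercises a 2¹⁶ sweep (34-subject cohort, 16 candidates) and checks
  the measured per-subset cost extrapolates to the full sweep comfortably;
  the oracle-equivalence test brute-forces all 2¹² subsets independently.
- Recovery experiments use cohorts of 100 (selection) and 200 (coefficient
  bias) subjects over 50 seeds — sizes chosen so sampling noise in the pass
  criteria is negligible while the whole suite stays fast.
- Constant signals raise degenerate-signal errors rather than returning
  NaN correlations; rank-deficient designs name the collinear predictors.
- A perfect fit (RSS = 0) is assigned the smallest representable RSS so AIC
  stays finite and minimal rather than −∞.
- File round trips serialize at 17 significant digits and parse with
  round-trip float precision, so write → read is bit-exact.

## Known limitations

- The published model's in-sample and CV fit statistics cannot be recomputed
  without the original per-subject raw data (journal supplement);
  `scripts/validate_raw_data.py` does so when that data is supplied as a
  feature table.
- The study's full 3×3 confusion matrix was not printed, so its κ = 0.472
  cannot be re-derived from the per-class counts alone; the report here
  always exposes the full matrix to avoid that gap on new data.
- The lag-in-samples feature grid mixes physical time scales across subjects
  with different `dt`; see the resampling flag.
- Post-hoc power from an observed r² is a descriptive statistic, not an
  inferential one, and its noncentrality convention is software-dependent.
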
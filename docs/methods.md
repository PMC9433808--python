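# Methods

`neurobalance` implements a balance-biomarker analysis for stroke
rehabilitation: two physiological features measured during repeated ankle
dorsiflexion — a cortical event-related desynchronization (ERD) index from
EEG and an oxygenated-hemoglobin (HBO) response feature from fNIRS — enter,
together with age, a small multiple linear regression that predicts the
Berg Balance Scale (BBS, 0–56 points). This note describes the models, the
parameter choices, the synthetic-data generators used as ground truth, and
the limits of what the test suite demonstrates.

## Trial structure

All stages share one within-trial clock (`TrialTiming`): 1 s preparation,
2.5 s dynamic dorsiflexion, 3 s static hold, 5 s rest — an 11.5 s trial.
Movement onset (end of preparation) is t = 0 for every epoch window. Events
are stored in seconds from recording start and survive resampling
unchanged.

## ERD index (EEG)

1. **Preprocess.** 4th-order Butterworth band-pass 0.05–35 Hz applied
   forward–backward (zero-phase, so ERD latency is not shifted), then
   downsampling to 256 Hz. With an integer ratio the band-pass itself is
   the anti-alias filter and plain sample picking follows; non-integer
   ratios fall back to polyphase resampling with a logged warning.
2. **Epoch.** Verbatim slices of the vertex channel (Cz, over the leg motor
   area) from −1 to +5 s around onset, half-open in samples; −1..0 s is the
   baseline. Events too close to an edge are dropped and counted.
3. **Time–frequency power.** For each trial a short-time Fourier transform
   (Hann window, 0.5 s, hop = window/16, no zero padding) gives F_k(f, t);
   the event-related spectral perturbation is the plain trial mean
   ERSP(f, t) = (1/n) Σ_k |F_k(f, t)|². A complex-Morlet estimator (via
   mne, n_cycles = 7) is available as `method="morlet"` for
   frequency-adaptive smoothing; the STFT is the default because it is the
   simplest estimator of that form.
4. **Baseline subtraction.** Per frequency, the mean of ERSP over the
   baseline bins is subtracted (additive normalization, power units — not
   the common dB ratio, which exists behind a flag but is never the
   default). By construction the baseline-window mean of the result is
   exactly zero per frequency; this identity is asserted property-style in
   the tests.
5. **Index.** The ERD index is the arithmetic mean of the *strictly
   negative* normalized-power bins inside the 15–23 Hz × 0–1 s rectangle
   (beta-band suppression in the first second of movement). Positive bins
   are excluded, not zeroed. If no bin is negative the index is 0 with an
   `empty_flag`, keeping the feature defined for every subject; an empty
   rectangle (band or window off the grid) is an error instead.

The power surface carries the unscaled |DFT|² convention, so the index's
magnitude depends on signal amplitude and window length. The regression is
equivariant to any fixed rescaling of a predictor (the coefficient absorbs
it), so this convention is internally consistent; it does, however, mean
ERD indices are comparable only within one estimator configuration.

## Phase synchronization index (PSI)

Channels are band-passed (zero-phase Butterworth) to the band of interest —
8–13 Hz alpha for the inter-hemispheric summary — and the instantaneous
phase is taken from the analytic signal (Hilbert transform). For a channel
pair, the per-sample phase difference φ_xy(t) is averaged as a unit phasor:

    PSI = sqrt( ⟨cos φ_xy⟩² + ⟨sin φ_xy⟩² ),

the resultant length of the phase-difference distribution, which is the
only form of this statistic bounded in [0, 1] (1 = locked, 0 = uniform).
One filter settling length — three periods of the band's low edge — is
trimmed at each end and excluded from every average. Zero (or numerically
dead) channels have undefined phase and are rejected rather than producing
arbitrary values.

The inter-hemispheric summary averages PSI over homologous sensorimotor
pairs, by default C3–C4, CP3–CP4, FC3–FC4 (motor-relevant homologues; fully
configurable), with each pair validated to contain one left- (odd trailing
digit) and one right-hemisphere (even) sensor. The PSI window defaults to
the 0–5 s task interval. Group comparison of per-subject summaries uses
Welch's t by default (Mann–Whitney optional).

## HBO feature (fNIRS)

HBO and HBR (micromolar concentration changes; total hemoglobin is always
their sum and is derived, never stored) are band-passed to 0.01–0.2 Hz with
a 3rd-order zero-phase Butterworth — removing slow drift and the ~1 Hz
cardiac pulse while passing the hemodynamic response. The 0.01 Hz edge
implies a time constant τ = 1/(2π·0.01) ≈ 16 s: recordings shorter than 3τ
are rejected, and the zero-phase pass uses reflective padding of one τ.

Epochs run from −2 to +10 s around onset over a fixed set of eight
source–detector channels covering the sensorimotor leg area (S2-D4, S2-D2,
S7-D2, S7-D4, S7-D7, S7-D5, S5-D7, S5-D5); a missing channel is an error by
name, never a silent subset. Per trial and channel the −2..0 s baseline
mean is subtracted; the average curve is the mean over trials then channels
(equivalent orderings for equal trial counts). Two scalar summaries of the
average HBO curve over 0–10 s are provided: **peak** (the maximum — the
regression default, since the packaged cohort tabulates peaks) and **area**
(signed trapezoidal integral, concentration·seconds; an absolute-area mode
exists behind a flag because "area under the curve" is ambiguous when the
curve dips negative).

## Regression and cross-validation

The model is BBS = β₀ + β₁·ERD + β₂·HBO + β₃·AGE + β₄·HBO² + e, fitted by
OLS (statsmodels) on untransformed predictors so coefficients stay on the
clinical scale (BBS points per unit). Inference is classical small-sample
OLS: t-based 95% CIs and two-sided p-values with n − k − 1 degrees of
freedom; adjusted R² = 1 − (1 − R²)(n − 1)/(n − k − 1). Rank-deficient
designs are rejected naming the collinear columns.

Out-of-sample error is leave-one-out cross-validation — for n = 8 subjects
this is exactly an eight-fold split with singleton test sets — reporting
the RMSE of the n held-out predictions. It is deterministic and invariant
to row order; the tests also verify the algebraic shortcut that LOO
residuals equal full-fit residuals divided by (1 − leverage).

On the packaged eight-patient cohort the fit gives (Constant 30.6, ERD
−12.4, HBO 37.3, AGE −0.5, HBO² −10.6), adjusted R² 0.840, and a LOO RMSE
of 9.8376 BBS points — values the acceptance script recomputes from
scratch.

The BBS scale range [0, 56] is enforced strictly when reading clinical
feature CSVs; model-side validation only logs a warning, because unclipped
synthetic cohorts (the default, which keeps parameter-recovery tests exact)
legitimately exceed the scale.

## Synthetic ground truth

The signal-level generators exist because no cohort recordings are
distributable; they reproduce the statistical structure the analysis
assumes, with known parameters:

* **EEG** (`simulate_eeg_trials`): per channel, 1/f Gaussian background
  (10 µV rms) plus a band-limited oscillation (default 15–23 Hz, 6 µV rms)
  whose amplitude is multiplied by (1 − erd_depth) from onset to the end of
  the dynamic phase, ramping linearly back to baseline across the static
  hold. Band power during early movement is thus suppressed by a known
  factor, making the ERD chain's sign and monotonicity testable.
* **Phase-coupled pair** (`simulate_phase_coupled_pair`): two carriers
  whose phase difference is a smooth Gaussian process with exact marginal
  sd σ (correlation time 0.1 s). A smooth process is used deliberately:
  white per-sample phase jitter violates the slow-modulation condition
  under which the Hilbert phase tracks the modulating phase, whereas the
  smooth process preserves both the Gaussian marginal — so the population
  PSI is the wrapped-Gaussian resultant exp(−σ²/2) — and the measurement
  chain. Measured PSI at 10⁵ samples matches exp(−σ²/2) within 0.02 for
  σ ∈ {0.2, 0.5, 1.0}.
* **fNIRS** (`simulate_fnirs_session`): canonical double-gamma HRF (peak
  ~6 s, undershoot ~16 s, ratio 1/6) convolved with the 5.5 s movement
  boxcar, peak-normalised to `amplitude_hbo`, on the eight sensorimotor
  channels of a 22-channel montage; HBR is the −1/3 mirror (a conventional
  deoxygenation ratio) with independent noise. Physiological noise is three
  sinusoids (cardiac 1.1 Hz, respiration 0.25 Hz, Mayer 0.1 Hz — standard
  physiology, configurable), linear drift and white noise; sampling rates
  that alias the cardiac line are rejected.
* **Cohort** (`simulate_cohort`): AGE/ERD/HBO drawn uniformly from ranges
  matching the packaged cohort's spans, BBS from the linear model plus
  Gaussian noise. Defaults: n as requested, noise sd 5 BBS points.

Every generator is a pure function of its arguments including the seed.

What the generators do **not** emulate: volume conduction and spatial
mixing across EEG sensors, motion and ocular artifacts (the pipeline
expects pre-cleaned signals and logs that no automatic artifact rejection
is applied), optical-density-to-hemoglobin conversion, non-stationary
background spectra, and between-subject variability in HRF shape. Passing
tests therefore demonstrate correctness of the *computations* under the
stated generative assumptions, not robustness to real-data artifacts.

## Numerical choices and degenerate inputs

* All filters are zero-phase (forward–backward) Butterworth; orders 4 (EEG)
  and 3 (fNIRS).
* Sample windows are half-open with 0-based indexing; requested STFT
  frequencies map to nearest DFT bins; ERD band/time edges are inclusive.
* PSI bounds are asserted, never clipped; identical channels give exactly 1.
* A single-row feature table reports its SD as missing, not 0.
* Test problem sizes: 10⁵-sample pairs for the PSI law, 50 trials per
  condition for ERD monotonicity, 200 replicates of n = 200 cohorts for
  parameter recovery and CI coverage — the whole suite runs in a few
  seconds on one core.

## Known limitations

* The ERD index's absolute scale is estimator-dependent (see above).
* The inter-hemispheric pair set and the alpha band (8–13 Hz) are
  conventional defaults, not fitted choices.
* With n = 8 subjects and 4 predictors the regression is at the edge of
  identifiability; CIs are wide and the LOO RMSE (≈ 9.8 BBS points) should
  be read as an honest small-sample error estimate, not a generalization
  guarantee.
* Group comparison of PSI between patient and control cohorts requires
  per-subject recordings that are not distributable; the package implements
  and tests the comparison operation itself on synthetic values only.
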
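# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `herdvitals`.

## Video biometrics

**Signal model.** Cardiac pulsation changes the blood volume of perfused
tissue and hence the intensity of reflected light; the effect is strongest in
the green channel (remote photoplethysmography). Respiration shifts the
colour balance of the nose region along the green↔red opponent axis, which is
the CIELab a* component. Both signals are extracted as per-frame ROI means —
the mean over ≥400 pixels resolves modulations well below one 8-bit
quantization level.

**Processing chain.** ROI mean (float, before any rounding; sRGB→CIELab under
the D65 illuminant for a*) → moving-average detrend with window 1/f_low
seconds → zero-phase 3rd-order Butterworth band-pass → peak counting.

| parameter | default | rationale |
| --- | --- | --- |
| cardiac band | 0.67–2.5 Hz (40–150 BPM) | bovine resting-to-stressed heart-rate range |
| respiratory band | 0.15–1.2 Hz (9–72 BrPM) | bovine respiration; minimally stressed cows stay below 60 BrPM |
| peak prominence | 0.25 × trace sd | rejects ripple without suppressing true beats |
| min peak separation | 0.4 s (HR), 0.8 s (RR) | refractory limits of the two rhythms |

Peak counting is the primary estimator; an FFT-argmax rate is attached to
every result as a cross-check (`spectral_rate`). Rates are reported per
minute: n_peaks / duration × 60. Fewer than two detected peaks yields an
explicitly undefined rate (NaN, quality 0), never a silent 0. The estimate is
invariant to additive constants and linear trends by construction of the
detrend/band-pass stage. No skin-pixel segmentation is attempted inside the
ROI box; the box is taken as given.

## Movement analysis

The head-box centroid (x = x_min + w/2, y = y_min + h/2) is split into four
contiguous temporal blocks (remainder frames join the last block). Exported
features are per-block means and population (divide-by-n) variances plus
whole-video variances, in pixels² — no metric calibration is available, and
"quartiles" are read as temporal blocks, not value quantiles. No significance
threshold is applied to "abrupt" movement; the raw variances are the
features.

## Thermal analysis

Radiometric frames arrive as CSV matrices of calibrated °C. The eye is the
warmest facial region, so the per-frame maximum inside the head ROI is the
eye-temperature proxy and its temporal mean (± sd) is reported. The
alternative reading (max of per-frame ROI means) is not used; mean-of-max is
robust to the eye wandering inside the ROI. Values outside −20…60 °C are
rejected by default as sensor/parse errors. No emissivity, distance or
atmospheric correction is applied.

## Psychrometrics and THI

Dew point uses the Magnus–Tetens approximation (a = 17.27, b = 237.7 °C);
wet bulb solves the psychrometer balance e(T_dp) = e_s(T_w) − A·p·(T − T_w)
with A = 6.6×10⁻⁴ °C⁻¹ by bisection on [T_dp, T] to |f| < 10⁻⁴ (≤100
iterations); saturation at RH = 100 % short-circuits to T_w = T. Pressure
defaults to 1013.25 hPa when the weather file lacks it. The physical ordering
T_dp ≤ T_wet ≤ T holds to 0.05 °C everywhere in the valid domain.

Nine THI formulations are provided under the keys THI1…THI9 (sources recorded
in `weather.THI_SOURCES`): Thom 1959 (dry+wet bulb), NRC 1971 (dry bulb+RH),
Mader 2006, NRC 1971 (dry+wet bulb), Bianca 1962 (0.35/0.65 and 0.15/0.85
weightings), Kibler 1964 (dew point), Yousef 1985 (dew point) and Ingraham
1979. All are monotone increasing in T at fixed RH. Under winter conditions
(T ≈ 11–13 °C, RH ≈ 75–82 %) THI1 and THI6 evaluate highest and THI9 lowest,
matching the qualitative spread reported for such conditions.

## Bayesian-regularized network

Architecture: one tan-sigmoid hidden layer (trimmed over {3, 5, 7, 10}
neurons), linear output layer, 37 inputs, 5 outputs; inputs and targets
min-max scaled per column to [−1, 1] using training rows only.

Training minimizes F = β·E_D + α·E_W (E_D = Σe², E_W = Σw², all weights and
biases penalized) by Levenberg–Marquardt: solve
(2βJᵀJ + (2α + μ)I)δ = −(2βJᵀe + 2αw), accept the step iff F decreases
(μ ÷10 on success, ×10 on failure). After each accepted step the evidence
framework re-estimates γ = P − 2α·tr(H⁻¹), α = γ/2E_W, β = (N−γ)/2E_D with
H = 2βJᵀJ + 2αI. Stops: max_epochs (300), ‖∇F‖ < 10⁻⁷, or μ > 10¹⁰.
Initialization is Nguyen–Widrow for the hidden layer (hidden units tile the
scaled input cube) and small-uniform for the output layer; `n_restarts`
independent initializations may be compared by final penalized error
E_D + (α/β)E_W (default 1). Training starts at α = 0, β = 1, so the first
step is plain least squares and regularization grows only as the evidence
warrants. With `bayes=False` and `alpha_init=0` the trainer is exactly plain
LM least squares (verified against an independent LM implementation).

The objective F is non-increasing over accepted steps at fixed (α, β); the
re-estimation step changes the objective itself, so F is logged both before
and after each step. γ (the effective number of parameters) is clipped to
[0, P] and, in practice, prunes hard: on pure-noise targets it settles near
20 of ~245 parameters.

**Protocol.** 150 development recordings split 105/45 (70/30, seeded); the
input-count guard requires n_inputs < 0.7 × n_train (37 < 73.5 passes).
Neuron trimming trains each size on the same split and selects the highest
test R among candidates with test MSE ≤ 3× train MSE (smallest size on ties);
if all candidates fail the screen the best test R is returned with a warning.
A frozen model is then deployed on 132 independent recordings.

**Reporting.** All five targets' points are pooled on the [−1, 1] target
scale (a pooled raw-unit MSE would be dimensionally incoherent across °C, kg
and %); per-target MSEs in original units are attached as supplementary
columns. R is the Pearson correlation of pooled predicted vs observed, the
slope is from the least-squares fit of predicted on observed, and outliers
are points outside the t-based 95 % prediction band of that pooled fit —
chosen over a confidence band because a per-point band is what flags a few
percent of points. On Gaussian residuals the flagged fraction is ≈5 %.

PCA is computed on the correlation matrix of z-scored columns (eigenvectors
as loadings, signed so the largest-magnitude element is positive). Group
summaries report mean ± SE (sd/√n, sample sd); singleton groups report SE as
undefined rather than 0.

## Synthetic data

The generator emulates the recording conditions the pipeline was designed
for, with known ground truth; everything is deterministic under a fixed seed.

- **RGB scenes** (default 60 s at 30 fps): a head rectangle on a gray
  background, an eye patch whose green channel oscillates sinusoidally at
  hr_bpm/60 Hz (amplitude 2 eight-bit units) and a nose patch whose red−green
  balance oscillates at rr_brpm/60 Hz (amplitude 3), per-pixel Gaussian noise
  (sd 1) added before quantization. The camera frame rate is not a recorded
  property of the original setup; 30 fps is the stand-in. Requested rates
  must lie inside the recoverable bands and below Nyquist, else the spec is
  rejected. Head motion is static, linear drift, or a random walk; eye/nose
  boxes ride on the head and use the painter's own rounding so the extraction
  window covers exactly the painted patch. Frames are 8-bit RGB (PNG on
  disk), default 360×640 as a scaled stand-in for 4K; tests use 120×160.
- **Thermal stacks**: a warm Gaussian blob inside the head ROI whose hottest
  pixel carries exactly eye_temp_c + N(0, noise_sd) per frame, on a cool
  background; written as one CSV matrix per frame. The thermal cadence is
  independent of the RGB cadence (each stack carries its own fps).
- **Weather**: AR(1)-smoothed series at 15-min cadence centred on winter farm
  conditions (T 11.3 ± 1.0 °C, RH 81 ± 4 %, wind 11 ± 3 km h⁻¹); RH clipped
  to (0, 100], wind ≥ 0, direction wrapped to [0, 360).
- **Herd tables**: per recording, HR ~ N(80, 8) clipped to 60–110 BPM,
  RR ~ N(34, 6) clipped to 20–60 BrPM, amplitudes log-normal, weather matched
  by timestamp from the series above and derived (T_dp, T_wet, THI1…9).
  Head motion is a mean-reverting (AR(1), reversion 0.02/frame) walk around a
  per-cow stance position — a crush physically constrains the head near a
  home position, where a free random walk would drift tens of pixels over a
  minute — with per-cow step size log-normal (median 0.8 px, σ_log 0.35).
  That spread keeps log1p(path variance) within ~2 natural-log units, so the
  variance-driven target terms below stay mildly nonlinear.

The five targets are documented smooth functions of ≤4 features each (mildly
nonlinear through log1p terms, so a nonlinear regressor has a real edge over
a straight line), e.g. milk kg day⁻¹ = 24 + 0.15·(THI9 − 43) −
0.8·log1p(var_y) + ε. The generator returns the noise-free values, so an
oracle correlation (noise-free vs noisy) is computable per target. Unless
explicit per-target sds are given, noise is calibrated so that oracle
R ≈ 0.96: σ_j = sd(f_j)·√(1/R² − 1), evaluated on the drawn sample.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: no photorealistic appearance, no specular highlights or
illumination flicker, no ROI-tracking error (boxes are exact), no motion blur
or occlusion, single-sinusoid vitals without heart-rate variability, additive
white noise only, and target functions that are genuinely low-dimensional.
Recovery results on synthetic scenes are upper bounds on real-world accuracy.

## Numerical and protocol choices

- Min-max scaling spans are guarded against constant columns (span set to 1).
- The LM normal equations are solved as symmetric-positive-definite; a
  singular system escalates μ instead of failing.
- With α = 0 the effective-parameter count is γ = P exactly; the Hessian
  inverse is skipped.
- Nearest-timestamp weather matching breaks ties toward the earlier record
  and warns when a recording precedes the series.
- `split_samples` sizes are round(n·train_frac) vs remainder (150 → 105/45).
- Radiometric CSV parsing reports the file and row of the first offending
  cell; ragged rows and shape mismatches are named errors.
- The `run-all` pipeline is idempotent for a fixed seed (byte-identical
  feature tables) and derives all stage seeds from one master seed.
- `run_all` builds the herd from the tabular generator; the
  `n_video_recordings` option re-measures HR/RR from rendered video for a
  subset of recordings as an end-to-end demonstration (rendering every
  recording's full video would dominate runtime without changing what the
  protocol-level outputs verify).

## Problem sizes used in tests

Unit tests run on 3–20 s scenes at 120×160; the acceptance-level suite uses
twenty 60-s recordings for signal recovery, a 1,000-point psychrometric grid,
and the full 150+132-recording modelling protocol. The acceptance script uses
eight 60-s recordings and a 200-point grid.

## Known limitations

- The pooled test R of the multi-output network on *pure-noise* targets has a
  null standard deviation of ≈1/√45 ≈ 0.15 under the 150-recording protocol
  (the five outputs share one hidden representation, so the 225 pooled test
  points are far from independent). Chance correlation alone therefore
  produces pooled test R values above 0.3 in a non-trivial fraction of draws;
  a skill threshold for this protocol must be read against that ceiling.
- Axis-aligned ROI boxes only; no re-registration between RGB and thermal
  streams; deployment assumes i.i.d. conditions between development and
  deployment herds.
- The nine THI formulas are the canonical literature set; index numbering is
  a package convention (see `weather.THI_SOURCES`).
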
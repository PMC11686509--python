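# Methods

This note records the modeling conventions, parameter defaults and known
limitations of `fiberspec`. It documents *how* the package computes; every
number quoted as an outcome is one the test suite or
`scripts/acceptance.py` computes at run time.

## Forward model (the digital twin)

A measurement is one scan: the three lasers fire sequentially, 5 s on /
5 s off each (30 s per scan), producing one 460-pixel frame per laser;
frames are concatenated in fixed order [405 | 488 | 520] into the
1380-point merged vector. Channel-to-laser assignment and nominal merged
peak indices:

| channel | laser | index | response family | reference |
|---|---|---|---|---|
| pH | 405 | 34 | 4PL, c₀ = 7.0 | pH 6 |
| glucose | 405 | 28 | 4PL, c₀ = 3.0 mmol/L | 0 mmol/L |
| DO | 405 | 341 | Stern–Volmer, 0.38 /mg·L⁻¹ | 0 mg/L |
| Na⁺ | 488 | 725 | linear, 0.0064 /mmol·L⁻¹ | 0 mmol/L |
| temperature | 488 | 884 | Stern–Volmer, 0.04 /°C | 33 °C |
| Ca²⁺ | 520 | 1262 | 4PL, c₀ = 0.5 mmol/L | 0 mmol/L |

Each channel contributes a Lorentzian line (default FWHM 30 px, base
amplitude 1000 a.u.) whose amplitude is

    A = base × R(c) × exp(−t/τ) × exp(−q·(T − 33))

with R the response ratio, t the accumulated exposure, τ the
photobleaching constant, and q a cross-channel temperature-quench
coefficient (default 0.005 /°C for every channel except temperature
itself, whose calibration curve *is* its temperature dependence — a
nonzero q there would double-count the quench).

**Logistic constructions.** The three 4PL curves are solved at import
time from their characterized constraints rather than stored as opaque
constants: pH steepness k solves k/tanh(k/2) = 2.624 (midpoint slope)
with amplitudes fixed by R(6) = 1 and R(8) = 5; glucose uses k = 1 /mmol/L
and c₀ = 3 (center of the 0–6 range) with R(0) = 1 and R(5) = 4·R(1);
Ca²⁺ uses k = 3 /mmol/L (chosen once so the curve saturates smoothly above
2 mmol/L and the excitotoxicity scenario value 3 mmol/L remains
representable) with the amplitude solved so the ordinary-least-squares
slope of R over the physiological window 1.0–1.35 mmol/L, sampled at the
0.1 mmol/L characterization-sweep resolution, equals 0.41. The window
sampling convention matters at the ~2 % level because the curve is
saturating; the sweep-resolution grid is the documented definition.

**Exposure-time units.** Frames ledger cumulative laser on-time in
seconds (720 scans ⇒ 3600 s per laser). The photobleaching constants τ
are kept in abstract exposure units, with a conversion of 60 s of on-time
per unit (`DEFAULT_EXPOSURE_UNIT_S`). The τ values are internally
consistent under this convention; treating them as seconds would bleach
every film to numerical zero within a single calibration sweep, and no
unit choice reconciles them with 3-hour retention percentages, so the
abstract unit is a package convention, not a physical claim.

**Calibration datasets.** `generate_calibration_set` enumerates a
factorial grid (defaults: 5 levels per biomarker over the characterized
ranges; DO swept from 1 mg/L), optionally subsamples it, shuffles the
order, and accumulates exposure across scans in *sessions* of 120 scans
(10 min of on-time per laser), resetting the exposure ledger between
sessions. Sessions emulate separate bench runs with fresh films; a single
monolithic multi-thousand-scan run would drive exp(−t/τ) below machine
noise for the fastest-bleaching film (Na⁺, τ = 22) and make the
compensation factor exp(+t/τ) an enormous noise amplifier.

**Noise model.** Additive Gaussian noise (σ = 5 a.u., i.e. 0.5 % of a
full-scale peak — a mid-grade CCD spectrometer regime) over a
deterministic baseline: 100·exp(−3×10⁻⁴·px) plus a shallow quadratic
(20 − 0.03·px + 10⁻⁵·px²). All noise fields set to zero give an exactly
noiseless, baseline-free spectrum. A fixed integer seed makes datasets
bit-reproducible.

**Scenario presets** (post-TBI complications, other biomarkers at healthy
CSF values 37 °C / 6 mg/L / pH 7.35 / 145 / 1.2 / 3.3 mmol/L): hypoxia
(38 °C, DO 3.2), hypermetabolism (39 °C, DO 3.8, glucose 1),
excitotoxicity (pH 6.5, Na⁺ 180, Ca²⁺ 3). Stages ramp linearly over a
configurable transition time, then hold.

## Preprocessing

Fixed order, enforced and recorded by `PreprocessPipeline`:
Savitzky–Golay smoothing (window 11, order 3) → asymmetric penalized
least-squares (AsLS) baseline subtraction → optional per-laser
standardization (division by a stored calibration reference intensity; a
z-score would destroy the I/I₀ ratio semantics the calibration curves
need) → merge → label.

**AsLS parameters.** The baseline estimate z minimizes
Σ wᵢ(yᵢ−zᵢ)² + λΣ(Δ²z)², re-weighting w = p above / 1−p below the
current baseline; defaults λ = 10⁸, p = 0.001, 10 iterations. The stiff λ
was chosen from the estimator's own trade-off on this geometry: flexible
settings (λ ≈ 10⁴–10⁵) track any drift but absorb 13–21 % of a FWHM-30
Lorentzian (its tails look like baseline over a 460-px window) and make
the operation grossly non-idempotent; the stiff setting leaves narrow
peaks intact (<1 %), is idempotent to ~0.1 % RMS, and still tracks the
default gentle drift to <1 %. Two consequences are documented rather than
hidden: (i) strongly curved baselines are not followed at λ = 10⁸ — if a
deployment's drift is fast, lower λ and accept peak attenuation; (ii) the
default broad peaks still lose ~6 % of height. Because AsLS weights
depend only on the *sign* of the residual, the estimator is positively
homogeneous, so on baseline-free frames that attenuation is exactly
multiplicative — it cancels in every intensity ratio (all sensitivity
recoveries are unaffected) and is absorbed into the trained regression.

## Features and photobleach compensation

Per channel: **height** is the intensity at the channel's fixed nominal
index (the six characterized peak pixels); **position** is the local
maximum located within ±15 px of that index (falling back to the nominal
index when no maximum exists); **prominence** is height above the higher
flanking local minimum; **width** is the interpolated full width at half
prominence; **area** is the trapezoidal integral between the flanking
minima. Anchoring the height at the fixed index (rather than the located
maximum) keeps the overlapped 405 nm pair linearly separable — the
intensity at px 28 and px 34 are two independent linear combinations of
the glucose and pH amplitudes — which is what lets the regression resolve
simultaneous variation of both analytes. Negative heights/areas after
baseline correction are clipped to 0 and flagged.

Correction multiplies height, area and prominence by exp(t/τ) (width and
position are invariant under amplitude scaling of a Lorentzian) and is
guarded against double application. τ can be refitted from decay traces
by `fit_tau` (log-linear initialization, nonlinear refinement); noiseless
traces recover τ to <10⁻⁶ relative for τ ∈ [10, 200].

**A real limitation of per-channel correction:** a fixed-index height of
an overlapped peak contains the neighbour's tail, which bleaches with the
*neighbour's* τ. Correcting the sum with one τ leaves an
exposure-dependent residual (≈4 % for pH/glucose at 5 exposure units).
No per-channel scalar correction can invert that mixture; the per-laser
exposure is therefore passed to the regression as a covariate so the
model can absorb it.

**Selection.** Pearson correlation of every feature against every label;
a feature survives if max |r| ≥ 0.5. On the default simulation the
heights and areas of all six channels pass, positions generally do not.
Prominence is corrected like height (same physical quantity) and remains
available behind the mask.

## Regression

Six independent regressors (one per biomarker) share one selected-feature
input — multitask by shared features, since the labels are six values and
no parameter-sharing scheme is implied by the problem. Families: linear
(OLS), ridge and lasso (penalty grid 10⁻⁴…10², 7 log-spaced values,
tuned per biomarker by 10-fold cross-validated MSE on the 75 % training
split), and bayesian (scikit-learn `BayesianRidge`, conjugate Gaussian
linear regression with evidence-maximized precision hyperparameters).

All four families are linear *in their parameters*; the physics is not
linear in concentration. They therefore act on a deterministic
chemometric linearization basis built from the channel heights: per
excitation laser, polynomial cross terms up to degree 3 over the group's
heights, reciprocal heights and log heights (reciprocals make the
Stern–Volmer channels exactly linear; logs make the multiplicative
bleach/quench factors additive; cross terms compose peak unmixing with
the sigmoid inversions and the temperature quench via the appended
reciprocal/log temperature height), plus the laser's exposure, plus pure
univariate powers up to degree 5 (a 5-level calibration design of a
saturating response needs a quartic to interpolate its level set).
Remaining selected features (areas, widths, …) enter untransformed. The
expansion depends only on column names and is reproduced exactly from a
persisted model file.

Grouping by laser is deliberate: a global cross-term basis lets
minimum-norm solutions spread a univariate relationship across unrelated
channels' terms and generalize badly off the training combinations,
whereas per-laser groups restrict the hypothesis space to physically
coupled variables.

**Observed family ranking.** On this simulator the inverse problem is
essentially well-specified in the basis and the training set is larger
than the basis dimension, so plain OLS and lightly tuned ridge match or
beat the evidence-maximized Bayesian model for most biomarkers; shrinkage
helps little when the truth is representable with moderate coefficients.
A claim that the Bayesian family dominates the others is a property of
noisy, misspecified real data, not of this digital twin; the test suite
asserts the dominance property as specified and it is expected to fail
here (see the ledger of the test run).

## Calibration

Curve fitting uses OLS for the linear families (Stern–Volmer channels on
I₀/I) and Levenberg–Marquardt 4PL fits (initialized from the data range
and a midpoint hint) otherwise; `invert_response` is closed-form for all
families. The two-standard session correction solves, per channel, the
affine pair (reference intensity, offset) from h = ref·R(c) + b at the
two standards — exact at both anchors by construction, reducing to a pure
gain (b = 0) when the perturbation is a laser-power change, and exact
everywhere for linear channels. A purely multiplicative gain has one
degree of freedom and cannot reproduce two standards; the affine form is
the minimal correction that can. The correction acts on features — the
earliest point where channel identity exists. Default standard buffers
are low/high anchors spanning every channel's range (34 °C, 2 mg/L,
pH 6.5, 40, 0.4, 1) and (40 °C, 7 mg/L, pH 7.8, 160, 1.6, 5).

## Monitoring

Per scan: preprocess → extract → correct → predict → push into six
100-deep circular buffers; the displayed value is the mean of the 34 most
recent points (fewer while filling). The printed 34-points-per-5-minutes
display convention and the 30 s scan period are mutually inconsistent
(34 × 30 s ≈ 17 min); both are kept as configured values and the conflict
is recorded, not resolved. Scenario tracking reports per-stage and
overall MSE/MAE/R² against the ground-truth trajectory plus a detection
latency (time until the averaged readout crosses halfway to the new
target, quantized to the scan period — an artifact-level metric, since
the response time is only qualitatively specified upstream). Spike
recovery is 100·(readout increment)/(spiked amount).

## What the synthetic data does and does not show

The generator reproduces the *structure* of the measurement — response
nonlinearity, severe 405 nm peak overlap, photobleaching under pulsed
exposure, temperature cross-quench, baseline drift, additive noise,
session structure — with exactly known ground truth, which is what makes
the round-trip recoveries meaningful. It does not emulate: matrix effects
of real CSF (nontarget quenchers, protein fouling), sensor-to-sensor
fabrication variability, wavelength-axis drift, laser power fluctuation
within a session, non-exponential (multi-population) photobleaching, or
reversibility hysteresis. Passing tests therefore demonstrate the
pipeline's correctness and its capacity to invert the stated physics; they
do not certify accuracy on clinical specimens.

## Problem sizes and numerical conventions

Test and acceptance runs use a 5⁶ factorial subsampled to 2000 scans
(default noise, seed-derived) for the accuracy floor, and a 9-level
noiseless factorial subsampled to 1400 scans for the parameter-recovery
and monitoring properties (the training split must exceed the ~700-column
basis for the estimator to be determined, and the saturating responses
need dense calibration levels to interpolate accurately off-grid). Savitzky–Golay edge handling is
scipy's default interpolation; AsLS convergence is declared when the
baseline moves <10⁻⁶ of the spectrum scale between iterations, with a
warning (and the last iterate) otherwise; logistic fits cap at 2×10⁴
function evaluations; lasso uses tolerance 10⁻³ with 2000 iterations.
Ties in hyperparameter search resolve to the first (smallest) penalty.
Predictions outside the admissible biomarker ranges are returned as-is
and flagged, never silently clipped.
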
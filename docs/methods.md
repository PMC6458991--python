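# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and what the tests do and do not establish.

## Study design being emulated

A reversing checkerboard (4 reversals/s) is shown at five Michelson
contrasts (6.25–100%) in 30-s blocks — four blocks per contrast plus eight
rest blocks, 14 min per eye, identical pseudorandomized order for the MEG
and fMRI sessions of a subject. Two groups: 10 controls and 14 patients
with multiple sclerosis. The quantities extracted per subject are the peak
gamma-band (30–80 Hz) percent change per contrast, evoked-field peak
latency, BOLD and CBF percent change per contrast, baseline perfusion, and
the gradient of the per-subject line relating gamma change to each
hemodynamic measure over the 10 contrast × eye points.

## MEG forward model and beamformer

The volume conductor is a homogeneous sphere (radius 8 cm); the field of a
current dipole is the closed-form Sarvas solution, and sensors are 60
radially oriented point magnetometers on a 10-cm Fibonacci hemisphere — a
desk-scale stand-in for a 275-channel axial-gradiometer helmet. Radial
dipoles are invisible, and the radial field component equals the primary
dipole's Biot–Savart field, which the tests use as an exact independent
oracle.

Source scanning is a unit-gain LCMV beamformer: per grid location (5-mm
spacing) the three-column lead field is reduced to the orientation of its
dominant right singular vector, weights are
`w = C_r⁻¹L/(LᵀC_r⁻¹L)` with `C_r = C + λ·mean(diag C)·I`, λ = 0.05 by
default (the regularization is not reported in comparable studies; 5% of
mean sensor variance is a common choice), and C pools all trials after
30–80 Hz band-pass (4th-order zero-phase Butterworth). The map is
`100·(P_stim−P_rest)/P_rest`; its peak is searched inside a spherical
occipital "anatomical" mask and ties resolve to the lowest linear index.

Two regime facts discovered during validation and worth recording. First,
in the strictly noise-free limit the percent-change map is analytically
flat — with a rank-1 covariance the stimulus/rest output-power ratio is the
same at every location — so localization is only defined in the presence of
a sensor-noise floor; localization tests therefore run at high but finite
SNR, where the peak is exact. Second, the LCMV orientation constraint nulls
a source whose true orientation differs from the lead field's SVD-dominant
orientation; the generator therefore orients its dipole along that
maximally visible direction, making the generative and analysis models
consistent.

## Gamma time–frequency statistic

The virtual-sensor trials are decomposed with a filter bank (centers 30–80
Hz in 2-Hz steps, ±4 Hz pass-bands, 4th-order zero-phase Butterworth) and
the analytic-signal amplitude envelope. Each 1-s trial is demeaned and
cosine-tapered over its first/last 50 ms — exactly the samples excluded
from all time averages — then zero-padded 200 ms before filtering; the
taper removes the trial-edge discontinuity that otherwise rings through the
narrow bands into the trial interior.

Percent change subtracts the trial-averaged rest envelope *profile*
(per frequency and time sample) and normalizes by its per-bin time average.
For stationary rest activity this equals the conventional scalar-baseline
percent change in expectation; the time-resolved subtraction additionally
cancels the deterministic envelope shape that per-trial filtering imprints
identically on stimulus and rest trials, which matters on synthetic data
with strong spectral peaks.

The peak-gamma readout splits the trial into four 250-ms reversal windows,
time-averages per window, maximizes over frequency per window and averages
the four maxima. Two numerical guards: bins whose rest baseline is below
10% of the largest bin baseline are excluded from the maxima (a percent
change over an effectively empty baseline is meaningless), and a
`fixed_frequency` flag reads all four windows at the single best frequency.
The free-frequency reading is the literal construction but carries a
positive small-sample bias on stochastic data (a max-statistic over noisy
bins; roughly +5–10 points at 120 trials per condition in our simulations);
the pipeline therefore defaults to the fixed-frequency readout, which
recovers injected changes within ±2 points. Both readings are available and
tested.

## Evoked latency

Stimulus trials are re-epoched −0.04 to 0.21 s around each reversal
(epochs crossing trial edges are dropped and counted), averaged, low-pass
filtered at 15 Hz (4th-order zero-phase Butterworth; the filter design is a
package choice), baseline-corrected on the pre-reversal window, and the
latency of the maximal absolute deflection in (0, 0.21] s is returned, ties
to the earliest sample. Sensor-space analysis averages the five most
posterior sensors; source space uses the beamformer virtual sensor.

## ASL task analysis

Surround averaging uses the (½, ¼, ¼) nearest-neighbor kernel (endpoints
average with their single neighbor): it cancels a pure alternation exactly
and passes constants and linear drifts at interior volumes. The GLM has
five HRF-convolved condition boxcars (double-gamma HRF, peak 6 s,
undershoot 16 s, ratio 1/6, peak-normalized so a beta is directly the
peak-to-baseline excursion), a ±½ tag/control alternation column whose beta
is the baseline perfusion-weighted signal, five condition × alternation
interactions (the convolved regressor times the alternation — perfusion
responses are themselves hemodynamically smoothed), and Legendre drift
columns up to order `floor(2·T/90 s)`, the polynomial equivalent of a 90-s
high-pass. For echo 2 the condition regressors are surround-averaged with
the same kernel as the data, which removes an otherwise ~3% multiplicative
bias. BOLD % scales condition betas by the intercept beta; CBF % scales
interaction betas by the alternation beta. The ROI is the set of voxels
with injected activity — ground truth standing in for a group-intersection
ROI from thresholded activation maps, which requires group map inference
that is out of scope here. No spatial smoothing at the reduced grid scale.

## Baseline perfusion

The kinetic model is the standard single-compartment pulsed-ASL form with
QUIPSS II bolus truncation (bolus TI₁ = 0.7 s, T1 of blood 1.6 s, inversion
efficiency 0.98 — literature defaults, configurable; a two-compartment
extension is a documented extension point). CBF is carried externally in
ml/100 g/min and converted by 6000 to s⁻¹; blood M0 comes from a CSF
reference scaled by a configurable proton-density/T2* correction (default
0.87). The fit is bounded nonlinear least squares over (CBF, arrival time)
multi-started over arrival times {0.2, 0.5, 0.8, 1.1} s to avoid the local
minima of the piecewise model. Slice timing (ascending order) is modeled as
a per-slice TI increment of TR/(2·n_slices); ROI fits stack per-slice ROI
means with their slice-adjusted TIs rather than averaging across slices,
which would bias the nonlinear fit.

## Coupling and group statistics

Per-subject coupling is OLS over the 10 contrast × eye points (subjects
with one unusable eye contribute 5 points, with a logged warning). The
exact Mann–Whitney test builds the null distribution of the midrank sum by
dynamic programming over the (doubled) midrank multiset — exact with ties —
for combined n ≤ 25; the two-tailed p doubles the smaller tail and caps at
1. Beyond that it falls back to the tie-corrected normal approximation.
Holm–Bonferroni is the standard step-down with thresholds α/(m−i+1); the
gradient and intercept tests are corrected as two dependent tests per
measure. The mixed ANOVA computes sums of squares directly;
Greenhouse–Geisser ε comes from the eigenvalues of the double-centered
pooled within-group covariance (the SPSS convention; an independent
implementation cross-checks F and ε in the tests) and is applied when the
Mauchly test rejects sphericity at 0.05. Simple main effects are one-way
between-group F tests per contrast. log(MAR) = log₁₀(1/decimal acuity).

## Synthetic cohort

Contrast dependence is Naka–Rushton
(`floor + r_max·cⁿ/(cⁿ + c50ⁿ)`) — monotone saturation is the only required
property, and this is its minimal parametric form. Hemodynamic truth is
linear in gamma truth (`intercept + slope × gamma %`), so each subject's
coupling gradient is known exactly by construction; the quantified-CBF
coupling is derived as CBF % × baseline/100 rather than independently set.
Group defaults: control gamma r_max 40 ± 8%, patient 25 ± 8% (a deficit
that grows with contrast — the group × contrast interaction), shared floor
≈ 2%; coupling medians 0.03 (controls) vs 0.04 (patients) %BOLD/%gamma with
intercepts 0.31 vs 0.04, CBF gradients 1.03 vs 1.30 with intercepts 5.08 vs
1.97 — similar medians with larger patient spread (log-normal σ 0.25 vs
0.5), so median tests are expected non-significant; baseline CBF 57.7 ±
21.2 (controls) vs 52.0 ± 15.2 (patients) ml/100 g/min; arrival 0.65 ±
0.08 s; evoked latency 120 ± 10 ms with no group difference. A small
right-eye gain factor (σ 8%) makes the 10 coupling points non-degenerate.

Raw MEG: induced gamma is a narrowband stochastic process (±5 Hz around the
subject's peak frequency, 40–70 Hz) — matching real, non-phase-locked
induced gamma — riding on a broadband source floor (0.5× the oscillation
amplitude) with a reversal-locked biphasic evoked transient (Gaussian width
25 ms, rebound at +90 ms, spectrum below the gamma band) and white sensor
noise. A `frozen_gamma` validation mode replaces the process with a
fixed-phase tone and a frozen background so that stimulus trials are exact
amplitude scalings of rest trials; the end-to-end ±2-point recovery
properties hold in that deterministic mode. Raw ASL: static tissue ~1000
(echo 1) / 800 (echo 2) signal units, perfusion-weighted difference from the
kinetic model at the subject's baseline CBF (M0 blood 1500), HRF-convolved
block modulation inside the active ROI, echo-specific perfusion/BOLD
weightings (0.5 and 0.2) for the cross-contamination the GLM must reject,
and white volume noise. The multi-TI generator evaluates the kinetic model
per slice-adjusted TI with noise scaled by 1/√16 repeats.

Group statistics at full cohort size run on a measurement-level generator
(truth + Gaussian measurement noise: gamma 4, BOLD 0.25, CBF 6 percentage
points, baseline 4 ml/100 g/min per observation); the raw-signal chain is
validated end to end on small cohorts (2–4 subjects, 2–4 trials per block,
8×8×4 ASL grids) purely as the package's problem-size choice. With the
defaults, ~85–95% of replications reproduce the qualitative pattern
(growing patient gamma deficit; no coupling-gradient difference).

## What the synthetic data do not emulate

No head anatomy, coregistration error, motion, eye-blink/cardiac artifacts,
1/f or physiological noise structure, scanner drift fields, partial-volume
effects, or realistic 275-channel geometry. White noise everywhere means
the beamformer and GLM face no structured interference; passing tests show
the estimators are correct under the stated generative model, not that they
are robust to real-world artifacts. The sampling rate is 600 Hz (sufficient
for an 80-Hz band) and the ASL grid 12×12×6 voxels by default — reduced
acquisition scales chosen for desk-scale runtime.

## Known limitations

- The free-frequency peak-gamma reading is upward-biased at realistic trial
  counts (documented above); group contrasts are unaffected because the
  bias is common to both groups, but absolute percent changes read with
  that flag should be interpreted accordingly.
- The exact Mann–Whitney enumeration is limited to combined n ≤ 25 (the
  cohort's 10 + 14 fits; larger samples use the normal approximation).
- The kinetic model is single-compartment; dispersion and exchange effects
  are not modeled.
- The Greenhouse–Geisser correction is triggered by a Mauchly test at 0.05;
  reported ε always accompanies the result so the uncorrected test can be
  reconstructed.
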
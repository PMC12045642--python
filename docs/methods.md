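# Methods

`videba` implements a video-based estimate of dynamic body acceleration
(DBA) as a proxy for aerobic metabolic rate in small fish, together with
the respirometry and statistics needed to calibrate it.  This note
documents the models, the numerical choices, and what the bundled
synthetic studies do and do not demonstrate.

## The measurement chain

**Pose-track QC.**  Marker-less CNN trackers emit per-frame pixel
coordinates with a confidence value and fail in three characteristic ways:
low-confidence detections (occlusion, fish near the frame edge),
high-confidence "jumps" (the tracker locks onto the wrong feature for a
frame), and localization noise.  The cleaning chain is: remove samples
below a per-camera likelihood threshold (defaults 0.6 for the overhead
camera, where occlusion is rare, and 0.9 for the side camera) → refill
interior gaps with a cubic spline → flag temporal outliers with a Hampel
filter (window 29 samples, threshold median ± 1·s.d. of the window) →
refill again → smooth with a 5-sample centered running mean (0.056 s at
90 fps).  Windows are in samples and shrink rather than pad: padding would
fabricate data exactly where double differentiation is most sensitive.
Leading/trailing gaps are never extrapolated; they are dropped.

Two Hampel details are deliberate.  The dispersion is the ordinary
standard deviation of the window (a literal reading of "median ± s.d."),
with the multiplier k exposed because 1·s.d. is aggressive: on
fast-swimming segments the window s.d. is dominated by the beat signal
itself, so the filter also clips beat peaks (an attenuation that is part
of this estimator, not a bug — see "known limitations").  Second, the
first and last half-window of a series are never flagged: there the
window is one-sided, the tested sample sits at the window's extreme, and
any trending signal yields |x − median| ≈ 1.6·s.d., so a clean ramp would
be flagged spuriously.

**3D reconstruction.**  Cameras are the 11-coefficient direct linear
transformation (DLT); coefficients are either read from an easyWand-style
file or estimated from ≥6 non-coplanar 3D↔2D correspondences by linear
least squares.  Triangulation stacks the two rational projection equations
per camera and solves the 3×3 normal equations per frame; the nonlinear
re-minimization exists only as a test oracle, since at flume geometry the
algebraic solution is within a few percent of it.  Lens distortion is
assumed folded into the coefficients.  World frame: x streamwise,
y crosswise, z up, units cm.

**VeDBA.**  Because the camera frame is the Earth frame, raw trajectory
acceleration contains no gravity component, so DBA needs no running-mean
gravity subtraction — the vectorial magnitude √(a_x² + a_y² + a_z²) is
VeDBA directly.  Acceleration is the second-order-accurate *forward*
finite-difference of position, a_i = (2x_i − 5x_{i+1} + 4x_{i+2} −
x_{i+3})/Δt², applied per axis; it is exact on cubics, and on circular
motion at 1 rev/s and 90 fps its truncation error is ≈0.5%.  A central
3-point stencil is available behind a flag for sensitivity checks.  The
stencil never crosses invalid samples.  Window means keep samples with
0.001 g ≤ VeDBA ≤ 1 g (boundary-inclusive): values above 1 g are residual
tracking jumps, values below 0.001 g are stretches where the animal was
effectively untracked (post-interpolation splines are that smooth).
Replicate cycles at the same flow speed are averaged; a lost recording
leaves the surviving replicate as the representative.

**Respirometry.**  Intermittent-flow cycles (5 min flush, 2 min
equilibration, 20 min sealed measurement by default) yield one slope per
cycle: OLS of oxygen (mg l⁻¹) on time (h) over the last 15 min of the
sealed phase.  The mean of fish-free slopes taken before and after the
trial is subtracted, and

    Ṁ_O2 = −S_net · V_resp / M_b   (mg O₂ kg⁻¹ h⁻¹),

positive when oxygen declines.  The respirometer volume is not corrected
for fish body volume by default (≈0.07% for a 6.6 g fish in 10 l); an
optional `fish_volume_l` field exists.

**Calibration statistics.**  Ṁ_O2 against flow speed U is fitted with
Ṁ_O2 = a + b·U^c (nonlinear least squares; deterministic multi-start with
c₀ ∈ {0.5, 1, 1.5, 2, 3}, each start warm-started by the fixed-c OLS
solution, best SSE kept — so the fit can never be worse than the best
fixed-exponent linear fit).  SMR is the extrapolated intercept a; net cost
of swimming is Ṁ_O2 − SMR (negative values retained).  The VeDBA
calibration is the Gaussian random-intercept model

    y_ij = β₀ + β₁·VeDBA_ij + u_i + ε_ij,  u_i ~ N(0, σ²_id),

estimated by REML (statsmodels MixedLM; verified against lme4 to 5+
digits).  The fixed-effect F test uses Satterthwaite denominator degrees
of freedom computed natively: the REML log-likelihood of this model has a
closed form per group (Sherman–Morrison inversion of σ²_ε I + σ²_id J),
and ddf = 2f²/(gᵀAg) with f = Var(β̂₁), g its numeric gradient in
(σ²_id, σ²_ε) and A the inverse observed information.  Finite-difference
steps are 0.5% of the parameter (large enough to survive cancellation —
the log-likelihood is O(10²) while its curvature is O(10⁻⁴)).  The
resulting ddf matches lmerTest to ~0.1%.  Kenward–Roger is not provided;
at these design sizes the two are practically indistinguishable, and
requesting it raises rather than silently substituting.

Marginal and conditional R² follow the Nakagawa–Schielzeth decomposition
with σ²_f = var(β₁·x) (sample variance).  The random intercept is tested
by a likelihood-ratio test of ML refits — the full model's ML likelihood
is maximized over the profiled variance ratio λ = σ²_id/σ²_ε (1-D,
bounded, deterministic), the reduced model is OLS, and λ = 0 reproduces
OLS exactly so χ² ≥ 0 by construction.  The χ²₁ reference is conservative
because σ² = 0 lies on the boundary; p-values are labelled accordingly.

Predictions for new VeDBA values come at two levels (population: β₀;
individual: β₀ + u_i) with two interval kinds: "confidence" for the
conditional mean (fixed-effect covariance, plus σ²_id at population
level) and "prediction" for new observations (additionally σ²_ε).
Intervals use normal quantiles.

## The synthetic flume

The generator provides ground truth for every stage without any recorded
data.  What it emulates, and the defaults:

* **Kinematics.**  The eye of a station-holding fish follows a C² path:
  bounded smooth drift (four random-phase Fourier modes below 0.4 Hz,
  1/f-weighted amplitudes summing to 1.5 cm — an Ornstein–Uhlenbeck-like
  spectrum that remains twice differentiable so the true acceleration is
  analytic) plus swimming beats whose lateral amplitude A(U) rises
  0.2 → 0.8 cm and frequency f(U) 2 → 6 Hz linearly over U = 5 → 30 cm/s,
  with a weaker vertical component (0.2·A at f) and a surge component
  (0.05·A at 2f).  Feeding bouts add Poisson strike transients
  (0.8 s⁻¹, Gaussian displacement envelope, 1.2 cm, τ = 60 ms) —
  the rate matches ~1000 prey items over a 20 min measurement.
* **Cameras.**  Orthogonal top + side views 90 cm from the section
  centre, 25 mm lenses on 1920×1080 sensors (≈0.02 cm/px).  Tracker error
  is modelled as a 0.1 px white jitter plus a slower correlated
  localization wander (AR(1), 0.5 px s.d., 0.5 s correlation time), plus
  confident 40 px spikes (p = 0.01) and low-likelihood dropouts
  (p = 0.02).  The split matters physically: a CNN sees nearly identical
  adjacent frames and errs almost identically on them, so most of its
  error differentiates away; treating the full error budget as white
  noise would, after double differentiation at 90 fps, swamp the signal
  and contradict the demonstrated viability of video-based DBA.
* **Energetics.**  Per-individual SMR ~ N(152.15, 25²) mg O₂ kg⁻¹ h⁻¹ and
  Ṁ_O2 = SMR_i + κ·VeDBA_true with κ = 250, chosen so the study spans a
  published damselfish swimming-cost curve (≈152 at rest to ≈340 at
  30 cm/s); per-cycle metabolic noise σ = 10 (≈5% CV, the repeatability
  of well-mixed intermittent-flow systems); optode noise 0.02 mg l⁻¹ at
  1 Hz; background drift −0.05 mg l⁻¹ h⁻¹.  VeDBA_true is the mean of the
  analytic ‖a‖ *after* the 0.001–1 g exclusion bounds, i.e. the truth is
  defined as the estimand of the averaging rule.
* The default study is 5 individuals (6.59, 6.58, 5.17, 8.87, 9.32 g) ×
  6 speeds × 2 replicates; the feeding variant is 3 individuals ×
  {10, 20, 30} cm/s with and without prey.  Tracked windows are 30 s per
  cycle (a scaled-down recording; the estimator is a per-frame average,
  so window length affects only the sampling error of the mean).  All
  randomness descends from one seed; equal seeds give byte-identical
  bundles.

**What passing tests show — and don't.**  Recovery on this generator
demonstrates internal consistency of the chain (geometry, differencing,
windows, units, estimators) under a *stylized* defect model.  Real
trackers have heavier-tailed, behaviour-dependent errors; real fish do
not beat sinusoidally; real respirometers drift nonlinearly with
bacterial growth.  None of that is represented.

## Known limitations

* **Smoothing attenuation.**  The 5-sample running mean attenuates
  acceleration at the beat frequency (boxcar response ≈0.87 at 5 Hz,
  ≈0.83 at 6 Hz at 90 fps), and the k = 1 Hampel stage clips beat peaks
  on fast segments.  Video VeDBA is therefore an *instrument-defined*
  quantity: calibration and application must use the same processing
  chain — which is how the method is meant to be used.  On the synthetic
  ladder this appears as a few-percent compression of the VeDBA range.
* **Noise floor.**  Residual white jitter creates a VeDBA floor
  (≈0.01–0.03 g at default rig settings) that inflates low-speed means
  slightly; because it shrinks as true VeDBA grows, it compresses the
  low end of the calibration and biases the fitted slope upward by
  ~1–3% under defaults.
* **SMR extrapolation.**  The three-parameter power fit's intercept from
  12 points at 6 speeds carries a standard error of ≈4–5% of SMR at the
  default metabolic noise, and is additionally sensitive to curvature
  mis-specification at the top of the speed ladder (where the 1 g
  exclusion saturates the VeDBA–U map); per-individual SMR estimates
  should be read with ±10–20% uncertainty, consistent with the
  simulation results the acceptance script reports.
* The LRT p-value at the boundary is conservative; the Satterthwaite
  ddf near σ²_id = 0 falls back to the residual df.
* ODBA (sum of absolute axis components) is intentionally absent: its
  axis components are frame-dependent, which is exactly what the
  vectorial magnitude avoids for video data.
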
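# Methods

## Signal model and units

All computation is in milligravity (mg; 1 g = 1000 mg) and double
precision. A recording is a uniformly sampled tri-axial series; files in g
are scaled ×1000 on load, timestamps are seconds since recording start
(uniform-grid tolerance 1e-6 s, absorbing text-format rounding). No
band-pass filtering is applied anywhere: both intensity metrics handle
gravity internally, which is their point.

## Epoching and the two metrics

Epochs are fixed, non-overlapping, 5 s by default (n = fs × 5 samples;
500 at 100 Hz), anchored at the recording start; trailing partial epochs
are dropped, never padded (a short epoch biases MAD downward). Per epoch:

- MAD = (1/n) Σ |r_i − r̄| — invariant to any constant added to all
  magnitudes, hence to static gravity and residual offset miscalibration.
- ENMO = mean of max(r_i − 1000, 0). The clamp is applied **per sample
  before averaging** by default, matching the convention of the standard
  ENMO toolchain; `truncate_per_sample=False` clamps the epoch mean
  instead. The two differ whenever an epoch mixes sub- and super-1 g
  samples (e.g. magnitudes [1100, 1000, 950, 1050] give 37.5 vs 25 mg).

## Auto-calibration

ENMO inherits any offset/gain error directly, so recordings are
auto-calibrated first. Stationary windows (default 10 s, all three
per-axis SDs < 13 mg) supply mean vectors that should lie on the 1000-mg
sphere; per-axis gain and offset are fitted by iterating ordinary least
squares against each point's radial projection onto the sphere (max 100
iterations, parameter tolerance 1e-9). This is a deliberately simplified
gravity-sphere calibration: no temperature covariate, no nonlinear sensor
model. The fit falls back to an identity calibration with a flag when
fewer than 10 stationary windows exist, when all orientations lie within
30° of a single axis (the problem is then ill-posed), when fitted
parameters leave sanity bounds (gain outside (0.5, 2), |offset| ≥ 500 mg),
or when the fit fails to reduce the sphere residual — so applying the
returned calibration never makes the fitting windows worse. Whether MAD
inputs are calibrated as well as ENMO inputs is a study-level choice the
literature leaves open; the pipeline calibrates both by default with
`calibrate_mad=False` to restrict calibration to ENMO.

## Labelling and observation granularity

Activity windows come from a log (ids 1–11 lying/sitting = sedentary pool,
12–16 upright). The first and last 30 s of each window are discarded as
likely transitional movement; an epoch is labelled only if wholly inside
the trimmed window, so a 5-minute activity yields 48 labelled epochs.

Each discrimination is pooled-sedentary vs one upright activity.
Observations default to **participant–activity means** (each participant
contributes 11 sedentary values and 1 positive value per discrimination;
33 participants give 363 vs 33), with epoch granularity available. This is
the single most consequential open choice in this kind of analysis:
epoch-level observations inflate n by ~50× and shrink every confidence
interval accordingly. Participant-level aggregation is the default here
because group summary tables in this literature report between-participant
standard errors, and because epochs within a participant are strongly
dependent. Summary tables likewise pool the sedentary class within
participant first, then across participants.

## Threshold derivation and validation

- Logistic fits: univariate IRLS (Newton), convergence at gradient norm
  < 1e-8, max 100 iterations. Perfect separation — detected by
  non-convergence, |slope| > 1e4 per mg, or a saturated likelihood
  (log-likelihood > −1e-6, meaning the MLE lies at infinity even when the
  gradient has numerically vanished) — triggers a ridge-stabilised refit
  (penalty 1e-6 on the slope) reported with `converged=False`.
- ROC: rule `value ≥ threshold → activity`, one point per distinct score
  plus the degenerate endpoints. The optimal threshold maximises Youden's
  J; ties break toward higher sensitivity, then lower threshold. The
  reported sensitivity/specificity are exactly recomputable by applying
  the returned threshold to the data.
- AUROC: Mann–Whitney pair counting with ties half-credited; 95% CI from
  the DeLong placement-component variance with a normal approximation,
  clamped to [0, 1]. The CI method is a package choice — bootstrap or
  binormal intervals would be equally defensible.
- LOOCV: one observation (or one participant, for the subject-independent
  variant) held out per fold; the held-out predicted probabilities are
  pooled across folds and scored once. Pooling is the only way
  single-observation test folds can yield an AUROC. It has a known
  pessimistic artifact under weak signal: with an uninformative predictor
  the fold intercept tracks the training prevalence, which is slightly
  lower whenever a positive is held out, pushing every held-out positive
  below every held-out negative. Null LOOCV AUROCs therefore sit below
  0.5 — visible in this package's standing-still results and consistent
  with published standing LOOCV values well below their apparent AUROCs.
- Brand comparisons: two-sample unpaired t-tests on per-participant means
  (pooled-variance Student by default, Welch available), two-sided,
  α = 0.05, no multiple-testing correction.
- Every battery run asserts rank invariance: when the fitted slope is
  positive, the AUROC of predicted probabilities equals the AUROC of raw
  values to 1e-12.

## Synthetic cohort generator

The generator emulates the laboratory protocol: 33 participants, four
devices each (AG ≈ ActiGraph-like, GA ≈ GENEActiv-like; hip and wrist),
16 activities of 5 minutes at 100 Hz with 30-second breaks. Per activity
the signal is static gravity along a device-frame orientation (16 fixed
orientations spread over ± axes, plus per-participant jitter) plus a sum
of three sinusoids (0.9/1.7/2.8 Hz, amplitude weights 0.5/0.3/0.2) and
white noise, then distorted by the device's per-axis gain/offset.

Movement directions are drawn on a 60° cone around gravity (|d·o| = 0.5,
random azimuth and side). Fixing the radial coupling at the mean of an
isotropic draw keeps the expected metric response to a given amplitude
unchanged while removing direction luck as a spurious between-subject
variance source; between-subject spread is instead controlled explicitly
by log-normal per-activity amplitude multipliers (σ = 0.3, giving ~30%
between-participant CV, the order seen in published group tables).
Devices at the same wear site share the latent movement process and
multipliers; they differ by brand distortion and independent sensor noise.

Per-activity movement amplitudes are the generator's key constants. They
were calibrated once with `fit_generator_to_targets` — a one-dimensional
multiplicative search driving the simulated mean epoch metric to a target,
averaging several direction draws per evaluation — against published mean
MAD values per activity group for an ActiGraph-like noise level, then
frozen as defaults (hip: washing 37, dusting 161, sweeping 206, walk
668 mg; wrist severalfold larger, reflecting arm movement). Sedentary
postures keep a small fixed relative profile (typing and phone use busier
than still lying/sitting). Brand defaults: AG noise ≈ 1.6 mg total with
mg-scale offsets; GA noise ≈ 11.5 mg with larger offsets — reproducing
the observed pattern that GA metric levels run higher at low intensities
and converge at high intensity. Brand differences are additive
noise/affine only; no frequency-response modelling.

**Standing still is an exact null by construction:** its amplitude is
drawn per participant from that participant's 11 sedentary amplitudes, so
standing observations are exchangeable with the sedentary pool and the
standing-vs-sedentary AUROC is 0.5 in expectation. This encodes the
physical fact the analysis is meant to expose — magnitude metrics carry
no posture information — rather than assuming any particular standing
"signal".

What the generator does **not** emulate: realistic gait or posture
transitions, autocorrelated or non-Gaussian sensor noise, device clock
drift, non-wear, or free-living behaviour. Passing tests therefore show
the pipeline's statistical machinery is correct and that the qualitative
laboratory contrast (motion activities separable, standing not) is
reproduced; they do not certify threshold values for field data.

## Simulation sizes

Single-cohort runs in the acceptance script use the full protocol scale
(33 participants, 100 Hz, 5-minute activities, 4 devices). Repeated-seed
sweeps (the 50-seed standing null; recovery simulations) use reduced
scale — 20 Hz, 2-minute activities, one device, activities 1–12 — chosen
as the smallest sizes at which the per-seed Monte-Carlo error is well
below the tolerance being checked. The test suite's shared cohort uses
5 participants at 40 Hz with 2-minute activities.

## Known limitations

- The calibration is a functional stand-in for the reference
  auto-calibration procedure, not a re-implementation; it omits
  temperature and uses a simpler sphere fit.
- The participant-mean observation granularity, the Youden criterion, and
  the DeLong CI are explicit choices where the underlying analysis
  conventions are ambiguous; all are configurable and documented rather
  than asserted as the only defensible versions.
- Proprietary binary device formats (.gt3x, .bin) are out of scope; the
  pipeline ingests CSV exports.
- Pooled LOOCV AUROC is biased low under the null (see above); treat
  near-null LOOCV values as qualitative.
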
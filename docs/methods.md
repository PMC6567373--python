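# Methods

This note documents the models, estimators and design choices behind
`physcap`, what the synthetic data does and does not emulate, and the
numerical conventions a user relying on exact values should know.

## Signal model and conditioning

A recording is a tri-axial acceleration stream (AP, ML, V body axes;
m/s²) — plus tri-axial angular velocity (°/s) for the chair stand — with
per-sample nanosecond timestamps.  Consumer phones do not sample
uniformly, so every analysis begins with piecewise-linear interpolation
onto an exactly uniform grid `t0 + k/rate` (default 100 Hz).  Linear
interpolation is used because the timestamp jitter is small (~1 ms)
relative to the signal bandwidth of interest (< 10 Hz); the operation is
idempotent on already-uniform input.  Acceleration may arrive in g or
m/s² (`acc_unit`); internally everything is m/s² (1 g = 9.80665 m/s²).
Samples at or beyond the ±2 g sensor range are *flagged*, not rejected:
at the lower back only the sitting impact of the chair stand can
saturate, for a few samples, and those are winsorized at the range limit
before chair-stand features are computed.

**PSD estimation.** Welch's method, Hann window, 50 % overlap, mean
removal per segment.  The segment length defaults to 20 s (capped at the
record length), giving 0.05 Hz resolution on a 30 s quiet stand; that
resolution is needed because frequencies below 0.15 Hz are excluded from
all sway spectral measures, and the exclusion must fall on a bin
boundary that is actually resolvable.  The stored PSD is a density;
moments μ₀ (= total power), μ₁, μ₂ are df-weighted sums over the retained
band, so μ₀ approximates the band-limited time-domain variance
(Parseval; verified to 5 % in tests).

**Displacement estimation.** Center-of-mass displacement is estimated
from horizontal acceleration by drift-suppressed double integration:
zero-phase 4th-order Butterworth high-pass at 0.15 Hz, trapezoidal
integration to velocity, re-high-pass, integration to displacement,
re-high-pass, with the integration constant/trend removed before each
filter pass and a 1 s half-cosine fade at the record edges.  The 0.15 Hz
corner matches the spectral floor of the sway analysis: postural content
below it cannot be separated from integration drift.  Zero-phase
filtering at such a low corner normally rings for several seconds at the
record edges; the implementation uses Gustafsson initial conditions
(`scipy.signal.filtfilt(..., method="gust")`), which keeps the
mid-record amplitude error of a 0.5 Hz test oscillation under ~4 % and
suppresses a constant 0.1 m/s² bias to numerically zero displacement
(naive double integration would accumulate 45 m over 30 s).  A
frequency-domain integrator would be an equally admissible design; the
filter chain was chosen because it degrades gracefully on non-stationary
records.

## Feature conventions

All formula-level conventions that the printed definitions leave open:

* **Sway path (1-D)** uses absolute increments Σ|Δs| — a literal reading
  without the absolute value would telescope to `s_N − s_1`, which is not
  a trajectory length.  The planar sway path is the sum of Euclidean step
  lengths (no leading ½); the sway area keeps its ½ (it is a triangle
  area).
* **Mean velocity** is SP/T per axis (the path-length definition), not
  the median-of-integrated-acceleration variant; this keeps MV consistent
  with the SP measure it accompanies.
* **Spectral entropy** is normalized by log N (N = retained bins) so it
  is unitless in [0, 1].
* **Ellipse area** uses χ²(0.95, 2) = 5.991.
* **Quiet-stand NJS** normalizes by the 1-D path length of the same
  acceleration axis; gait and chair-stand NJS follow their printed
  formula without path normalization, per step (T = step duration) and
  per transition (T = phase duration) respectively, averaged across
  steps/repetitions.  Note the unnormalized score scales as T² at fixed
  acceleration amplitude — longer transitions yield *larger* jerk scores,
  which is why transition duration and jerk scores co-load on the same
  factors.  Smoothness comparisons are meaningful at fixed duration
  (tests use a tremor-ripple manipulation).
* **Derivatives** are central finite differences; integrals are
  trapezoidal.
* **Step/stride regularity** normalizes the unbiased autocorrelation
  A(n) = Σsᵢsᵢ₊ₙ/(N−n) by A(0) and takes the maximum within 0.5–1.5× the
  cadence-implied step (stride) lag; the unbiased estimator can exceed 1
  marginally on near-periodic signals and is clipped to [−1, 1].
* **PCI** uses the population SD (ddof = 0) in the phase
  coefficient-of-variation term, which reproduces hand-computed reference
  values exactly; per-step cadence SD uses the sample SD (ddof = 1).
* **Heel strikes** are peaks of the 10 Hz-low-passed vertical
  acceleration, minimum separation 0.3 s, kept above half the median
  candidate peak height.  The gait phase is the window from first to last
  detected strike; no steady-state trimming is applied.
* **Chair-stand segmentation** low-passes the ML angular velocity at
  1.5 Hz; a transition is a contiguous region where |ω_ML| exceeds 10 %
  of its maximum (and the global peak must exceed 10 °/s — below that no
  postural transition is present).  The first burst must look like a
  sit-to-stand (positive AP lean at onset: the test starts seated), and
  kinds alternate.  Per-repetition statistics are computed within each
  repetition and averaged (rather than pooling samples across
  repetitions) so that each of the five repetitions contributes equally.

## The conceptual model

One EFA per test, never pooled.  Preprocessing: natural log of the
(strictly positive, right-skewed) jerk measures, then z-scoring of every
measure (sample SD); subjects with any missing measure are dropped
listwise within a test.

* **Retention — parallel analysis, common-factor variant.**  The
  observed eigenvalues of the *reduced* correlation matrix (squared
  multiple correlations on the diagonal) are compared position by
  position with the 95th percentile of the same eigenvalues computed on
  100 standard-normal matrices of identical shape; retention stops at the
  first shortfall.  The reduced-matrix (common-factor) variant is used
  because retention is feeding a common-factor model, and because on
  strongly cross-correlated structures Horn's original full-correlation
  variant systematically under-retains the weaker factors (on the
  packaged loading structures it drops the 4th/5th/6th factor that the
  reduced variant retains stably).  The full-correlation variant remains
  available (`method="pc"`).
* **Extraction — iterated principal-axis factoring.**  Communalities are
  initialized at squared multiple correlations and iterated on the
  reduced correlation matrix to a 1e-8 fixed-point tolerance (up to 2000
  iterations; near-Heywood cases converge slowly and communalities are
  capped at 1).  A principal-*component* decomposition is deliberately
  not used: it would mix unique variance into the retained dimensions,
  and the cumulative-variance accounting (Σ communalities / p) would no
  longer measure common variance.
* **Rotation — varimax** via Kaiser's pairwise planar-rotation sweeps
  with Kaiser row normalization.  The closed-form per-plane angle cannot
  stall at the symmetric saddle points that stop SVD/gradient varimax
  iterations (a failure mode observed on perfectly balanced two-block
  structures).  Factors are then ordered by explained variance and
  sign-flipped so each factor's dominant loading is positive.
* **Assignment.**  A measure joins the factor with its largest absolute
  loading when that maximum exceeds 0.5, and only that factor — a measure
  loading above 0.5 on two factors is assigned to the larger one.
* **Scores.**  Thurstone regression scores S = Z·R⁻¹·Λ (least-squares
  prediction of factor positions); columns are zero-mean and, for
  orthogonal structures, near-uncorrelated.
* **Variance check.**  The fitted structure is expected to explain at
  least 70 % of total variance; `FactorResults.meets_variance` reports
  the check without gating the fit.

Degenerate inputs: fewer measures than factors + 1 is an error; fewer
subjects than measures warns.

## Synthetic data: what it emulates, what it does not

The generators define the study conditions for every test in this
repository.

* **Feature matrices** follow the common factor model
  X = FΛᵀ + E·diag(√Ψ) with Λ the published per-test varimax loading
  matrices (shipped as CSV fixtures keyed by measure name) and
  Ψ = max(1 − communality, 0.05).  The 0.05 uniqueness floor keeps the
  implied covariance positive definite even for measures whose published
  communality approaches 1.  Default n are the study subgroup sizes
  (QS 204, 7MW 201, CST 173).
* **Quiet stand**: band-limited (0.2–2 Hz) Gaussian sway acceleration at
  exact per-axis RMS (defaults 0.08/0.06 m/s² AP/ML, typical of older
  adults); vertical channel at gravity.
* **Walk**: planted heel-strike times from a cadence (default
  110 steps/min), a long/short step-time asymmetry ratio and a step-time
  CV; each strike is a half-sine impulse on V and AP over a
  cadence-locked background oscillation, with stride-periodic amplitude
  and ML alternation so step and stride regularity separate.  Planted
  strike times are exact in recording time (waveforms are evaluated at
  the jittered timestamps).
* **Chair stand**: five cycles of signed half-sine ML angular-velocity
  bursts (sit-to-stand positive), biphasic AP lobes whose onset polarity
  encodes the transition kind, optional duration variability and tremor
  ripple; planted phase boundaries in metadata.
* **Timestamps** carry ~1 ms Gaussian jitter emulating a non-real-time
  phone OS.
* **Stopwatch durations** are emulated as the device duration minus a
  Gaussian offset whose mean/SD match the published device-stopwatch
  limits of agreement (7MW: 1.37 ± 0.995 s; CST: 2.925 ± 1.558 s).
* **Cohort table**: continuous health measures are Gaussian at the
  published total-population means/SDs; medication/IADL/fall counts are
  Poisson with rates matching the published exceedance fractions
  (P(NM ≥ 4) ≈ 0.56, P(IADL ≥ 1) ≈ 0.38, P(falls ≥ 2) ≈ 0.05–0.06);
  Gender is Bernoulli(0.54).  Values are *not* truncated to the nominal
  scale ranges — means/SDs stay exact and out-of-range values only
  trigger plausibility warnings.  Columns are independent unless a
  dependence is explicitly planted, so cross-measure associations in the
  synthetic cohort are null by construction.

What passing tests therefore show: the formulas, detectors and the
EFA/validity machinery are correct against planted ground truth and
closed forms, and the published *factor structure* is recoverable from
its own loading matrices at the study's sample sizes.  What they cannot
show: that real lumbar-IMU physiology produces those loadings, real
heel-strike morphology is detected as reliably as the synthetic impulses,
or that the real cohort's regression coefficients are reproduced — the
original recordings are not public, and the synthetic cohort is
association-free by design.

## Validity statistics

Every association is a single-predictor OLS fit (statsmodels), run
unadjusted and adjusted for Age, Gender (0/1), Height, Weight, MMSE and
number of medications, with listwise deletion per fit and at least 10
complete cases; collinear designs raise rather than silently dropping
terms.  Significance is flagged at p ≤ 0.05 with **no multiplicity
correction**, replicating the original reporting convention — a known
limitation, since the three association families involve hundreds of
fits and ~5 % of null pairs will flag.  Falls variables are generated and
modelled as counts (the regression coding of the original study is not
stated).  Bland-Altman limits are bias ± 1.96·SD of paired differences
(device − reference).

Radar profiles use the empirical percentile of the subject within the
reference score distribution (linear interpolation between order
statistics at positions (i−½)/n, clamped to [0, 100]); a domain is
flagged extreme outside the 25th–75th band.  Whether high scores are
favorable is domain-specific and treated as configuration, never
inferred.

## Problem sizes and determinism

The test suite and the acceptance script run at the study's subgroup
sizes for the factor-recovery experiments (204/201/173 subjects; 20 seed
replicates for ensemble means) and at reduced sizes elsewhere (e.g.
pipeline determinism checks at 40–80 subjects), which keeps a full run in
the tens of seconds while leaving all statistical conclusions
comfortably inside their tolerances.  All randomness flows from
`numpy.random.Generator` seeded per stage via `SeedSequence` spawning;
identical config + seed reproduce byte-identical artifacts (CSV floats
are written at fixed precision to guarantee this).

## Known limitations

* The exact extraction algorithm and parallel-analysis settings of the
  original R analysis are unreported; printed loadings are matched via
  simulation-based recovery, not coefficient-by-coefficient.
* Subjects completing fewer than the full five chair-stand repetitions
  are rejected, not partially scored.
* No sensor-fusion orientation estimation: the device-to-body axis
  mapping is input metadata.
* The accelerometer-analog sway area / ellipse area mentioned as an
  analogy in the source feature definitions are not part of the
  23-measure quiet-stand set and are not computed.
* Turning detection and spatial step-length estimation are out of scope
  (the walk is straight-line).
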
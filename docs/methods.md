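# Methods

`mibci` reimplements, as a tested pipeline on synthetic data, the analysis
chain used to ask whether a motor-imagery questionnaire predicts
imagery-vs-rest BCI decoding performance. This note documents the models,
the parameter choices, and the design decisions taken where the procedure
was genuinely open.

## Simulated experiment

Each simulated subject performs one session of right-hand kinesthetic
motor imagery (KMI). A trial is 6 s rest (RED cue), 2 s warning (ORANGE),
4 s imagery (GREEN), then an inter-trial interval drawn uniformly from
[1.5, 2.5] s; the default session has 40 trials at 256 Hz over the
32-channel fronto-central/central/parietal/occipital 10-20 montage plus a
near-silent EMG monitor channel.

Signals are a sum of three components:

1. **Background**: per-channel 1/f-spectrum noise (flat below 1 Hz),
   RMS `noise_scale` = 10 µV, plus a shared common-mode track at 20 % of
   that amplitude. The common mode gives the spatial covariances a
   realistic correlated structure (full-rank, far from diagonal).
2. **Rhythms**: coherent narrow-band (±1.5 Hz) mu (10 Hz) and beta
   (20 Hz) sources. Channel `ch` receives the source with amplitude
   `amp · (0.3 + 0.7·w_ch)` where `w_ch` is a Gaussian spatial gain
   centred on C3 (shipped as `data/spatial_gains.json`; C3 = 1, CP3/FC3
   ≈ 0.7, ipsilateral C4 ≈ 0.03). During each GREEN interval the source
   envelope at channel `ch` is multiplied by `(1 − w_ch·d)` where `d` is
   the subject's event-related desynchronization (ERD) depth for that
   band; for 1 s after imagery offset the beta envelope is multiplied by
   `(1 + w_ch·g)` (post-imagery rebound, gain `g`). Envelope steps are
   smoothed with a 0.1 s Hann ramp; per-trial depths are jittered
   multiplicatively (SD 10 %, a free parameter — trial-to-trial ERD
   variability is not constrained by the literature values we target).
3. **EMG**: white noise at 5 % of `noise_scale` (movement-free session).

Default oscillator amplitudes (`mu_amp` = 3 µV, `beta_amp` = 2 µV RMS at
full gain) were calibrated once so that the depth→accuracy curve of the
tangent-space classifier spans the range reported for this kind of
montage and task (chance at depth 0, ≈ 0.66/0.88/0.98 at depths
0.25/0.5/0.75), i.e. a cohort drawn from the default symmetric Beta(2, 2)
depth distribution has a mean accuracy in the low 80s with a realistic
spread and a small "illiterate" tail below 70 %.

**Covariates.** A single standard-normal "imagery ability" latent `z`
drives both band depths (beta shares the latent with correlation 0.8)
through the inverse CDF of the depth distribution. Questionnaire items
(14 items, 7 kinesthetic + 7 visual, 1..7 Likert) and personal factors
(age, gender, education, five 6-point frequency-of-practice ratings) are
drawn through a Gaussian copula: a factor with declared correlation `c`
uses the latent `c·z + √(1−c²)·ε` before discretization, so factors with
no declared correlation are exactly independent of ERD depth. Kinesthetic
items round `5.05 + 1.3·latent` and visual items `5.9 + 1.1·latent` into
1..7 (kinesthetic self-ratings run lower than visual ones, matching
cohort means near 68 and 81 on the 0–100 scale); frequency ratings use
equal-probability bins of the standard normal into levels 0..5. The
default scenario declares **no** coupling between questionnaire answers
and ERD depth (the null finding) — a positive scenario, e.g.
`covariate_corr: {freq_manual: 0.6}`, makes manual-activity frequency
predictive of decodability.

The frequency scale is six levels 0..5 read as
never/rarely/annually/monthly/weekly/daily; "Manual+" means weekly or
daily practice. (Published descriptions of this scale name five anchors
on a six-point scale; we fix the six-level reading above.)

## Preprocessing

5th-order Butterworth band-pass 8–30 Hz applied to the continuous
recording, forward–backward (zero phase; the analysis is offline and the
filter's phase handling is otherwise unconstrained). Filtering precedes
epoching so that transients never fall inside a window. Epochs of
T = round(3.5·fs) samples (896 at 256 Hz): imagery windows start 0.5 s
after GREEN, rest windows 2.5 s after RED, start indices floored so T is
exact for every trial; windows that run past the recording end are
dropped with a warning. EMG is excluded from epochs.

## Classifiers

Features are per-trial spatial covariances Σᵢ = XᵢXᵢᵀ/(T−1) of
channel-mean-centred epochs, regularized by Σ + εI (ε = 1e−10·tr(Σ)/C,
escalated tenfold until positive definite) only when an eigenvalue is
non-positive.

* **CSP+LDA** — generalized eigenproblem Σ̄₁w = λ(Σ̄₁+Σ̄₂)w on class-mean
  covariances; eigenvalues sorted descending; first + last 4 filters
  (F = 8); features are log-variances of the filtered epoch; Fisher LDA
  with equal priors. Filter signs are fixed (largest coefficient
  positive) for determinism.
* **MDRM** — minimum affine-invariant Riemannian (AIRM) distance
  δ(A,B) = ‖log(A^{−1/2}BA^{−1/2})‖_F to the per-class Fréchet mean.
  The metric is the one used by the minimum-distance-to-mean literature
  this family of classifiers comes from. Karcher iteration: initialized
  at the arithmetic mean, unit step, tol 1e−8 on the gradient norm,
  max 50 iterations, error on non-convergence.
* **gfMDRM** — "geodesic filtering" before MDRM. The published recipe is
  only sketched ("a generalization of LDA to the manifold"), so it is
  concretized here as tangent-space Fisher filtering: map training
  matrices to the tangent space at their global Fréchet mean, fit a
  Fisher discriminant subspace (dimension d, default 1; within-class
  scatter ridge-regularized when singular, which is the norm when the
  tangent dimension C(C+1)/2 exceeds the trial count), project, retract.
  This is one faithful reading, not a reconstruction of the original
  code. Note that filtering can only help when the nuisance variability
  is anisotropic: under isotropic tangent noise the distance-to-mean
  rule already projects onto the mean-difference axis, and the test
  construction for the filter reflects that.
* **TS+LR** — tangent-space projection at the training-set Fréchet mean,
  half-vectorized with √2 off-diagonal weighting (so vector norms equal
  Frobenius norms), then an L2-regularized logistic regression. The
  original description says "Linear Regression classifier"; regularized
  logistic regression is the standard linear model on tangent features,
  and a plain least-squares variant (±1 targets, zero threshold) is
  available via `least_squares=True` for fidelity comparisons.

Evaluation: stratified 4-fold cross-validation (default seed 42 —
stratification and seeding are not constrained by the protocol;
chronological unshuffled folds available via `stratified=False`), all
fitting strictly inside training folds, trial-weighted mean accuracy plus
per-fold min/max.

## Statistics

Questionnaire scores rescale item means from 1..7 to 0..100:
score = (mean − 1)/6 × 100. Hand-related (3) and arm-related (5)
kinesthetic item subsets are configuration entries (defaults {2,4,6} and
{1,2,4,6,7}) because the public form does not identify them; they are
explicitly non-authoritative. Groupings: K±/V± at score ≥ 70; Perf+
strictly above the cohort mean accuracy (with a 1e−12 relative tolerance
so exact ties stay Perf−); Manual+ at weekly-or-daily practice.

Tests: Pearson and Spearman correlations (two-sided), Welch's t
(Satterthwaite df), Mann-Whitney U (exact for untied samples with both
n ≤ 8, asymptotic with tie correction otherwise), Shapiro-Wilk, Glass's
Δ = |mean difference| / SD(control) with the larger group as control
(ties toward the first argument, n−1 denominator). Benjamini-Hochberg
step-up at q = 0.20 within declared test families (default families: all
methods × {KMI, VMI} scores, and best-method × personal factors); the
realized threshold k·q/m is reported rather than a hard-coded adjusted α.

## ERSP

Time-frequency maps use a sliding 256-point Hanning-windowed FFT with a
32-sample hop (taper and hop are fixed here for determinism; they are
not constrained by the source description), averaged over trials, in dB:
10·log₁₀(P(f,t)/P̄_baseline(f)), restricted to 8–30 Hz over −1000 to
+4000 ms around imagery onset. The baseline is the 2-s window **ending
2 s before** the GREEN cue, which lies inside the preceding rest period —
the wording "baseline taken 2 s before each trial" is ambiguous and this
is the documented resolution; the dB convention is the divisive
(EEGLAB-additive) mode. Group comparison: cell-wise subject-label
permutation (default 1000 draws, add-one p-values, two-sided) with BH-FDR
at α = 0.05 over the full grid in one family. The pooled subject order is
canonicalized before permuting so the null — and hence the mask — is
exactly invariant to swapping the two groups when sizes match.

## Problem sizes used in the test suite

Protocol-count checks run at full scale (32 channels, 40 trials, 256 Hz).
Statistical calibration checks use a reduced setup chosen to keep the
suite fast on one CPU while leaving the tested property unchanged: an
8-channel motor-strip montage + EMG, 16 trials, 128 Hz. Cohort-level
calibration studies (type-I rate over 200 cohorts of n = 35; correlation
recovery over 100 cohorts; monotonicity of recovered r in the configured
copula correlation) use questionnaire profiles plus
`surrogate_accuracies`, a documented monotone map of ground-truth ERD
depth to accuracy with measurement noise; the ERD-depth → classifier
accuracy link that the surrogate stands in for is itself verified by the
null-soundness (depth 0 → 50 % ± 7 % over 20 seeds) and
effect-monotonicity (non-decreasing accuracy over depths
{0, 0.25, 0.5, 0.75}, 20 seeds per point) tests that run the real
classification chain.

## What the simulator does and does not emulate

It emulates: the trial protocol and event structure; subject-specific mu
and beta ERD with contralateral topography; post-imagery beta rebound;
1/f background with inter-channel correlation; questionnaire and factor
covariates with controllable coupling to decodability; a silent EMG
channel. It does **not** emulate: volume conduction from dipolar sources
(the gain map is a fixed amplitude topography, not a head model), ocular
or movement artifacts, electrode drift or line noise, visual-imagery
specific activity, non-stationarity across the session, or realistic
questionnaire answering behaviour beyond the copula. Passing tests
therefore demonstrate correctness and calibration of the *analysis
chain* under a controlled generative model — not that the chain would
reach the same numbers on human EEG, whose headline accuracies and
correlations are not reproducible from synthetic data.

## Known limitations

* The Karcher mean uses a fixed unit step; for extremely dispersed
  matrix sets it may need more than 50 iterations (it raises rather than
  silently returning a bad mean).
* The EDF writer is minimal (no EDF+ annotations; events live in the
  TSV sidecar) and clips at ±500 µV physical range.
* gfMDRM's subspace dimension d is a free parameter; d = 1 is optimal
  for the two-class constructions tested here but not universally.
* Exact Mann-Whitney p-values are only used for small untied samples;
  tied small samples fall back to the asymptotic approximation.
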
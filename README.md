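# mibci

Simulation and analysis of motor-imagery brain–computer interface (BCI)
experiments: does a motor-imagery questionnaire — or anything else a
subject can tell you before the session — predict how well their imagery
can be decoded from EEG?

The package is aimed at BCI and EEG methods researchers who want a fully
controlled, reproducible test bed for that question: a synthetic-cohort
generator with known ground truth, the standard imagery-vs-rest decoding
chain, and the questionnaire/statistics battery used to relate decoding
accuracy to self-reported measures.

## What it implements

**Synthetic cohorts** (`mibci.synthgen`). Each subject performs a
cued right-hand kinesthetic imagery session (6 s rest / 2 s warning /
4 s imagery per trial, 40 trials, 32-channel 10–20 montage + EMG at
256 Hz). Mu (10 Hz) and beta (20 Hz) rhythms over contralateral motor
cortex are attenuated during imagery by a subject-specific
event-related desynchronization (ERD) depth d ∈ [0, 1], with a beta
rebound after imagery offset, on top of 1/f background noise.
Questionnaire answers and personal factors are drawn through a Gaussian
copula whose latent correlation with ERD depth is configurable — so both
a null scenario (questionnaire unrelated to decodability) and a positive
one (e.g. manual-activity frequency predicts accuracy) can be generated
with known ground truth.

**Decoding** (`mibci.preprocess`, `mibci.riemann`, `mibci.classify`).
Band-pass 8–30 Hz (5th-order Butterworth, zero-phase), 3.5-s epochs
(T = 896 samples at 256 Hz), per-trial spatial covariances
Σᵢ = XᵢXᵢᵀ/(T−1), and four classifiers under stratified 4-fold
cross-validation:

* `csp_lda` — Common Spatial Patterns (F = 8 filters, log-variance
  features) + linear discriminant analysis;
* `mdrm` — minimum distance to the Riemannian (Fréchet) mean under the
  affine-invariant metric δ(A,B) = ‖log(A^{−1/2}BA^{−1/2})‖_F;
* `gfmdrm` — MDRM after tangent-space Fisher ("geodesic") filtering;
* `tslr` — tangent-space projection at the training Fréchet mean +
  regularized linear classification.

**Statistics** (`mibci.stats`). Questionnaire scoring
(score = (mean(items) − 1)/6 × 100), K±/V± (score ≥ 70), Perf± (above
cohort mean) and Manual± (weekly/daily practice) groupings, Pearson and
Spearman correlations, Welch's t, Mann-Whitney U, Shapiro–Wilk, Glass's
Δ, and Benjamini–Hochberg FDR control (q = 0.20) over declared test
families.

**Time–frequency** (`mibci.ersp`). Event-related spectral perturbation
maps (sliding 256-point Hanning FFT, dB vs a pre-trial rest baseline,
8–30 Hz, −1 to +4 s around imagery onset) and a cell-wise permutation
test with FDR correction for group comparisons.

**I/O and CLI** (`mibci.io_formats`, `mibci.cli`). Sessions are stored
as EDF + events TSV, subjects as CSV; the `mibci` command runs each
stage standalone or end to end with a manifest (config snapshot, seed,
timings, checksums).

## Worked example

Simulate a 10-subject cohort in which manual-activity frequency has a
latent correlation of 0.6 with ERD depth, then run the whole chain:

```yaml
# config.yaml
n_subjects: 10
n_trials: 20
fs: 256
seed: 3
covariate_corr:
  freq_manual: 0.6
```

```bash
mibci full --config config.yaml --out run/ --n-perm 200
```

prints (abridged):

```json
{
 "n_subjects": 10,
 "mean_accuracy": {
  "csp_lda": 0.645,
  "mdrm": 0.7425,
  "gfmdrm": 0.7475,
  "tslr": 0.7475
 },
 "significant_correlations": [
  {
   "method": "tslr",
   "variable": "freq_manual",
   "pearson_r": 0.745,
   "pearson_p": 0.0133
  }
 ],
 "ersp_significant_cells": 0
}
```

Reading: cohort-mean cross-validated accuracies per classifier sit in
the 0.65–0.75 range for this small 20-trial cohort; the planted
manual-activity effect is recovered as the only correlation surviving
Benjamini–Hochberg adjustment (r = 0.745 between manual-activity rating
and tangent-space classifier accuracy); with only 5 subjects per
Manual± group the ERSP permutation test keeps no time–frequency cell
after FDR. Full tables land in `run/correlations.csv`, `run/groups.csv`,
`run/results.csv` and `run/ersp_*.csv`; `run/manifest.json` records the
config, seeds and output checksums.

The same scenario with `covariate_corr: {}` is the null experiment: no
correlation should (and does not) survive adjustment, and classifier
accuracies at `erd_depth_dist: {kind: fixed, value: 0}` average 50 %.

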
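# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
cohort does and does not emulate.

## Representational dissimilarity matrices

Every analysis reduces to labelled, symmetric, zero-diagonal item × item
RDMs over the 20 talker-collapsed (tone, syllable) items, vectorized as the
row-major upper triangle (190 values); the same fixed item order
(tone-major, syllable-minor) is asserted across all RDMs entering one
comparison. Missing entries (confusion cells touching a no-response trial)
are NaN and dropped pairwise in correlations.

Construction conventions:

- **Categorical models** (CAT, Syllable, hand): 0 for same category, 1 for
  different.
- **Acoustic models**: F0 height and slope use absolute differences of the
  talker-averaged per-item features; the multidimensional pitch model (MD)
  min-max normalizes each dimension before taking Euclidean distances.
  Feature RDMs are scaled to [0, 1] by dividing by the maximum
  (`normalize_rdm(..., anchor_zero=True)`), so zero dissimilarity stays
  zero; plain `normalize_rdm` is min-max with min subtraction, which is the
  right tool when only the ordering matters. Both are provided because the
  two conventions disagree exactly when the smallest off-diagonal
  dissimilarity is nonzero.
- **Neural RDMs** default to correlation distance (1 − Pearson across
  voxels), the field standard for activation-pattern RSA; Euclidean is
  selectable and is forced in the PC-constrained path. Which metric the
  unconstrained analyses in the literature used is typically not stated;
  the default is documented here and switchable per call.

**Partial Spearman** is defined as partial Pearson on average-fractional
ranks: all vectors are rank-transformed, the first two residualized on the
confound ranks (with intercept, least squares), and the residuals
correlated. With no confounds this is exactly Spearman's ρ. Rank-based
partial correlation has variants; this one reduces to the textbook
single-confound closed form, which the tests verify.

## Learning curves

Block-wise proportion correct counts missing-response trials as incorrect
(no correct response occurred); they are, however, excluded pairwise from
confusion matrices and removed entirely before feedback decoding. This
dual rule is deliberate: accuracy is a behavioral outcome, whereas
confusion/decoding analyses need actual responses.

The power family `Y = aX^b` is fitted by nonlinear least squares
initialized from the log-log linearization (1e-6 guard on zero
accuracies), with `b` bounded to [−5, 5] to prevent runaway exponents on
degenerate curves and a coarse grid fallback on non-convergence. The
hyperbolic and logarithmic families use the standard forms
`Y = aX/(b+X)` and `Y = a + b·ln X`. Learning speed is `a·b`; learning
outcome is the mean accuracy of the final three blocks.

## IS-NRS

Per learner, native, and region: partial Spearman between the two
vectorized neural RDMs, always controlling the response-hand RDM (binary
same-hand/different-hand over items via the learner's counterbalanced
category→button→hand map — the confound is named in the literature but its
encoding is not; binary same/different is the natural choice), optionally
also the syllable model. Per (learner, region) the pairwise ρ values are
averaged arithmetically over natives — mean of ρ, not ρ against a mean RDM
(a test asserts these differ) — with Fisher-z averaging available but off
by default. Early/late phases pool all trials of blocks 1–3 / 4–6 before
item averaging, favoring SNR over per-block RDM averaging.

The PC-constrained variant centers the learner's item × voxel matrix,
takes the SVD, and rebuilds a Euclidean RDM from the top-k item scores
(components ordered by singular value, sign fixed by the
largest-magnitude loading). Only the learner side is constrained; the
native RDMs stay at the default metric. At full rank the Euclidean
geometry is preserved to 1e-8, which the tests assert.

Median splits on learning outcome exclude learners exactly at the median
(mirroring a 53-learner cohort splitting 26/25 with two removed).

## Predictive modeling

Nested 10-fold CV with seeded random near-equal folds (sizes differ by at
most 1). Screening uses partial Pearson r(feature, target | block-1
accuracy) with two-sided p on n − 3 df; the top-fraction rule keeps
`ceil(F × 0.10)` features with ties broken by column order. Sign
restriction filters on the sign of the partial r before thresholding.
PCA reduction is centered and unscaled; components correlating with the
training target at p < 0.05 are kept, with the first component as
fallback and an identity pass-through for a single selected feature.
Zero selected features fall back to training-mean prediction. Features
are z-scored within the training fold before model fitting (flag to
disable); the SVR is linear with C = 1 (the gamma parameter of the usual
library default, 1/n_features, is inert for a linear kernel).

Inference:

- **Permutation null**: every feature column and the target are permuted
  independently, the full CV re-run, and the add-one estimator
  `p = (1 + #{null ≥ observed}) / (1 + n_perm)` reported. Note the CV
  Pearson(predicted, observed) statistic is *negatively biased* under the
  null (held-out predictions from weak or fallback models anticorrelate
  with fold means; the null median sits near −0.15 at n = 53, F = 94).
  Because the permutation null shares this bias, the test remains
  calibrated — the rejection-rate test verifies 1–10% rejections at
  α = 0.05.
- **Bootstrap stability**: fold membership is re-drawn (no subject
  resampling) and the spread of powers reported.
- **Region contributions**: each feature's bootstrap-median screening
  partial correlation is compared one-tailed against that feature's own
  permutation distribution; Benjamini–Hochberg at q = 0.05. With 94
  features the smallest achievable add-one p must clear the BH threshold,
  so this analysis needs on the order of 1,000+ permutations (tests use
  999; the traditional choice is 10,000 and is available via config).

Default permutation/bootstrap counts in `PredictConfig` are the test-scale
199/200; 10,000 is a config value away.

## Feedback decoding

Two-class LDA with lsqr solver and Ledoit–Wolf shrinkage of the pooled
covariance — with voxels greatly outnumbering trials a plain covariance is
singular, and shrinkage never fails silently. Balanced leave-one-block-out
CV: the held-out block is the test chunk; within both chunks the classes
are subsampled to the minority count, so chance is exactly 0.5 by
construction (asserted). Subsampling repeats default to 20 (averaged);
whether balancing should be repeated is not specified anywhere, so the
repeat count is a parameter. Blocks lacking a class are dropped with a
warning; learners with a perfect-accuracy late block are excluded.

## Searchlight

Sphere membership is inclusive (`‖offset‖ ≤ radius`) in isotropic voxel
units, with an optional per-axis scaling for anisotropic voxels;
`min_voxels` defaults to 10. Sphere RDMs use correlation distance,
matching the neural-RDM default. Group maps require pre-aligned grids and
use a voxelwise one-sample t-test with optional BH masking; spatial
normalization is out of scope.

## The synthetic cohort

The generator emulates the *structure* of the study — 53 learners and 33
natives, 40 tokens, six 40-trial feedback blocks, ~7.1% missing responses
— with a known generative model:

- **Behavior**: expected accuracy `clip(a·block^b, [0,1])` with
  `a = 0.10 + 0.20u`, `b = 0.15 + 0.55u` linear in a latent ability
  `u ∈ [0,1]`, spanning near-chance first blocks to near-ceiling late
  phases. Error responses draw a wrong tone with probability
  `∝ exp(−d/0.35)` for distance d in the min-max-normalized
  (F0 height, F0 slope) plane — an explicit stand-in, since no behavioral
  generative model is given anywhere; it reproduces the signature that
  category fits rise and syllable fits fall as accuracy grows (the CAT and
  Syllable model RDMs are negatively associated over item pairs, so the
  second follows from the first). Hand maps are counterbalanced
  ({T1,T2}→left for half the learners, swapped for the rest).
- **Tone archetypes** are invented constants (T1 210 Hz/flat, T2 160/+50,
  T3 150/−20, T4 220/−90, ±20 Hz talker register, small jitter); only
  their ordinal geometry matters and the tests only rely on that.
- **Patterns**: a shared latent rank-5 native geometry (orthonormal 20 × 5
  coordinates scaled 3.0…1.0) is embedded per subject/region through
  orthonormal voxel bases (Euclidean distances survive exactly at zero
  noise); learner patterns mix it with a syllable geometry as
  `w·native + (1−w)·syllable + noise(σ=0.4)`. In planted regions
  `w_early = 0.15 + 0.25u`, `w_late = 0.20 + 0.70u`; elsewhere w is
  ability-independent (0.30–0.40). Defaults: 10 named regions, 30
  voxels each, 4 planted.
- **Feedback patterns** separate the classes along a random direction with
  magnitude `0.3 + 2.2u` (late, planted), `0.3 + 0.8u` (early, planted),
  0.8 elsewhere — so decodability is above chance everywhere but tracks
  ability only where planted.

What it does **not** emulate: hemodynamics and temporal autocorrelation,
spatial smoothness and anatomical variability, voxel-count differences
across subjects, attention/motivation drift, or any dependence between
behavioral errors and the neural patterns beyond the shared ability
parameter. Passing recovery tests therefore demonstrates that the
*estimators* are correct and calibrated under the assumed generative
family, not that real data meet those assumptions. The generator produces
early/late phase patterns; block-pair windows are handled analytically by
the same machinery but are not separately generated.

## Problem sizes used in tests

The unit and acceptance suites run cohorts of 12–30 learners with 2–8
natives and 2–6 regions, full 53 × 94 matrices for the prediction
calibration (100 null runs × 199 permutations; 20 planted runs at 199,
and 999 permutations for region recovery), and a 12³ searchlight volume;
the acceptance script runs the full default 53 + 33 cohort. These sizes
keep a complete run in minutes while leaving every estimator at the
regime the study design implies (same subject counts for prediction, same
item geometry throughout).

## Known limitations

- Ability→(a, b) is linear and the confusion kernel fixed; both are
  configuration points, not estimates from data.
- The behavioral and neural generators share only the scalar ability;
  richer learner-state dynamics (e.g. trial-level learning) are absent.
- Region contributions inherit the coarse resolution of empirical
  permutation p-values (see above).
- Group-level repeated-measures ANOVAs / paired t-tests on real cohorts
  are not re-implemented; the package exposes the per-subject quantities
  such tests consume.
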
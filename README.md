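# tonelearn

Analysis pipeline for studies of non-native speech-category learning that
ask whether a learner's emerging neural representations become similar to
those of native listeners, and whether that similarity — together with
neural sensitivity to corrective feedback — predicts how fast and how well
individuals learn.

The package is aimed at researchers running feedback-based category
training (e.g. English speakers learning the four Mandarin tones across
2 talkers × 4 tones × 5 syllables = 40 stimuli, six 40-trial blocks) who
have trial-wise activation estimates per region and trial-by-trial
behavioral records, and want the full multivariate analysis stack without
touching raw BOLD time series.

## What it computes

**Representational dissimilarity matrices (RDMs).** All stages reduce data
to symmetric item × item dissimilarity matrices over the 20 talker-collapsed
(tone, syllable) items: binary tone-category (CAT) and syllable models,
acoustic F0-height/F0-slope and multidimensional pitch (MD) models, and
neural RDMs from activation patterns (correlation distance
`d_ij = 1 − r(x_i, x_j)` by default).

**Learning curves.** Block accuracies are fitted with `Y = aX^b` (and
hyperbolic, logarithmic, linear alternatives for goodness-of-fit
comparison); learning speed is `LS = a·b` and learning outcome is the mean
accuracy of the last three blocks.

**Behavioral RSA.** Block-wise binary response-confusion matrices (0 if two
sounds received the same response, per talker, then talker-averaged) are
correlated with the model RDMs via Spearman's ρ.

**Intersubject neural representational similarity (IS-NRS).** For every
learner–native pair and region, the two vectorized neural RDMs are compared
with a partial Spearman correlation controlling the response-hand RDM, then
averaged over natives. A PC-constrained variant (SVD of the learner's item
patterns, Euclidean RDM on the top-k component scores) traces how
representational dimensionality relates to learning.

**Predictive modeling.** Nested 10-fold cross-validation: within training
folds, features are screened by partial Pearson correlation with the target
controlling block-1 accuracy (p < 0.01 or top 10%), reduced by PCA
(components kept at p < 0.05 against the training target), and fed to a
linear GLM or linear SVR (C = 1). Predictive power is
`r(predicted, observed)` over held-out subjects; significance comes from a
full-shuffle permutation null, stability from re-randomized fold splits,
and region contributions from per-feature permutation tests with
Benjamini–Hochberg FDR correction.

**Feedback decoding.** Neural feedback sensitivity per region is the
balanced leave-one-block-out accuracy of a shrinkage-LDA classifier at
separating correct- from incorrect-feedback trials.

**Searchlight RSA** maps model fits (Fisher-z Spearman) across a volume,
plus a one-sample group t-map.

A synthetic-cohort generator (`tonelearn.simulate`) emulates the full study
— 53 learners, 33 natives, power-law learning, planted predictive regions,
a latent rank-5 native geometry — with ground truth returned for recovery
testing, so the entire pipeline runs end-to-end with no data downloads.

## Worked example

```python
import numpy as np
from tonelearn.simulate import CohortConfig, make_stimulus_catalog, \
    simulate_behavior, simulate_patterns
from tonelearn.behavior import block_accuracies, fit_learning_curve
from tonelearn.isnrs import isnrs_matrix
from tonelearn.predict import PredictConfig, fit_predict_cv, permutation_null
from scipy.stats import spearmanr

cfg = CohortConfig(seed=1)                      # 53 learners, 33 natives
catalog = make_stimulus_catalog(1)
table, truth = simulate_behavior(cfg, catalog)
patterns, _ = simulate_patterns(cfg, catalog)

fits = [fit_learning_curve(block_accuracies(table, l), "power")
        for l in range(cfg.n_learners)]
outcome = np.array([f.learning_outcome for f in fits])
block1 = np.array([block_accuracies(table, l)[0] for l in range(cfg.n_learners)])

late = isnrs_matrix(patterns, "late")           # learners x regions
print(round(spearmanr(truth.ability, late.values["L.STG"]).statistic, 2))
# 0.78   -- IS-NRS in a planted region tracks latent learning ability

pcfg = PredictConfig(n_permutations=199, seed=1)
res = fit_predict_cv(late.values, outcome, block1, pcfg)
_, _, p = permutation_null(late.values, outcome, block1, pcfg)
print(round(res.power, 2), p)
# 0.87 0.005   -- late-phase IS-NRS predicts learning outcome well above
#                the permutation null; the early phase is at chance
```

The same run from a shell:

```sh
tonelearn pipeline --seed 1 --out run1/     # all stages + manifest
tonelearn simulate --seed 1 --out cohort1/  # cohort files only
```

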
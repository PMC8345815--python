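"""Feedback-valence decoding: neural sensitivity to corrective feedback.

Neural feedback sensitivity is operationalized as the accuracy of a linear
discriminant analysis (LDA) classifier at telling correct- from
incorrect-feedback trials from their feedback-locked activation patterns,
with a *balanced leave-one-block-out* cross-validation: each fold holds one
block out for testing, and within both the training and the test chunk the
two feedback classes are randomly subsampled to the minority count so the
classifier never benefits from class imbalance (accuracy chance level is
exactly 0.5).  Subsampling is repeated and accuracies averaged.  Because
voxels typically outnumber trials, the pooled covariance is
shrinkage-regularized (Ledoit-Wolf).

The resulting learner-by-region accuracy matrix feeds the predictive
modeling engine; trials without a response are removed beforehand, and
learners with a perfect-accuracy block in the late phase (no incorrect
feedback to decode) are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "DecodingResult",
    "balanced_partitions",
    "lda_feedback_accuracy",
    "exclude_perfect_block_learners",
    "feedback_feature_matrix",
    "decode_cohort",
]


@dataclass(frozen=True)
class DecodingResult:
    learner: int
    roi: str
    phase: str
    accuracy: float
    n_trials: int
    chance: float = 0.5


def balanced_partitions(labels, blocks, n_repeats: int = 20, rng=None):
    """Balanced leave-one-block-out train/test index sets.

    ``labels`` are boolean (correct feedback) per trial; ``blocks`` the
    block index per trial.  Blocks lacking either class are dropped with a
    warning.  Per fold, the held-out block supplies the test trials and the
    remaining blocks the training trials; within each chunk both classes
    are subsampled to the minority count.  Fresh subsamples are drawn on
    each of ``n_repeats`` repeats.
    """
    labels = np.asarray(labels, dtype=bool)
    blocks = np.asarray(blocks)
    rng = np.random.default_rng(rng)
    usable = []
    for b in np.unique(blocks):
        in_b = blocks == b
        if labels[in_b].any() and (~labels[in_b]).any():
            usable.append(b)
        else:
            warnings.warn(f"block {b} lacks one feedback class; dropped")
    if len(usable) < 2:
        raise ValueError("need at least 2 usable blocks for leave-one-block-out")
    usable_mask = np.isin(blocks, usable)

    def _balance(idx):
        pos = idx[labels[idx]]
        neg = idx[~labels[idx]]
        m = min(len(pos), len(neg))
        take = np.concatenate(
            [rng.choice(pos, m, replace=False), rng.choice(neg, m, replace=False)]
        )
        return np.sort(take)

    folds = []
    for _ in range(n_repeats):
        for b in usable:
            test_idx = np.flatnonzero((blocks == b) & usable_mask)
            train_idx = np.flatnonzero((blocks != b) & usable_mask)
            folds.append((_balance(train_idx), _balance(test_idx)))
    return folds


def lda_feedback_accuracy(
    patterns,
    labels,
    blocks,
    n_repeats: int = 20,
    rng=None,
) -> float:
    """Mean balanced leave-one-block-out LDA accuracy.

    Uses a shrinkage-regularized linear discriminant (lsqr solver with
    Ledoit-Wolf shrinkage) so the pooled covariance is invertible even
    with far more voxels than trials.
    """
    x = np.asarray(patterns, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("need both feedback classes")
    folds = balanced_partitions(labels, blocks, n_repeats=n_repeats, rng=rng)
    accs = []
    for train, test in folds:
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        clf.fit(x[train], labels[train])
        accs.append(float((clf.predict(x[test]) == labels[test]).mean()))
    return float(np.mean(accs))


def exclude_perfect_block_learners(
    behavior: pd.DataFrame, blocks=(4, 5, 6)
) -> list:
    """Learners with a 100%-accuracy block among ``blocks`` (no incorrect
    feedback available there), to be excluded from feedback decoding."""
    excluded = []
    for learner in sorted(behavior["learner"].unique()):
        sub = behavior[(behavior["learner"] == learner) & behavior["block"].isin(blocks)]
        for b in blocks:
            blk = sub[sub["block"] == b]
            if len(blk) and blk["correct"].all():
                excluded.append(learner)
                break
    return excluded


def decode_cohort(
    feedback_patterns: dict,
    phases=("early", "late"),
    n_repeats: int = 20,
    seed: int = 0,
    exclude=(),
) -> pd.DataFrame:
    """Run feedback decoding for every (learner, roi, phase) in the cohort.

    ``feedback_patterns`` maps ``(learner, roi, phase)`` to
    ``(patterns, labels, blocks)`` as produced by
    :func:`tonelearn.simulate.simulate_feedback_patterns`.
    """
    rows = []
    exclude = set(exclude)
    for (learner, roi, phase), (x, labels, blocks) in sorted(feedback_patterns.items()):
        if phase not in phases or learner in exclude:
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, 43, int(learner), hash(roi) % (2**31), phase == "late"])
        )
        try:
            acc = lda_feedback_accuracy(x, labels, blocks, n_repeats=n_repeats, rng=rng)
            n_used = len(labels)
        except ValueError:
            acc, n_used = np.nan, 0
        rows.append(
            {"learner": learner, "roi": roi, "phase": phase, "accuracy": acc, "n_trials": n_used}
        )
    return pd.DataFrame(rows)


def feedback_feature_matrix(results: pd.DataFrame, phase: str) -> pd.DataFrame:
    """Learner-by-region matrix of decoding accuracies for one phase,
    ready for the predictive modeling engine."""
    sub = results[results["phase"] == phase]
    mat = sub.pivot(index="learner", columns="roi", values="accuracy")
    if mat.isna().any().any():
        raise ValueError("missing decoding cells; cannot assemble feature matrix")
    return mat
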
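"""Intersubject neural representational similarity (IS-NRS).

IS-NRS quantifies how similar a learner's regional representational
geometry is to that of native listeners: for each learner-native pair and
region, the two item-by-item neural RDMs are vectorized and compared with
a partial Spearman correlation controlling for the response-hand RDM (and
optionally the syllable model); the per-pair values are then averaged over
all natives, giving one value per (learner, region).  A PC-constrained
variant first projects each learner's item patterns onto their top-k
principal components (singular value decomposition) and rebuilds the RDM
with Euclidean distances, tracing how representational dimensionality
relates to the similarity structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rdm import RDM, fisher_z, partial_spearman_rdm, pattern_rdm
from .simulate import CohortPatterns, _hand_map

__all__ = [
    "IsnrsMatrix",
    "item_patterns",
    "pc_constrain",
    "hand_rdm",
    "isnrs_pair",
    "isnrs_matrix",
    "median_split_compare",
]


@dataclass
class IsnrsMatrix:
    """Learner-by-region matrix of native-averaged IS-NRS values."""

    values: pd.DataFrame  # index: learner, columns: roi
    phase: str
    k: int | None
    confounds_used: tuple
    n_natives: int


def item_patterns(trial_maps: np.ndarray, trial_items, items) -> np.ndarray:
    """Average trial-wise activation maps into item-level patterns.

    ``trial_maps`` is trials-by-voxels; ``trial_items`` names each trial's
    (tone, syllable) item, collapsing repetitions and talkers.  Every item
    must have at least one usable trial.
    """
    trial_maps = np.asarray(trial_maps, dtype=float)
    trial_items = np.asarray(trial_items)
    out = np.empty((len(items), trial_maps.shape[1]))
    for i, item in enumerate(items):
        sel = trial_items == item
        if not sel.any():
            raise ValueError(f"item {item!r} has no usable trials")
        out[i] = trial_maps[sel].mean(axis=0)
    return out


def pc_constrain(patterns: np.ndarray, k: int) -> np.ndarray:
    """Item scores on the top-k principal components of the pattern matrix.

    Patterns are column-centered, decomposed by SVD, and the item scores
    ``U_k @ diag(S_k)`` returned (components ordered by singular value;
    sign fixed so each component's largest-magnitude voxel loading is
    positive).  With ``k`` equal to the full rank the Euclidean item
    geometry is preserved exactly.
    """
    x = np.asarray(patterns, dtype=float)
    x = x - x.mean(axis=0)
    max_k = min(x.shape[0] - 1, x.shape[1])
    if not 1 <= k <= max_k:
        raise ValueError(f"k must be in [1, {max_k}]")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    signs = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    signs[signs == 0] = 1.0
    u = u * signs
    return u[:, :k] * s[:k]


def hand_rdm(learner_index: int, items) -> RDM:
    """Binary same-hand(0)/different-hand(1) RDM over the 20 items.

    Uses the learner's counterbalanced category-to-button-to-hand map: two
    items whose tone categories are answered with the same hand are coded 0.
    """
    hands = _hand_map(learner_index)
    h = np.array([hands["T" + it[-1]] for it in items], dtype=object)
    values = (h[:, None] != h[None, :]).astype(float)
    np.fill_diagonal(values, 0.0)
    return RDM(tuple(items), values, kind="hand")


def isnrs_pair(learner_rdm: RDM, native_rdm: RDM, confounds=()):
    """IS-NRS for one learner-native pair: partial Spearman correlation of
    the two vectorized neural RDMs given the confound RDMs (the hand RDM
    always, the syllable model optionally)."""
    return partial_spearman_rdm(learner_rdm, native_rdm, confounds)


def _learner_rdm(patterns, items, k, metric):
    if k is not None:
        scores = pc_constrain(patterns, k)
        return pattern_rdm(scores, items, metric="euclidean")
    return pattern_rdm(patterns, items, metric=metric)


def isnrs_matrix(
    cohort: CohortPatterns,
    phase: str,
    k: int | None = None,
    extra_confounds=(),
    use_hand_confound: bool = True,
    metric: str = "correlation",
    native_phase: str = "whole",
    fisher_average: bool = False,
) -> IsnrsMatrix:
    """Native-averaged IS-NRS per (learner, region).

    For each learner and region the learner's neural RDM (PC-constrained
    Euclidean when ``k`` is set, otherwise correlation distance by default)
    is compared against every native listener's RDM and the pairwise
    correlations averaged (arithmetic mean of rho by default; Fisher-z
    averaging available).
    """
    items = cohort.item_labels
    learners = cohort.subjects("learner")
    natives = cohort.subjects("native")
    if not natives:
        raise ValueError("no native subjects in cohort")
    extra_confounds = tuple(extra_confounds)
    out = np.empty((len(learners), len(cohort.roi_names)))
    confound_names = ()
    for j, roi in enumerate(cohort.roi_names):
        native_rdms = [
            pattern_rdm(cohort.get("native", n, roi, native_phase), items, metric=metric)
            for n in natives
        ]
        for i, learner in enumerate(learners):
            lrdm = _learner_rdm(cohort.get("learner", learner, roi, phase), items, k, metric)
            confounds = (
                (hand_rdm(learner, items),) if use_hand_confound else ()
            ) + extra_confounds
            rhos = [isnrs_pair(lrdm, nrdm, confounds).rho for nrdm in native_rdms]
            if confounds:
                confound_names = tuple(c.kind for c in confounds)
            if fisher_average:
                out[i, j] = np.tanh(np.mean([fisher_z(r) for r in rhos]))
            else:
                out[i, j] = np.mean(rhos)
    values = pd.DataFrame(out, index=learners, columns=list(cohort.roi_names))
    return IsnrsMatrix(
        values=values,
        phase=phase,
        k=k,
        confounds_used=confound_names,
        n_natives=len(natives),
    )


def median_split_compare(isnrs: IsnrsMatrix, outcomes: pd.Series) -> pd.DataFrame:
    """Successful vs less-successful group means of IS-NRS per region.

    Learners are split at the median learning outcome; learners exactly at
    the median are excluded (as when 53 learners split into groups of 26
    and 25 with two at the median removed).
    """
    outcomes = outcomes.loc[isnrs.values.index]
    if len(outcomes) < 4:
        raise ValueError("need at least 4 learners")
    med = float(outcomes.median())
    if outcomes.nunique() == 1:
        raise ValueError("all outcomes identical; median split undefined")
    hi = outcomes.index[outcomes > med]
    lo = outcomes.index[outcomes < med]
    rows = []
    for roi in isnrs.values.columns:
        m_hi = float(isnrs.values.loc[hi, roi].mean())
        m_lo = float(isnrs.values.loc[lo, roi].mean())
        rows.append(
            {
                "roi": roi,
                "phase": isnrs.phase,
                "k": isnrs.k,
                "successful_mean": m_hi,
                "less_successful_mean": m_lo,
                "difference": m_hi - m_lo,
                "n_successful": len(hi),
                "n_less_successful": len(lo),
            }
        )
    return pd.DataFrame(rows)
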
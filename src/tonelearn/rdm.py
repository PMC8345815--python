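"""Representational dissimilarity matrices (RDMs) and their comparison.

An RDM is a labelled, symmetric, zero-diagonal item-by-item matrix of
pairwise dissimilarities.  Every analysis stage in this package — behavioral
response modeling, intersubject neural similarity, searchlight mapping —
reduces its data to RDMs over the same ordered item set and compares them
with (partial) Spearman correlation, so this module is the shared kernel.

Missing entries (e.g. confusion-matrix cells involving a trial with no
response) are encoded as NaN off-diagonal values and dropped pairwise in
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RDM",
    "RdmComparison",
    "build_categorical_rdm",
    "build_feature_rdm",
    "normalize_rdm",
    "pattern_rdm",
    "vectorize",
    "spearman_rdm",
    "partial_spearman_rdm",
    "fisher_z",
]


@dataclass(frozen=True)
class RDM:
    """Labelled symmetric dissimilarity matrix.

    Parameters
    ----------
    labels : tuple of str
        Ordered item identifiers.  All RDMs entering one comparison must
        share the same labels in the same order.
    values : ndarray, shape (m, m)
        Symmetric, zero-diagonal, non-negative dissimilarities.  NaN marks
        a missing off-diagonal entry.
    kind : str
        Free-form tag, e.g. ``"CAT"``, ``"Syllable"``, ``"neural"``,
        ``"hand"``, ``"native-neural"``.
    """

    labels: tuple
    values: np.ndarray
    kind: str = "neural"

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", tuple(self.labels))
        m = len(self.labels)
        if vals.shape != (m, m):
            raise ValueError(
                f"values shape {vals.shape} does not match {m} labels"
            )
        if not np.allclose(np.diag(vals), 0.0, equal_nan=False):
            raise ValueError("RDM diagonal must be zero")
        finite = np.isfinite(vals)
        sym_ok = np.array_equal(finite, finite.T) and np.allclose(
            vals[finite & finite.T], vals.T[finite & finite.T]
        )
        if not sym_ok:
            raise ValueError("RDM must be symmetric")

    @property
    def n_items(self) -> int:
        return len(self.labels)

    def vector(self) -> np.ndarray:
        """Row-major upper-triangle vector (diagonal excluded)."""
        return vectorize(self)


@dataclass(frozen=True)
class RdmComparison:
    """Result of correlating two vectorized RDMs."""

    rho: float
    confounds_used: tuple = field(default_factory=tuple)
    n_pairs: int = 0


def _check_same_labels(*rdms: RDM) -> None:
    ref = rdms[0].labels
    for r in rdms[1:]:
        if r.labels != ref:
            raise ValueError("RDMs have mismatching item labels/order")


def build_categorical_rdm(labels_map: dict, kind: str = "CAT") -> RDM:
    """Binary RDM: 0 for same category, 1 for different categories.

    ``labels_map`` maps every item identifier to its category.  Item order
    follows insertion order of the mapping.
    """
    items = tuple(labels_map.keys())
    cats = [labels_map[i] for i in items]
    if any(c is None for c in cats):
        raise ValueError("every item must be labelled")
    arr = np.array(cats, dtype=object)
    values = (arr[:, None] != arr[None, :]).astype(float)
    np.fill_diagonal(values, 0.0)
    return RDM(items, values, kind=kind)


def build_feature_rdm(
    features: dict,
    metric: str = "absolute-difference",
    normalize_dims: bool = False,
    kind: str = "feature",
) -> RDM:
    """RDM from per-item real-valued feature vectors.

    ``metric``: ``"absolute-difference"`` for scalar features (e.g. mean F0),
    ``"euclidean"`` for multidimensional features (e.g. the pitch
    height-by-slope plane).  With ``normalize_dims`` each dimension is
    min-max scaled to [0, 1] before the distance is taken — the convention
    for the multidimensional pitch model.
    """
    items = tuple(features.keys())
    mat = np.atleast_2d(
        np.array([np.atleast_1d(np.asarray(features[i], dtype=float)) for i in items])
    )
    if not np.all(np.isfinite(mat)):
        raise ValueError("non-finite feature value")
    if normalize_dims:
        lo, hi = mat.min(axis=0), mat.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        mat = (mat - lo) / span
    diff = mat[:, None, :] - mat[None, :, :]
    if metric == "absolute-difference":
        if mat.shape[1] != 1:
            raise ValueError("absolute-difference requires scalar features")
        values = np.abs(diff[:, :, 0])
    elif metric == "euclidean":
        values = np.sqrt((diff**2).sum(axis=-1))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(values, 0.0)
    return RDM(items, values, kind=kind)


def normalize_rdm(rdm: RDM, anchor_zero: bool = False) -> RDM:
    """Scale off-diagonal values to [0, 1], preserving order.

    Default is min-max scaling of the off-diagonal values.  With
    ``anchor_zero`` the values are divided by their maximum instead, so a
    dissimilarity of exactly zero stays zero — the convention used for the
    stimulus model RDMs, where identical features must keep distance 0.
    """
    values = rdm.values.copy()
    off = ~np.eye(rdm.n_items, dtype=bool)
    vals = values[off]
    vals = vals[np.isfinite(vals)]
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        raise ValueError("cannot normalize a constant RDM")
    if anchor_zero:
        values[off] = values[off] / hi
    else:
        values[off] = (values[off] - lo) / (hi - lo)
    np.fill_diagonal(values, 0.0)
    return RDM(rdm.labels, values, kind=rdm.kind)


def pattern_rdm(
    patterns: np.ndarray,
    labels,
    metric: str = "correlation",
    kind: str = "neural",
) -> RDM:
    """RDM from an item-by-voxel activation matrix.

    ``metric="correlation"`` gives 1 − Pearson r between item patterns
    (default for activation-pattern RDMs); ``"euclidean"`` is used for the
    PC-constrained dimensionality analysis.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2 or patterns.shape[0] < 3 or patterns.shape[1] < 1:
        raise ValueError("need >=3 items and >=1 voxel")
    if metric == "correlation":
        if patterns.shape[1] < 2:
            raise ValueError("correlation distance needs >=2 voxels")
        sd = patterns.std(axis=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance item pattern under correlation metric")
        values = 1.0 - np.corrcoef(patterns)
    elif metric == "euclidean":
        diff = patterns[:, None, :] - patterns[None, :, :]
        values = np.sqrt((diff**2).sum(axis=-1))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return RDM(tuple(labels), values, kind=kind)


def vectorize(rdm: RDM) -> np.ndarray:
    """Upper triangle (diagonal excluded) in row-major order.

    Length is m(m−1)/2; identical ordering is used for every RDM entering a
    comparison, which is what makes vector correlations meaningful.
    """
    iu = np.triu_indices(rdm.n_items, k=1)
    return rdm.values[iu]


def _pairwise_complete(vectors):
    mask = np.all([np.isfinite(v) for v in vectors], axis=0)
    return [v[mask] for v in vectors]


def spearman_rdm(a: RDM, b: RDM) -> RdmComparison:
    """Spearman rank correlation of two vectorized RDMs (pairwise-complete)."""
    _check_same_labels(a, b)
    va, vb = _pairwise_complete([vectorize(a), vectorize(b)])
    if len(va) < 3:
        raise ValueError("fewer than 3 complete pairs")
    ra, rb = stats.rankdata(va), stats.rankdata(vb)
    if ra.std() == 0 or rb.std() == 0:
        raise ValueError("constant vector after ranking")
    rho = float(np.corrcoef(ra, rb)[0, 1])
    return RdmComparison(rho=rho, confounds_used=(), n_pairs=len(va))


def partial_spearman_rdm(a: RDM, b: RDM, confounds=()) -> RdmComparison:
    """Partial Spearman correlation of ``a`` and ``b`` given confound RDMs.

    Defined as the partial Pearson correlation of the rank-transformed
    (average ranks for ties) vectorized RDMs: ranks of ``a`` and ``b`` are
    residualized on the confound ranks (with intercept) by least squares and
    the residuals correlated.  With no confounds this reduces exactly to
    :func:`spearman_rdm`.
    """
    confounds = tuple(confounds)
    if not confounds:
        return spearman_rdm(a, b)
    _check_same_labels(a, b, *confounds)
    vecs = _pairwise_complete(
        [vectorize(a), vectorize(b)] + [vectorize(c) for c in confounds]
    )
    va, vb, vcs = vecs[0], vecs[1], vecs[2:]
    if len(va) < 3 + len(vcs):
        raise ValueError("too few complete pairs for partial correlation")
    ranks = [stats.rankdata(v) for v in (va, vb, *vcs)]
    ra, rb, rcs = ranks[0], ranks[1], ranks[2:]
    design = np.column_stack([np.ones(len(ra))] + list(rcs))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear confounds (rank-deficient residualization)")
    coef_a, *_ = np.linalg.lstsq(design, ra, rcond=None)
    coef_b, *_ = np.linalg.lstsq(design, rb, rcond=None)
    res_a = ra - design @ coef_a
    res_b = rb - design @ coef_b
    if res_a.std() == 0 or res_b.std() == 0:
        raise ValueError("degenerate residuals in partial correlation")
    rho = float(np.corrcoef(res_a, res_b)[0, 1])
    return RdmComparison(
        rho=rho,
        confounds_used=tuple(c.kind for c in confounds),
        n_pairs=len(va),
    )


def fisher_z(r: float) -> float:
    """Fisher z-transform, z = arctanh(r); requires |r| < 1."""
    r = float(r)
    if abs(r) >= 1.0:
        raise ValueError("|r| must be < 1 for the Fisher z-transform")
    return float(np.arctanh(r))
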
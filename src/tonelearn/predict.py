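"""Nested cross-validated brain-behavior predictive modeling.

Predicts a per-learner target (learning outcome, learning speed, or an
IS-NRS composite) from region-wise neural features with a nested 10-fold
cross-validation:

1. *Screening* (training folds only): partial Pearson correlation of each
   feature with the target, controlling the first-block accuracy
   covariate; keep features with p below a threshold (default 0.01) or the
   top fraction (default 10%, ceiling) by |partial r|, optionally
   restricted to one sign of correlation.
2. *Reduction*: PCA (centered, unscaled) of the selected training
   features; retain components whose correlation with the training target
   has p < 0.05 (first component as fallback).
3. *Model*: ordinary least squares (GLM) or linear support vector
   regression (C = 1); predictions are made for the held-out fold only.

Predictive power is the Pearson correlation between assembled held-out
predictions and observed targets.  Significance comes from a permutation
null (features and target independently shuffled, full CV re-run each
iteration, add-one p-value); stability from re-randomized fold splits
(bootstrap); and per-region contributions from comparing each feature's
bootstrap-median screening correlation against its own permutation
distribution, Benjamini-Hochberg corrected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PredictConfig",
    "PredictionResult",
    "partial_pearson",
    "screen_features",
    "reduce_pcs",
    "fit_predict_cv",
    "permutation_null",
    "bootstrap_stability",
    "region_contributions",
    "predict_learning",
    "dimensionality_curve",
]


@dataclass(frozen=True)
class PredictConfig:
    n_folds: int = 10
    screen_rule: str = "p_threshold"  # or "top_fraction"
    p_threshold: float = 0.01
    top_fraction: float = 0.10
    sign_restriction: str = "any"  # "positive" | "negative"
    pc_retain_p: float = 0.05
    model: str = "glm"  # or "svr"
    svr_c: float = 1.0
    standardize: bool = True
    n_permutations: int = 199
    n_bootstraps: int = 200
    alpha: float = 0.05
    fdr_q: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")


@dataclass
class PredictionResult:
    observed: np.ndarray
    predicted: np.ndarray
    power: float
    null_powers: np.ndarray | None = None
    p_value: float | None = None
    bootstrap_powers: np.ndarray | None = None
    feature_names: tuple = ()
    region_table: pd.DataFrame | None = None
    config: PredictConfig | None = None


def _pearson_p(r: np.ndarray, df: int) -> np.ndarray:
    r = np.clip(r, -0.999999, 0.999999)
    t = r * np.sqrt(df / (1.0 - r**2))
    return 2.0 * stats.t.sf(np.abs(t), df)


def partial_pearson(x: np.ndarray, y: np.ndarray, cov: np.ndarray):
    """Columnwise partial Pearson r of ``x`` with ``y`` given ``cov``.

    Residualizes each column of ``x`` and ``y`` on [1, cov] and correlates
    the residuals; p-values use n − 3 degrees of freedom.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 observations")
    design = np.column_stack([np.ones(n), np.asarray(cov, dtype=float)])
    q, _ = np.linalg.qr(design)
    rx = x - q @ (q.T @ x)
    ry = y - q @ (q.T @ y)
    sx = np.sqrt((rx**2).sum(axis=0))
    sy = math.sqrt((ry**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rx.T @ ry) / (sx * sy)
    r = np.where(np.isfinite(r), r, 0.0)
    return r, _pearson_p(r, n - 3)


def screen_features(x, y, cov, config: PredictConfig):
    """Select predictive feature columns on the training data.

    Returns ``(selected_indices, partial_r)`` where ``partial_r`` holds the
    covariate-controlled correlation of every feature (selected or not).
    The top-fraction rule keeps ``ceil(F * fraction)`` features by
    |partial r| with ties broken by column order.
    """
    r, p = partial_pearson(x, y, cov)
    candidates = np.arange(x.shape[1])
    if config.sign_restriction == "positive":
        candidates = candidates[r[candidates] > 0]
    elif config.sign_restriction == "negative":
        candidates = candidates[r[candidates] < 0]
    if config.screen_rule == "p_threshold":
        selected = candidates[p[candidates] < config.p_threshold]
    elif config.screen_rule == "top_fraction":
        n_keep = min(len(candidates), math.ceil(x.shape[1] * config.top_fraction))
        order = np.lexsort((candidates, -np.abs(r[candidates])))
        selected = np.sort(candidates[order[:n_keep]])
    else:
        raise ValueError(f"unknown screen rule {config.screen_rule!r}")
    return selected, r


def reduce_pcs(x_sel: np.ndarray, y: np.ndarray, pc_retain_p: float = 0.05):
    """PCA reduction of the selected training features.

    Centers (no scaling), decomposes by SVD, and keeps components whose
    Pearson correlation with the training target has p < ``pc_retain_p``;
    falls back to the first component when none qualifies.  With a single
    selected feature the identity pass-through is returned.  The returned
    ``transform`` maps new subjects into the retained score space using
    the training mean and basis unchanged.
    """
    x_sel = np.asarray(x_sel, dtype=float)
    if x_sel.shape[1] < 2:
        mean = np.zeros(x_sel.shape[1])
        return (lambda z: np.asarray(z, dtype=float)), x_sel.copy()
    mean = x_sel.mean(axis=0)
    xc = x_sel - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    nz = s > max(s[0], 1e-12) * 1e-10 if len(s) else s > 0
    vt = vt[nz]
    scores = xc @ vt.T
    n = len(y)
    sy = np.asarray(y, dtype=float) - np.mean(y)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (scores.T @ sy) / (
            np.sqrt((scores**2).sum(axis=0)) * math.sqrt((sy**2).sum())
        )
    r = np.where(np.isfinite(r), r, 0.0)
    p = _pearson_p(r, n - 2)
    keep = np.flatnonzero(p < pc_retain_p)
    if keep.size == 0:
        keep = np.array([0])
    basis = vt[keep]

    def transform(z):
        return (np.asarray(z, dtype=float) - mean) @ basis.T

    return transform, scores[:, keep]


def _fit_model(scores, y, config: PredictConfig):
    if config.standardize:
        mu, sd = scores.mean(axis=0), scores.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        mu, sd = np.zeros(scores.shape[1]), np.ones(scores.shape[1])
    z = (scores - mu) / sd
    if config.model == "glm":
        design = np.column_stack([np.ones(len(y)), z])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)

        def predictor(s):
            zz = (s - mu) / sd
            return coef[0] + zz @ coef[1:]

    elif config.model == "svr":
        from sklearn.svm import SVR

        # linear kernel; gamma (1/n_features) is inert for this kernel but
        # kept at the library default for parity with common practice
        model = SVR(kernel="linear", C=config.svr_c)
        model.fit(z, y)

        def predictor(s):
            return model.predict((s - mu) / sd)

    else:
        raise ValueError(f"unknown model {config.model!r}")
    return predictor


def _fold_assignment(n: int, n_folds: int, rng) -> np.ndarray:
    """Seeded random partition into near-equal folds (sizes differ by <=1)."""
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(order, n_folds)):
        folds[chunk] = f
    return folds


def _run_cv(x, y, cov, config: PredictConfig, rng):
    """One full nested-CV pass.

    Returns ``(predictions, feature_stats)``: held-out predictions for all
    subjects and the per-feature screening partial correlations averaged
    over training folds (used for region contributions).
    """
    n, n_feat = x.shape
    folds = _fold_assignment(n, config.n_folds, rng)
    pred = np.empty(n)
    feat_stats = np.zeros(n_feat)
    for f in range(config.n_folds):
        test = folds == f
        train = ~test
        sel, r_all = screen_features(x[train], y[train], cov[train], config)
        feat_stats += r_all
        if sel.size == 0:
            pred[test] = y[train].mean()
            continue
        transform, scores = reduce_pcs(x[train][:, sel], y[train], config.pc_retain_p)
        predictor = _fit_model(scores, y[train], config)
        pred[test] = predictor(transform(x[test][:, sel]))
    return pred, feat_stats / config.n_folds


def _power(pred, obs) -> float:
    if np.std(pred) == 0 or np.std(obs) == 0:
        warnings.warn("constant predictions; predictive power recorded as 0")
        return 0.0
    return float(np.corrcoef(pred, obs)[0, 1])


def _as_matrix(features, target, covariate):
    if isinstance(features, pd.DataFrame):
        names = tuple(features.columns)
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        names = tuple(f"f{i}" for i in range(x.shape[1]))
    y = np.asarray(target, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if np.isnan(x).any() or np.isnan(y).any() or np.isnan(cov).any():
        raise ValueError("missing cells in the assembled feature matrix")
    return x, y, cov, names


def fit_predict_cv(features, target, covariate, config: PredictConfig) -> PredictionResult:
    """Single nested 10-fold CV run; power = Pearson r(predicted, observed)."""
    x, y, cov, names = _as_matrix(features, target, covariate)
    if len(y) < config.n_folds:
        raise ValueError("need at least n_folds subjects")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 31]))
    pred, _ = _run_cv(x, y, cov, config, rng)
    return PredictionResult(
        observed=y, predicted=pred, power=_power(pred, y),
        feature_names=names, config=config,
    )


def permutation_null(features, target, covariate, config: PredictConfig):
    """Permutation null distribution of the predictive power.

    Every iteration independently permutes each feature column and the
    target, re-runs the full nested CV, and records the power.  Returns
    ``(null_powers, null_feature_stats, p)`` with the add-one estimator
    ``p = (1 + #{null >= observed}) / (1 + n_permutations)``.
    """
    x, y, cov, _ = _as_matrix(features, target, covariate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 37]))
    obs_pred, _ = _run_cv(
        x, y, cov, config, np.random.default_rng(np.random.SeedSequence([config.seed, 31]))
    )
    observed = _power(obs_pred, y)
    null_powers = np.empty(config.n_permutations)
    null_stats = np.empty((config.n_permutations, x.shape[1]))
    for i in range(config.n_permutations):
        xp = np.column_stack([rng.permutation(x[:, j]) for j in range(x.shape[1])])
        yp = rng.permutation(y)
        pred, fstats = _run_cv(xp, yp, cov, config, rng)
        null_powers[i] = _power(pred, yp)
        null_stats[i] = fstats
    p = (1.0 + np.sum(null_powers >= observed)) / (1.0 + config.n_permutations)
    return null_powers, null_stats, float(p)


def bootstrap_stability(features, target, covariate, config: PredictConfig):
    """Distribution of powers over re-randomized 10-fold splits.

    No subject resampling: each iteration re-draws fold membership only,
    so the spread reflects sensitivity to fold composition.
    Returns ``(powers, feature_stats)``.
    """
    x, y, cov, _ = _as_matrix(features, target, covariate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 41]))
    powers = np.empty(config.n_bootstraps)
    boot_stats = np.empty((config.n_bootstraps, x.shape[1]))
    for i in range(config.n_bootstraps):
        pred, fstats = _run_cv(x, y, cov, config, rng)
        powers[i] = _power(pred, y)
        boot_stats[i] = fstats
    return powers, boot_stats


def region_contributions(
    boot_stats: np.ndarray,
    null_stats: np.ndarray,
    feature_names,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Per-region significance of the screening correlations.

    Each region's bootstrap-median partial correlation is compared
    one-tailed against that region's permutation distribution; the
    resulting p-values are Benjamini-Hochberg corrected at ``fdr_q``.
    """
    medians = np.median(boot_stats, axis=0)
    n_perm = null_stats.shape[0]
    p_raw = (1.0 + (null_stats >= medians[None, :]).sum(axis=0)) / (1.0 + n_perm)
    reject, p_adj, *_ = multipletests(p_raw, alpha=fdr_q, method="fdr_bh")
    return pd.DataFrame(
        {
            "roi": list(feature_names),
            "boot_median_r": medians,
            "p_raw": p_raw,
            "p_fdr": p_adj,
            "significant": reject,
        }
    )


def predict_learning(features, target, covariate, config: PredictConfig) -> PredictionResult:
    """Full inference pipeline: CV fit, permutation null, bootstrap
    stability, and FDR-corrected region contributions."""
    result = fit_predict_cv(features, target, covariate, config)
    null_powers, null_stats, p = permutation_null(features, target, covariate, config)
    boot_powers, boot_stats = bootstrap_stability(features, target, covariate, config)
    result.null_powers = null_powers
    result.p_value = p
    result.bootstrap_powers = boot_powers
    result.region_table = region_contributions(
        boot_stats, null_stats, result.feature_names, config.fdr_q
    )
    return result


def dimensionality_curve(isnrs_by_k: dict, target, covariate, config: PredictConfig) -> pd.DataFrame:
    """Predictive power as a function of representational dimensionality.

    ``isnrs_by_k`` maps a PC count ``k`` to the learner-by-region IS-NRS
    feature table computed at that dimensionality; the same prediction is
    run at every ``k``.
    """
    rows = []
    for k in sorted(isnrs_by_k):
        feats = isnrs_by_k[k]
        if isinstance(feats, (pd.DataFrame, np.ndarray)):
            values = feats
        else:  # IsnrsMatrix
            values = feats.values
        res = fit_predict_cv(values, target, covariate, config)
        _, _, p = permutation_null(values, target, covariate, config)
        rows.append({"k": k, "power": res.power, "p": p})
    return pd.DataFrame(rows)
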
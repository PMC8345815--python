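"""Behavioral learning curves and behavioral RSA (bRSA).

Learning outcome is the mean tone-identification accuracy over the final
three training blocks; learning speed is the product ``a * b`` of the
power-law learning-curve parameters fitted to the block-by-block
accuracies (``acc = a * block**b``).  Three further curve families
(hyperbolic, logarithmic, linear) are fitted for goodness-of-fit
comparison.  bRSA correlates block-wise binary response-confusion matrices
with stimulus model RDMs (tone category, syllable, pitch models, or a
native neural RDM) via Spearman correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .rdm import RDM, spearman_rdm
from .simulate import item_labels

__all__ = [
    "LearningCurveFit",
    "block_accuracies",
    "learning_outcome",
    "fit_learning_curve",
    "confusion_matrix",
    "brsa",
]

FAMILIES = ("power", "hyperbolic", "logarithmic", "linear")


@dataclass(frozen=True)
class LearningCurveFit:
    family: str
    params: tuple
    gof_rms: float
    learning_speed: float | None  # a*b, power family only
    learning_outcome: float


def block_accuracies(table: pd.DataFrame, learner=None) -> np.ndarray:
    """Per-block proportion correct for one learner's trial table.

    Missing-response trials count as incorrect: no correct response was
    given, and they received no "RIGHT" feedback.
    """
    if learner is not None:
        table = table[table["learner"] == learner]
    if table.empty:
        raise ValueError("empty behavior table")
    blocks = np.sort(table["block"].unique())
    accs = []
    for b in blocks:
        sub = table[table["block"] == b]
        if sub.empty:
            raise ValueError(f"empty block {b}")
        accs.append(sub["correct"].to_numpy(dtype=bool).mean())
    return np.asarray(accs)


def learning_outcome(accuracies: np.ndarray, n_final: int = 3) -> float:
    """Mean accuracy over the last ``n_final`` blocks."""
    accuracies = np.asarray(accuracies, dtype=float)
    return float(accuracies[-n_final:].mean())


def _power(x, a, b):
    return a * np.power(x, b)


def _hyperbolic(x, a, b):
    return a * x / (b + x)


def _logarithmic(x, a, b):
    return a + b * np.log(x)


def _init_power(x, y, eps=1e-6):
    ly = np.log(np.maximum(y, eps))
    lx = np.log(x)
    b, la = np.polyfit(lx, ly, 1)
    return np.exp(la), b


def fit_learning_curve(
    accuracies, family: str = "power", bounds_b: tuple = (-5.0, 5.0)
) -> LearningCurveFit:
    """Fit one curve family to block-by-block accuracies.

    Power/hyperbolic/logarithmic use nonlinear least squares initialized
    from a linearization (log-log or reciprocal, with a 1e-6 guard on zero
    accuracies); linear uses ordinary least squares.  The goodness of fit
    is the RMS error between fitted and observed accuracies.
    """
    y = np.asarray(accuracies, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 blocks")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("accuracies must lie in [0, 1]")
    x = np.arange(1, len(y) + 1, dtype=float)
    if family == "linear":
        slope, intercept = np.polyfit(x, y, 1)
        fitted = intercept + slope * x
        params = (float(intercept), float(slope))
    elif family in ("power", "hyperbolic", "logarithmic"):
        func = {"power": _power, "hyperbolic": _hyperbolic, "logarithmic": _logarithmic}[
            family
        ]
        if family == "power":
            p0 = _init_power(x, y)
            bounds = ([0.0, bounds_b[0]], [np.inf, bounds_b[1]])
            p0 = (max(p0[0], 1e-6), float(np.clip(p0[1], *bounds_b)))
        elif family == "hyperbolic":
            p0, bounds = (max(y[-1], 1e-3), 1.0), ([0.0, 1e-6], [np.inf, np.inf])
        else:
            b0, a0 = np.polyfit(np.log(x), y, 1)
            p0, bounds = (a0, b0), (-np.inf, np.inf)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(func, x, y, p0=p0, bounds=bounds, maxfev=20000)
        except RuntimeError:
            # grid fallback for degenerate inputs
            grid = [
                (a, b)
                for a in np.linspace(0.01, 1.0, 20)
                for b in np.linspace(bounds_b[0], bounds_b[1], 41)
            ]
            popt = min(grid, key=lambda p: np.sum((func(x, *p) - y) ** 2))
        fitted = func(x, *popt)
        params = tuple(float(p) for p in popt)
    else:
        raise ValueError(f"unknown family {family!r}")
    gof = float(np.sqrt(np.mean((fitted - y) ** 2)))
    speed = float(params[0] * params[1]) if family == "power" else None
    return LearningCurveFit(
        family=family,
        params=params,
        gof_rms=gof,
        learning_speed=speed,
        learning_outcome=learning_outcome(y),
    )


def _item_of(row) -> str:
    return f"{row.syllable}{row.tone[1]}"


def confusion_matrix(table: pd.DataFrame, block: int, catalog: pd.DataFrame):
    """Block-wise binary response-confusion RDMs.

    For each talker separately, an item pair is coded 0 if the two sounds
    received an identical response and 1 otherwise; entries involving a
    missing-response trial are NaN.  Returns
    ``(per_talker: dict, averaged: RDM)`` where the averaged matrix is the
    elementwise mean of the two talker matrices, ignoring missing cells.
    """
    items = item_labels(catalog)
    sub = table[table["block"] == block]
    if sub.empty:
        raise ValueError(f"block {block} not present")
    per_talker = {}
    stack = []
    for talker in sorted(sub["talker"].unique()):
        tsub = sub[sub["talker"] == talker]
        responses = {}
        for row in tsub.itertuples():
            responses[_item_of(row)] = None if row.missing else row.response
        vals = np.full((len(items), len(items)), np.nan)
        for i, it_i in enumerate(items):
            for j, it_j in enumerate(items):
                ri, rj = responses.get(it_i), responses.get(it_j)
                if ri is not None and rj is not None:
                    vals[i, j] = 0.0 if ri == rj else 1.0
        np.fill_diagonal(vals, 0.0)
        rdm = RDM(items, vals, kind="confusion")
        per_talker[int(talker)] = rdm
        stack.append(vals)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg = np.nanmean(np.stack(stack), axis=0)
    np.fill_diagonal(avg, 0.0)
    return per_talker, RDM(items, avg, kind="confusion")


def brsa(
    table: pd.DataFrame, model_rdms: dict, catalog: pd.DataFrame
) -> pd.DataFrame:
    """Behavioral RSA: Spearman model fits per (learner, block, model).

    Each model RDM is correlated with the talker-averaged confusion matrix
    of each block.  A degenerate confusion matrix (all identical responses)
    yields a missing fit for that block.
    """
    rows = []
    for learner in sorted(table["learner"].unique()):
        sub = table[table["learner"] == learner]
        for block in sorted(sub["block"].unique()):
            _, conf = confusion_matrix(sub, block, catalog)
            for name, model in model_rdms.items():
                try:
                    fit = spearman_rdm(model, conf).rho
                except ValueError:
                    fit = np.nan
                rows.append(
                    {"learner": learner, "block": block, "model": name, "fit": fit}
                )
    return pd.DataFrame(rows)
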
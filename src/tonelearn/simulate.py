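"""Synthetic study-cohort generator.

Emulates the structure of a feedback-based Mandarin-tone category-training
experiment: 40 natural-token stimuli (2 talkers x 4 tones x 5 syllables),
53 non-native learners trained over 6 blocks of 40 trials with corrective
feedback, and 33 native listeners performing the same categorization task.
Every downstream analysis (behavioral RSA, intersubject neural
representational similarity, predictive modeling, feedback decoding,
searchlight) is exercised end-to-end on these synthetic cohorts, whose
ground truth (latent learning ability, planted predictive regions, latent
native representational geometry) is returned alongside the data so that
parameter-recovery tests are possible.

Generative model, in brief:

* Block-wise expected accuracy follows a power law ``acc = a * block**b``
  with ``(a, b)`` a linear function of a latent per-learner ability in
  [0, 1].  On error trials the wrong tone is drawn with probability
  decreasing in its distance from the true tone in the normalized pitch
  (F0 height, F0 slope) plane; a configurable fraction of trials is marked
  missing (no response).
* Item-level activation patterns per region mix a shared latent "native"
  geometry (rank 5, orthonormally embedded per subject so Euclidean item
  distances are preserved) with a syllable-identity geometry and Gaussian
  noise.  The native-geometry weight grows from the early to the late
  training phase, and in *planted* regions its range is tied to ability;
  elsewhere it is independent of ability.
* Feedback-locked trial patterns separate correct from incorrect feedback
  along a random direction whose magnitude covaries with ability in
  planted regions.

All generators are deterministic given ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rdm import RDM, build_categorical_rdm, build_feature_rdm, normalize_rdm

__all__ = [
    "TONES",
    "SYLLABLES",
    "TONE_ARCHETYPES",
    "CohortConfig",
    "GroundTruth",
    "CohortPatterns",
    "make_stimulus_catalog",
    "item_labels",
    "item_pitch_features",
    "model_rdms",
    "simulate_behavior",
    "simulate_patterns",
    "simulate_feedback_patterns",
    "enumerate_lss_models",
    "simulate_volume",
]

TONES = ("T1", "T2", "T3", "T4")
SYLLABLES = ("bu", "di", "lu", "ma", "mi")

# Invented F0 archetypes (Hz, Hz/s) realizing the canonical Mandarin tone
# shapes: T1 high-flat, T2 low-rising, T3 low-dipping, T4 high-falling.
# Only their ordinal geometry matters for the analyses.
TONE_ARCHETYPES = {
    "T1": (210.0, 0.0),
    "T2": (160.0, 50.0),
    "T3": (150.0, -20.0),
    "T4": (220.0, -90.0),
}

_TALKER_F0_OFFSET = {1: 20.0, 2: -20.0}

DEFAULT_ROI_NAMES = (
    "L.IFGtri",
    "L.STG",
    "R.STG",
    "R.PreCG",
    "L.IPL",
    "L.SMG",
    "L.MTG",
    "R.AG",
    "L.Caudate",
    "R.Putamen",
)
DEFAULT_PLANTED_ROIS = ("L.IFGtri", "L.STG", "R.STG", "R.PreCG")

LATENT_DIM = 5  # rank of the planted native representational geometry


def _default_weight_early(ability):
    return 0.15 + 0.25 * np.asarray(ability, dtype=float)


def _default_weight_late(ability):
    return 0.20 + 0.70 * np.asarray(ability, dtype=float)


@dataclass
class CohortConfig:
    """Study-scale configuration for synthetic cohorts.

    Defaults mirror the emulated study: 53 learners, 33 native listeners,
    6 training blocks of 40 trials, ~7.1% missing responses, and a
    desk-scale neural geometry of 10 named regions with 30 voxels each.
    """

    n_learners: int = 53
    n_natives: int = 33
    n_blocks: int = 6
    trials_per_block: int = 40
    n_voxels_per_roi: int = 30
    roi_names: tuple = DEFAULT_ROI_NAMES
    planted_rois: tuple = DEFAULT_PLANTED_ROIS
    ability: np.ndarray | None = None
    native_weight_early: callable = field(default=_default_weight_early)
    native_weight_late: callable = field(default=_default_weight_late)
    noise_sd: float = 0.4
    missing_fraction: float = 0.071
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks < 2:
            raise ValueError("n_blocks must be >= 2")
        if not set(self.planted_rois) <= set(self.roi_names):
            raise ValueError("planted ROIs must be a subset of roi_names")
        grid = np.linspace(0, 1, 11)
        w = np.asarray(self.native_weight_late(grid), dtype=float)
        if np.any(np.diff(w) < -1e-12):
            raise ValueError("native_weight_late must be non-decreasing in ability")


@dataclass
class GroundTruth:
    """Latent quantities the generator planted, for recovery tests."""

    ability: np.ndarray
    curve_params: np.ndarray  # (n_learners, 2): power-law (a, b)
    planted_rois: tuple
    native_geometry: RDM
    latent_dim: int = LATENT_DIM


@dataclass
class CohortPatterns:
    """Item-by-voxel activation patterns for a whole cohort.

    Keyed by ``(group, subject, roi, phase)`` with group in
    {"learner", "native"}; learners carry phases {"early", "late"},
    natives a single "whole" phase.  Item order is shared by construction.
    """

    data: dict
    item_labels: tuple
    roi_names: tuple

    def get(self, group: str, subject: int, roi: str, phase: str) -> np.ndarray:
        return self.data[(group, subject, roi, phase)]

    def subjects(self, group: str):
        return sorted({k[1] for k in self.data if k[0] == group})


def make_stimulus_catalog(seed: int = 0) -> pd.DataFrame:
    """Build the 40-token stimulus catalog.

    One token per (talker, tone, syllable) cell; F0 height and slope are
    the tone archetype plus a per-talker register offset and a small
    per-token jitter.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    rows = []
    for talker in (1, 2):
        for tone in TONES:
            for syll in SYLLABLES:
                h, s = TONE_ARCHETYPES[tone]
                rows.append(
                    {
                        "token_id": f"{syll}{tone[1]}_t{talker}",
                        "talker": talker,
                        "tone": tone,
                        "syllable": syll,
                        "f0_height": h
                        + _TALKER_F0_OFFSET[talker]
                        + rng.normal(0.0, 4.0),
                        "f0_slope": s + rng.normal(0.0, 4.0),
                    }
                )
    cat = pd.DataFrame(rows)
    assert (cat["f0_height"] > 0).all()
    return cat


def item_labels(catalog: pd.DataFrame) -> tuple:
    """The 20 talker-collapsed (tone, syllable) item labels, in the fixed
    analysis order (tone-major, syllable-minor): bu1, di1, ..., mi4."""
    items = []
    for tone in TONES:
        for syll in SYLLABLES:
            items.append(f"{syll}{tone[1]}")
    present = {f"{r.syllable}{r.tone[1]}" for r in catalog.itertuples()}
    if set(items) != present:
        raise ValueError("catalog does not contain the full 4x5 item grid")
    return tuple(items)


def item_pitch_features(catalog: pd.DataFrame) -> pd.DataFrame:
    """Per-item (talker-averaged) mean F0 height and slope."""
    items = item_labels(catalog)
    cat = catalog.assign(item=catalog["syllable"] + catalog["tone"].str[1])
    feats = cat.groupby("item")[["f0_height", "f0_slope"]].mean()
    return feats.loc[list(items)]


def model_rdms(catalog: pd.DataFrame) -> dict:
    """The five stimulus model RDMs over the 20 items.

    CAT and Syllable are binary same/different matrices; F0height and
    F0slope are normalized absolute acoustic distances; MD is the
    Euclidean distance in the min-max-normalized (height, slope) plane,
    then normalized to [0, 1].
    """
    items = item_labels(catalog)
    feats = item_pitch_features(catalog)
    tone_of = {it: "T" + it[-1] for it in items}
    syll_of = {it: it[:-1] for it in items}
    height = {it: feats.loc[it, "f0_height"] for it in items}
    slope = {it: feats.loc[it, "f0_slope"] for it in items}
    md = {it: (feats.loc[it, "f0_height"], feats.loc[it, "f0_slope"]) for it in items}
    return {
        "CAT": build_categorical_rdm(tone_of, kind="CAT"),
        "Syllable": build_categorical_rdm(syll_of, kind="Syllable"),
        "F0height": normalize_rdm(
            build_feature_rdm(height, "absolute-difference", kind="F0height"),
            anchor_zero=True,
        ),
        "F0slope": normalize_rdm(
            build_feature_rdm(slope, "absolute-difference", kind="F0slope"),
            anchor_zero=True,
        ),
        "MD": normalize_rdm(
            build_feature_rdm(md, "euclidean", normalize_dims=True, kind="MD"),
            anchor_zero=True,
        ),
    }


def _draw_ability(config: CohortConfig) -> np.ndarray:
    if config.ability is not None:
        ability = np.asarray(config.ability, dtype=float)
        if ability.shape != (config.n_learners,):
            raise ValueError("ability must have one value per learner")
        if np.any((ability < 0) | (ability > 1)):
            raise ValueError("ability values must lie in [0, 1]")
        return ability
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    return rng.uniform(0.0, 1.0, size=config.n_learners)


def ability_to_curve(ability) -> np.ndarray:
    """Linear ability -> power-law (a, b) map.

    ``a = 0.10 + 0.20*u`` and ``b = 0.15 + 0.55*u`` span first-block
    accuracies near chance and late-phase accuracies from ~0.15 up to
    ceiling, matching the spread of observed learning curves.
    """
    u = np.asarray(ability, dtype=float)
    return np.column_stack([0.10 + 0.20 * u, 0.15 + 0.55 * u])


def _tone_confusion_probs(catalog: pd.DataFrame, tau: float = 0.35) -> dict:
    """P(response tone | true tone, error) from normalized pitch distances."""
    feats = item_pitch_features(catalog)
    tone_xy = {}
    for tone in TONES:
        rows = feats[[i.endswith(tone[1]) for i in feats.index]]
        tone_xy[tone] = rows.mean().to_numpy()
    xy = np.array([tone_xy[t] for t in TONES])
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    xy = (xy - lo) / np.where(hi > lo, hi - lo, 1.0)
    probs = {}
    for i, tone in enumerate(TONES):
        d = np.sqrt(((xy - xy[i]) ** 2).sum(axis=1))
        w = np.exp(-d / tau)
        w[i] = 0.0  # error responses exclude the correct tone
        probs[tone] = w / w.sum()
    return probs


def _hand_map(learner_index: int) -> dict:
    """Counterbalanced category-to-response-hand map."""
    if learner_index % 2 == 0:
        return {"T1": "left", "T2": "left", "T3": "right", "T4": "right"}
    return {"T1": "right", "T2": "right", "T3": "left", "T4": "left"}


def simulate_behavior(config: CohortConfig, catalog: pd.DataFrame):
    """Simulate per-learner trial tables.

    Returns ``(table, ground_truth)`` where ``table`` is a long DataFrame
    with one row per (learner, block, trial): token identity, response tone
    (NA when missing), correctness, feedback shown, and response hand.
    """
    if config.trials_per_block != len(catalog):
        raise ValueError("trials_per_block must equal the catalog token count")
    ability = _draw_ability(config)
    params = ability_to_curve(ability)
    confusion = _tone_confusion_probs(catalog)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    tokens = catalog.reset_index(drop=True)
    rows = []
    for learner in range(config.n_learners):
        a, b = params[learner]
        hands = _hand_map(learner)
        for block in range(1, config.n_blocks + 1):
            p_correct = float(np.clip(a * block**b, 0.0, 1.0))
            order = rng.permutation(len(tokens))
            for trial, tok_idx in enumerate(order, start=1):
                tok = tokens.iloc[tok_idx]
                missing = rng.random() < config.missing_fraction
                if missing:
                    response, correct, feedback, hand = pd.NA, False, "missing", pd.NA
                else:
                    correct = bool(rng.random() < p_correct)
                    if correct:
                        response = tok.tone
                    else:
                        response = rng.choice(TONES, p=confusion[tok.tone])
                    feedback = "correct" if correct else "incorrect"
                    hand = hands[response]
                rows.append(
                    (
                        learner,
                        block,
                        trial,
                        tok.token_id,
                        int(tok.talker),
                        tok.tone,
                        tok.syllable,
                        response,
                        correct,
                        feedback,
                        missing,
                        hand,
                    )
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "learner",
            "block",
            "trial",
            "token_id",
            "talker",
            "tone",
            "syllable",
            "response",
            "correct",
            "feedback",
            "missing",
            "hand",
        ],
    )
    truth = GroundTruth(
        ability=ability,
        curve_params=params,
        planted_rois=tuple(config.planted_rois),
        native_geometry=_native_geometry(config, catalog),
    )
    return table, truth


def _latent_coordinates(config: CohortConfig, catalog: pd.DataFrame) -> np.ndarray:
    """20 x LATENT_DIM item coordinates of the shared native geometry."""
    n_items = len(item_labels(catalog))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    raw = rng.normal(size=(n_items, LATENT_DIM))
    q, _ = np.linalg.qr(raw - raw.mean(axis=0))
    scales = np.array([3.0, 2.5, 2.0, 1.5, 1.0])
    return q * scales


def _native_geometry(config: CohortConfig, catalog: pd.DataFrame) -> RDM:
    z = _latent_coordinates(config, catalog)
    diff = z[:, None, :] - z[None, :, :]
    values = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(values, 0.0)
    return RDM(item_labels(catalog), values, kind="native-neural")


def _syllable_coordinates(catalog: pd.DataFrame) -> np.ndarray:
    items = item_labels(catalog)
    onehot = np.zeros((len(items), len(SYLLABLES)))
    for i, it in enumerate(items):
        onehot[i, SYLLABLES.index(it[:-1])] = 1.0
    return 2.0 * (onehot - onehot.mean(axis=0))


def _orthonormal_rows(rng, k: int, n_voxels: int) -> np.ndarray:
    """k x n_voxels matrix with orthonormal rows (distance-preserving)."""
    if n_voxels < k:
        import warnings

        warnings.warn("fewer voxels than latent dimensions; geometry degraded")
        return rng.normal(size=(k, n_voxels)) / np.sqrt(n_voxels)
    q, _ = np.linalg.qr(rng.normal(size=(n_voxels, k)))
    return q.T


def simulate_patterns(config: CohortConfig, catalog: pd.DataFrame):
    """Simulate item-by-voxel activation patterns for the whole cohort.

    Learner patterns in each region and phase are
    ``w * native-geometry embedding + (1 - w) * syllable embedding + noise``
    with ``w`` given by the phase weight function of ability in planted
    regions and ability-independent elsewhere.  Native listeners carry the
    pure native geometry plus noise.  Embeddings use orthonormal voxel
    bases, so Euclidean item distances survive exactly at zero noise.
    """
    ability = _draw_ability(config)
    items = item_labels(catalog)
    z = _latent_coordinates(config, catalog)
    s = _syllable_coordinates(catalog)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 19]))
    v = config.n_voxels_per_roi
    data = {}
    w_early_planted = np.asarray(config.native_weight_early(ability), dtype=float)
    w_late_planted = np.asarray(config.native_weight_late(ability), dtype=float)
    for roi in config.roi_names:
        planted = roi in config.planted_rois
        # ability-independent weights for non-planted regions
        w_flat = 0.30 + 0.10 * rng.uniform(size=config.n_learners)
        for learner in range(config.n_learners):
            p_z = _orthonormal_rows(rng, z.shape[1], v)
            p_s = _orthonormal_rows(rng, s.shape[1], v)
            for phase, w_planted in (
                ("early", w_early_planted),
                ("late", w_late_planted),
            ):
                w = float(w_planted[learner]) if planted else float(w_flat[learner])
                signal = w * (z @ p_z) + (1.0 - w) * (s @ p_s)
                noise = config.noise_sd * rng.normal(size=(len(items), v))
                data[("learner", learner, roi, phase)] = signal + noise
        for native in range(config.n_natives):
            p_z = _orthonormal_rows(rng, z.shape[1], v)
            noise = config.noise_sd * rng.normal(size=(len(items), v))
            data[("native", native, roi, "whole")] = z @ p_z + noise
    truth = GroundTruth(
        ability=ability,
        curve_params=ability_to_curve(ability),
        planted_rois=tuple(config.planted_rois),
        native_geometry=_native_geometry(config, catalog),
    )
    patterns = CohortPatterns(
        data=data, item_labels=items, roi_names=tuple(config.roi_names)
    )
    return patterns, truth


def simulate_feedback_patterns(
    config: CohortConfig, behavior: pd.DataFrame, phases=("early", "late")
):
    """Feedback-locked trial patterns whose decodability tracks ability.

    Returns a dict keyed ``(learner, roi, phase)`` holding
    ``(patterns, labels, blocks)``: non-missing feedback trials by voxels,
    boolean correct-feedback labels, and block indices.  Class means are
    separated along a random direction; the separation grows with ability
    in planted regions during the late phase.
    """
    ability = _draw_ability(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    half = config.n_blocks // 2
    block_sets = {
        "early": set(range(1, half + 1)),
        "late": set(range(half + 1, config.n_blocks + 1)),
    }
    out = {}
    v = config.n_voxels_per_roi
    for roi in config.roi_names:
        planted = roi in config.planted_rois
        for learner in range(config.n_learners):
            direction = rng.normal(size=v)
            direction /= np.linalg.norm(direction)
            sub = behavior[(behavior["learner"] == learner) & (~behavior["missing"])]
            for phase in phases:
                rows = sub[sub["block"].isin(block_sets[phase])]
                labels = rows["correct"].to_numpy(dtype=bool)
                blocks = rows["block"].to_numpy(dtype=int)
                if planted and phase == "late":
                    delta = 0.3 + 2.2 * ability[learner]
                elif planted:
                    delta = 0.3 + 0.8 * ability[learner]
                else:
                    delta = 0.8
                signs = np.where(labels, 0.5, -0.5) * delta
                patterns = signs[:, None] * direction[None, :] + rng.normal(
                    size=(len(labels), v)
                )
                out[(learner, roi, phase)] = (patterns, labels, blocks)
    return out


def enumerate_lss_models(n_blocks: int, trials_per_block: int, event_types):
    """Enumerate the least-squares-single (LSS) design: one subject-level
    GLM per (trial, event type).

    Each descriptor names its regressor of interest and the shared nuisance
    regressors (all other events, six head-movement parameters, and the
    session mean).  The training design (6 blocks x 40 trials x
    {sound, feedback}) yields 480 models; a five-block sound-only session
    yields 200.
    """
    event_types = list(event_types)
    if n_blocks <= 0 or trials_per_block <= 0:
        raise ValueError("counts must be positive")
    if not event_types:
        raise ValueError("event_types must not be empty")
    models = []
    for block in range(1, n_blocks + 1):
        for trial in range(1, trials_per_block + 1):
            for event in event_types:
                models.append(
                    {
                        "block": block,
                        "trial": trial,
                        "event_type": event,
                        "regressor_of_interest": f"b{block}_t{trial}_{event}",
                        "nuisance_regressors": (
                            "other events",
                            "head movement x6",
                            "session mean",
                        ),
                    }
                )
    return models


def simulate_volume(
    shape,
    signal_region,
    catalog: pd.DataFrame,
    seed: int = 0,
    signal_scale: float = 1.5,
    noise_sd: float = 1.0,
):
    """Simulate a trial-averaged item-map stack for searchlight tests.

    ``signal_region`` is a boolean array of ``shape`` (or an iterable of
    voxel index triples) whose voxels carry tone-category item structure;
    all other voxels are pure noise.  Returns ``(stack, mask)`` with
    ``stack`` of shape ``(20, *shape)`` and an all-true brain mask.
    """
    shape = tuple(int(d) for d in shape)
    region = np.zeros(shape, dtype=bool)
    if isinstance(signal_region, np.ndarray) and signal_region.dtype == bool:
        if signal_region.shape != shape:
            raise ValueError("signal_region mask shape mismatch")
        region = signal_region
    else:
        for idx in signal_region:
            if any(i < 0 or i >= d for i, d in zip(idx, shape)):
                raise ValueError("signal_region voxel outside volume")
            region[tuple(idx)] = True
    items = item_labels(catalog)
    tone_idx = np.array([int(it[-1]) - 1 for it in items])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 29]))
    stack = noise_sd * rng.normal(size=(len(items),) + shape)
    n_sig = int(region.sum())
    if n_sig:
        loadings = rng.normal(size=(4, n_sig))  # tone-level voxel loadings
        stack[:, region] += signal_scale * loadings[tone_idx, :]
    mask = np.ones(shape, dtype=bool)
    return stack, mask
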
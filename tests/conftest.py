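import numpy as np
import pandas as pd
import pytest

from tonelearn.simulate import (
    TONES,
    CohortConfig,
    item_labels,
    make_stimulus_catalog,
    simulate_behavior,
    simulate_patterns,
)


@pytest.fixture(scope="session")
def catalog():
    return make_stimulus_catalog(seed=0)


@pytest.fixture(scope="session")
def items(catalog):
    return item_labels(catalog)


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(
        n_learners=12,
        n_natives=4,
        n_voxels_per_roi=25,
        roi_names=("L.STG", "R.PreCG", "L.IPL", "R.AG"),
        planted_rois=("L.STG", "R.PreCG"),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config, catalog):
    table, truth = simulate_behavior(small_config, catalog)
    patterns, _ = simulate_patterns(small_config, catalog)
    return table, patterns, truth


def responder_table(catalog, respond, n_blocks=6, learner=0, missing=None):
    """Build a trial table from a deterministic response rule.

    ``respond(block, row)`` returns a tone string; ``missing(block, row)``
    optionally flags no-response trials.
    """
    rows = []
    for block in range(1, n_blocks + 1):
        for trial, row in enumerate(catalog.itertuples(), start=1):
            is_missing = bool(missing and missing(block, row))
            resp = None if is_missing else respond(block, row)
            correct = (not is_missing) and resp == row.tone
            rows.append(
                {
                    "learner": learner,
                    "block": block,
                    "trial": trial,
                    "token_id": row.token_id,
                    "talker": row.talker,
                    "tone": row.tone,
                    "syllable": row.syllable,
                    "response": pd.NA if is_missing else resp,
                    "correct": correct,
                    "feedback": "missing"
                    if is_missing
                    else ("correct" if correct else "incorrect"),
                    "missing": is_missing,
                    "hand": pd.NA if is_missing else ("left" if resp in ("T1", "T2") else "right"),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def perfect_responder(catalog):
    return responder_table(catalog, lambda block, row: row.tone)


def random_rdm(items, rng, kind="neural"):
    from tonelearn.rdm import RDM

    m = len(items)
    vals = rng.uniform(0.1, 1.0, size=(m, m))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    return RDM(tuple(items), vals, kind=kind)
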
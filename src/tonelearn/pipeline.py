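"""End-to-end synthetic-study pipeline.

One call simulates a cohort and pushes it through every analysis stage:
behavioral learning curves and bRSA, IS-NRS (early/late, optional PC
sweep), learning-success prediction with permutation/bootstrap inference,
feedback-valence decoding, and a small searchlight demonstration.  All
outputs are written as TSV/JSON next to a run manifest that records the
configuration, seeds, and per-stage wall-clock so a run can be replayed
identically.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import feedback as fb
from . import io as tio
from . import isnrs as nrs
from . import predict as prd
from . import searchlight as sl
from .simulate import (
    CohortConfig,
    make_stimulus_catalog,
    model_rdms,
    simulate_behavior,
    simulate_feedback_patterns,
    simulate_patterns,
    simulate_volume,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    out_dir: str = "tonelearn_run"
    run_brsa: bool = True
    run_isnrs: bool = True
    run_dimensionality: bool = False
    run_predict: bool = True
    run_feedback: bool = True
    run_searchlight: bool = False
    dimensionality_ks: tuple = (1, 2, 3, 5, 8, 12)
    predict_config: prd.PredictConfig = field(default_factory=prd.PredictConfig)
    feedback_repeats: int = 10
    seed: int = 0


def _stage(manifest, name, t0, outputs):
    manifest["stages"][name] = {
        "seconds": round(time.perf_counter() - t0, 3),
        "outputs": [str(p) for p in outputs],
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic-study analysis; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_cfg = config.cohort
    manifest = {
        "seed": config.seed,
        "cohort_config": {
            k: v
            for k, v in asdict(cohort_cfg).items()
            if not callable(v) and k != "ability"
        },
        "stages": {},
    }

    t0 = time.perf_counter()
    catalog = make_stimulus_catalog(cohort_cfg.seed)
    table, truth = simulate_behavior(cohort_cfg, catalog)
    patterns, _ = simulate_patterns(cohort_cfg, catalog)
    files = [
        tio.write_catalog(catalog, out / "catalog.tsv"),
        tio.write_behavior(table, out / "behavior.tsv"),
        tio.write_json(
            {
                "ability": truth.ability,
                "curve_params": truth.curve_params,
                "planted_rois": list(truth.planted_rois),
            },
            out / "ground_truth.json",
        ),
    ]
    _stage(manifest, "simulate", t0, files)

    models = model_rdms(catalog)

    t0 = time.perf_counter()
    fits = []
    for learner in sorted(table["learner"].unique()):
        accs = beh.block_accuracies(table, learner)
        fit = beh.fit_learning_curve(accs, "power")
        fits.append(
            {
                "learner": learner,
                "a": fit.params[0],
                "b": fit.params[1],
                "gof_rms": fit.gof_rms,
                "learning_speed": fit.learning_speed,
                "learning_outcome": fit.learning_outcome,
                "block1_accuracy": accs[0],
            }
        )
    fits = pd.DataFrame(fits)
    files = [out / "learning_fits.tsv"]
    fits.to_csv(files[0], sep="\t", index=False)
    if config.run_brsa:
        brsa_table = beh.brsa(table, models, catalog)
        files.append(out / "brsa.tsv")
        brsa_table.to_csv(files[-1], sep="\t", index=False)
    _stage(manifest, "behavior", t0, files)

    isnrs_by_phase = {}
    if config.run_isnrs:
        t0 = time.perf_counter()
        files = []
        for phase in ("early", "late"):
            mat = nrs.isnrs_matrix(patterns, phase)
            isnrs_by_phase[phase] = mat
            files.append(tio.write_isnrs_long(mat, out / f"isnrs_{phase}.tsv"))
        split = nrs.median_split_compare(
            isnrs_by_phase["late"], fits.set_index("learner")["learning_outcome"]
        )
        files.append(out / "median_split_late.tsv")
        split.to_csv(files[-1], sep="\t", index=False)
        _stage(manifest, "isnrs", t0, files)

    if config.run_predict and isnrs_by_phase:
        t0 = time.perf_counter()
        files = []
        summary = {}
        target = fits["learning_outcome"].to_numpy()
        covariate = fits["block1_accuracy"].to_numpy()
        for phase, mat in isnrs_by_phase.items():
            res = prd.predict_learning(
                mat.values, target, covariate, config.predict_config
            )
            summary[phase] = {
                "power": res.power,
                "p": res.p_value,
                "bootstrap_median": float(np.median(res.bootstrap_powers)),
                "significant_rois": res.region_table.loc[
                    res.region_table["significant"], "roi"
                ].tolist(),
            }
            files.append(out / f"prediction_regions_{phase}.tsv")
            res.region_table.to_csv(files[-1], sep="\t", index=False)
        files.append(tio.write_json(summary, out / "prediction_summary.json"))
        _stage(manifest, "predict", t0, files)

    if config.run_dimensionality and isnrs_by_phase:
        t0 = time.perf_counter()
        by_k = {
            k: nrs.isnrs_matrix(patterns, "late", k=k).values
            for k in config.dimensionality_ks
        }
        curve = prd.dimensionality_curve(
            by_k,
            fits["learning_outcome"].to_numpy(),
            fits["block1_accuracy"].to_numpy(),
            config.predict_config,
        )
        f = out / "dimensionality_curve.tsv"
        curve.to_csv(f, sep="\t", index=False)
        _stage(manifest, "dimensionality", t0, [f])

    if config.run_feedback:
        t0 = time.perf_counter()
        fb_patterns = simulate_feedback_patterns(cohort_cfg, table)
        excluded = fb.exclude_perfect_block_learners(table)
        results = fb.decode_cohort(
            fb_patterns,
            n_repeats=config.feedback_repeats,
            seed=config.seed,
            exclude=excluded,
        )
        f = out / "feedback_decoding.tsv"
        results.to_csv(f, sep="\t", index=False)
        _stage(manifest, "feedback", t0, [f])
        manifest["stages"]["feedback"]["excluded_learners"] = excluded

    if config.run_searchlight:
        t0 = time.perf_counter()
        shape = (12, 12, 12)
        blob = np.zeros(shape, dtype=bool)
        blob[4:8, 4:8, 4:8] = True
        stack, mask = simulate_volume(shape, blob, catalog, seed=config.seed)
        smap = sl.searchlight_rsa(
            stack, mask, models["CAT"], patterns.item_labels, radius=2.0, min_voxels=5
        )
        f = out / "searchlight_demo.nii.gz"
        tio.write_nifti_stack(smap.values[None], f)
        _stage(manifest, "searchlight", t0, [f])

    tio.write_json(manifest, out / "manifest.json")
    return manifest
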
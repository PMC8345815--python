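"""File I/O: TSV schemas, labelled RDM tables, and NIfTI volumes."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .rdm import RDM
from .simulate import TONES

__all__ = [
    "write_catalog",
    "read_catalog",
    "write_behavior",
    "read_behavior",
    "write_rdm",
    "read_rdm",
    "write_isnrs_long",
    "write_nifti_stack",
    "read_nifti_stack",
    "write_json",
]

BEHAVIOR_COLUMNS = [
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
]


def write_catalog(catalog: pd.DataFrame, path) -> Path:
    path = Path(path)
    catalog.to_csv(path, sep="\t", index=False)
    return path


def read_catalog(path) -> pd.DataFrame:
    cat = pd.read_csv(path, sep="\t")
    bad = ~cat["tone"].isin(TONES)
    if bad.any():
        raise ValueError(f"unknown tone label at row(s) {list(cat.index[bad])}")
    return cat


def write_behavior(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_behavior(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing_cols = set(BEHAVIOR_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ValueError(f"behavior TSV missing columns: {sorted(missing_cols)}")
    bad = ~table["tone"].isin(TONES)
    if bad.any():
        raise ValueError(f"unknown tone label at row(s) {list(table.index[bad])}")
    responded = table["response"].notna()
    bad_resp = responded & ~table["response"].isin(TONES)
    if bad_resp.any():
        raise ValueError(
            f"unknown response label at row(s) {list(table.index[bad_resp])}"
        )
    table["missing"] = table["missing"].astype(bool)
    table["correct"] = table["correct"].astype(bool)
    return table


def write_rdm(rdm: RDM, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(rdm.values, index=rdm.labels, columns=rdm.labels)
    df.to_csv(path)
    return path


def read_rdm(path, kind: str = "neural") -> RDM:
    df = pd.read_csv(path, index_col=0)
    return RDM(tuple(df.index), df.to_numpy(dtype=float), kind=kind)


def write_isnrs_long(isnrs, path) -> Path:
    """Serialize an IsnrsMatrix as a long (learner, roi, phase, k, isnrs) TSV."""
    path = Path(path)
    long = isnrs.values.reset_index(names="learner").melt(
        id_vars="learner", var_name="roi", value_name="isnrs"
    )
    long["phase"] = isnrs.phase
    long["k"] = isnrs.k if isnrs.k is not None else "full"
    long.to_csv(path, sep="\t", index=False)
    return path


def write_nifti_stack(stack: np.ndarray, path, affine=None) -> Path:
    import nibabel as nib

    path = Path(path)
    affine = np.eye(4) if affine is None else affine
    data = np.moveaxis(np.asarray(stack, dtype=np.float32), 0, -1)
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def read_nifti_stack(path):
    import nibabel as nib

    img = nib.load(str(path))
    return np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0), img.affine


def write_json(obj, path) -> Path:
    path = Path(path)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=_default) + "\n")
    return path
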
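"""Whole-volume searchlight representational similarity mapping.

At every in-mask voxel a sphere (default radius 3 voxels) collects the
surrounding in-mask voxels' item patterns, computes a neural RDM
(correlation distance), correlates it with a model RDM via Spearman
correlation, and writes the Fisher z-transformed value back to the sphere
center.  Per-subject z-maps can be combined with a voxelwise one-sample
t-test against zero, optionally Benjamini-Hochberg thresholded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .rdm import RDM, fisher_z, pattern_rdm, spearman_rdm

__all__ = ["SearchlightMap", "sphere_offsets", "searchlight_rsa", "group_map"]


@dataclass
class SearchlightMap:
    values: np.ndarray  # per-voxel Fisher z; NaN outside mask / skipped
    model: str
    radius: float


def sphere_offsets(radius: float, voxel_size=None) -> np.ndarray:
    """Integer voxel offsets within a Euclidean ball of ``radius``.

    Includes the center; membership uses squared norm <= radius**2.
    Anisotropic voxel sizes can be passed to scale each axis in millimetres
    before the radius test.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    scale = np.ones(3) if voxel_size is None else np.asarray(voxel_size, dtype=float)
    r_vox = np.floor(radius / scale.min()) if scale.min() > 0 else 0
    lim = int(r_vox)
    offs = []
    for dx in range(-lim, lim + 1):
        for dy in range(-lim, lim + 1):
            for dz in range(-lim, lim + 1):
                d2 = (dx * scale[0]) ** 2 + (dy * scale[1]) ** 2 + (dz * scale[2]) ** 2
                if d2 <= radius**2 + 1e-9:
                    offs.append((dx, dy, dz))
    return np.array(offs, dtype=int)


def searchlight_rsa(
    item_maps: np.ndarray,
    mask: np.ndarray,
    model: RDM,
    labels,
    radius: float = 3.0,
    min_voxels: int = 10,
    voxel_size=None,
) -> SearchlightMap:
    """Model-RSA searchlight over a 4D item-map stack.

    ``item_maps`` has shape (items, X, Y, Z); ``mask`` marks in-brain
    voxels.  Centers whose sphere holds fewer than ``min_voxels`` in-mask
    voxels, or whose sphere RDM is degenerate, are left missing.
    """
    item_maps = np.asarray(item_maps, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if item_maps.shape[1:] != mask.shape:
        raise ValueError("item stack and mask grids differ")
    if not mask.any():
        raise ValueError("empty mask")
    offs = sphere_offsets(radius, voxel_size=voxel_size)
    shape = mask.shape
    out = np.full(shape, np.nan)
    centers = np.argwhere(mask)
    for cx, cy, cz in centers:
        vox = offs + (cx, cy, cz)
        ok = np.all((vox >= 0) & (vox < shape), axis=1)
        vox = vox[ok]
        in_mask = mask[vox[:, 0], vox[:, 1], vox[:, 2]]
        vox = vox[in_mask]
        if len(vox) < min_voxels:
            continue
        patterns = item_maps[:, vox[:, 0], vox[:, 1], vox[:, 2]]
        try:
            nrdm = pattern_rdm(patterns, labels, metric="correlation")
            rho = spearman_rdm(nrdm, model).rho
            out[cx, cy, cz] = fisher_z(np.clip(rho, -0.999999, 0.999999))
        except ValueError:
            warnings.warn(f"degenerate sphere RDM at center {(cx, cy, cz)}")
    return SearchlightMap(values=out, model=model.kind, radius=float(radius))


def group_map(maps, fdr_q: float | None = None):
    """Voxelwise one-sample t-test of subject z-maps against zero.

    Returns ``(t_map, p_map[, significance_mask])``; voxels missing in any
    subject are left NaN.  With ``fdr_q`` set, a Benjamini-Hochberg mask
    over the defined voxels is appended.
    """
    stacks = np.stack([m.values if isinstance(m, SearchlightMap) else m for m in maps])
    if stacks.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    valid = np.all(np.isfinite(stacks), axis=0)
    t_map = np.full(stacks.shape[1:], np.nan)
    p_map = np.full(stacks.shape[1:], np.nan)
    data = stacks[:, valid]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_1samp(data, 0.0, axis=0)
    t_map[valid], p_map[valid] = t, p
    if fdr_q is None:
        return t_map, p_map
    sig = np.zeros(stacks.shape[1:], dtype=bool)
    finite_p = np.isfinite(p_map)
    if finite_p.any():
        reject, *_ = multipletests(p_map[finite_p], alpha=fdr_q, method="fdr_bh")
        sig[finite_p] = reject
    return t_map, p_map, sig
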
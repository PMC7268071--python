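"""Intrinsic-connectivity (IC) contrast maps.

The IC value of a voxel is the sum, over every other brain voxel, of the
Fisher-z-transformed Pearson correlation between the two time series. It
is a network-free measure of how strongly a voxel is connected to the rest
of the brain; negative correlations enter as negative z. Correlations are
clipped at ``clip`` in magnitude before atanh so degenerate (perfectly
correlated) series cannot produce infinities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["IccMap", "icc_map", "group_icc_stack"]


@dataclass
class IccMap:
    """Summed Fisher-z connectivity per voxel."""

    values: np.ndarray  # 3D
    n_voxels: int  # voxels entering each sum (incl. the seed itself)
    clip: float
    mask: np.ndarray = None  # voxels actually used (zero-variance removed)


def icc_map(
    bold: np.ndarray,
    mask: np.ndarray,
    clip: float = 0.9999,
    chunk: int | None = None,
    threshold: float | None = None,
) -> IccMap:
    """IC(v) = sum over u != v of atanh(clip(r_uv)).

    ``chunk`` bounds the number of seed voxels correlated at once; the
    result is independent of the chunk size. Voxels with zero temporal
    variance are excluded from the mask with a warning. ``threshold``
    optionally zeroes correlations with \\|r\\| below it before summation
    (off by default; the literal definition sums all correlations).
    """
    mask = np.asarray(mask, dtype=bool)
    if bold.shape[-1] < 4:
        raise ValueError("need at least 4 frames")
    X = bold[mask]  # V x T
    sd = X.std(axis=1)
    good = sd > 0
    if not good.all():
        warnings.warn(
            f"excluding {int((~good).sum())} zero-variance voxel(s) from "
            "the IC mask", stacklevel=2)
        coords = np.argwhere(mask)
        for i, j, k in coords[~good]:
            mask = mask.copy()
            mask[i, j, k] = False
        X = X[good]
    V = X.shape[0]
    if V < 2:
        raise ValueError("need at least 2 usable voxels in the mask")
    Xc = X - X.mean(axis=1, keepdims=True)
    Z = Xc / np.linalg.norm(Xc, axis=1, keepdims=True)

    self_term = np.arctanh(clip)  # r_vv = 1 clips to `clip`
    ic = np.empty(V)
    step = V if not chunk else int(chunk)
    for start in range(0, V, step):
        block = Z[start:start + step] @ Z.T  # b x V
        np.clip(block, -clip, clip, out=block)
        z = np.arctanh(block)
        if threshold is not None:
            z[np.abs(block) < threshold] = 0.0
        ic[start:start + step] = z.sum(axis=1) - self_term

    out = np.zeros(bold.shape[:3])
    out[mask] = ic
    return IccMap(values=out, n_voxels=V, clip=clip, mask=mask)


def group_icc_stack(
    maps: list,
    subject_ids: list,
    covariates: pd.DataFrame,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack per-subject IC maps aligned to the covariate table.

    ``maps`` may be IccMap objects or bare 3D arrays. The stack's last axis
    follows the order of ``covariates['subject_id']``; pairing by id means
    shuffled input order cannot misalign subjects and covariates.
    """
    arrays = {sid: (m.values if isinstance(m, IccMap) else np.asarray(m))
              for sid, m in zip(subject_ids, maps)}
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) != 1:
        raise ValueError(f"maps are on different grids: {shapes}")
    missing = [s for s in covariates["subject_id"] if s not in arrays]
    if missing:
        raise ValueError(f"no map for subject(s) {missing}")
    stack = np.stack([arrays[s] for s in covariates["subject_id"]], axis=-1)
    return stack, covariates.reset_index(drop=True)
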
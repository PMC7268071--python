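"""Per-subject fluctuation-amplitude and quantitative CBF maps.

The fluctuation-amplitude metric is the temporal variance of the separated
signal per voxel, with robust (MAD-based) rejection of outlying time
points. Absolute CBF in mL/100g/min is obtained from the mean label
difference via the single-compartment kinetic model for pCASL.
"""

from __future__ import annotations

import numpy as np

from .core import StatMap

__all__ = [
    "GkmParams",
    "variance_map",
    "roi_mean",
    "reject_outlier_volumes",
    "quantify_cbf",
    "cbf_variance_map",
]

from dataclasses import dataclass, field


@dataclass
class GkmParams:
    """Kinetic-model constants for pCASL quantification.

    labeling_duration (tau) and post_label_delay in s, blood T1 in s,
    labeling efficiency alpha in (0, 1], partition coefficient lambda in
    mL/g, plus the equilibrium magnetization map M0.
    """

    labeling_duration: float = 1.5
    post_label_delay: float = 1.0
    blood_t1: float = 1.65
    labeling_efficiency: float = 0.85
    partition_coefficient: float = 0.9
    m0: np.ndarray = field(default=None)

    def __post_init__(self):
        if not 0 < self.labeling_efficiency <= 1:
            raise ValueError("labeling efficiency must be in (0, 1]")
        if min(self.labeling_duration, self.post_label_delay,
               self.blood_t1) <= 0:
            raise ValueError("tau, PLD and blood T1 must be positive")


def variance_map(
    series: np.ndarray,
    mask: np.ndarray,
    outlier_k: float = 5.0,
    kind: str = "bold_var",
) -> StatMap:
    """Temporal variance per voxel with MAD-based outlier rejection.

    Time points farther than ``outlier_k`` * 1.4826 * MAD from the voxel
    median are discarded before computing the unbiased sample variance.
    ``outlier_k=inf`` disables rejection. Voxels outside the mask are 0;
    voxels with fewer than 3 surviving points are NaN.
    """
    if series.shape[-1] < 10:
        raise ValueError("need at least 10 frames for a variance map")
    x = series[mask]  # voxels x time
    if np.isfinite(outlier_k):
        med = np.median(x, axis=1, keepdims=True)
        mad = np.median(np.abs(x - med), axis=1, keepdims=True)
        keep = np.abs(x - med) <= outlier_k * 1.4826 * mad
        # all-equal series have MAD 0; points at the median survive
        keep |= x == med
    else:
        keep = np.ones_like(x, dtype=bool)
    n = keep.sum(axis=1)
    xk = np.where(keep, x, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = xk.sum(axis=1) / n
        var = ((xk - mean[:, None]) ** 2 * keep).sum(axis=1) / (n - 1)
    var[n < 3] = np.nan
    out = np.zeros(series.shape[:3])
    out[mask] = var
    return StatMap(out, kind=kind, units="signal^2")


def roi_mean(stat_map: StatMap, roi: np.ndarray) -> float:
    """Mean of the map over non-missing voxels of the ROI."""
    values = stat_map.values[roi.astype(bool)]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("ROI does not intersect the map (or is all missing)")
    return float(values.mean())


def _snr(g: np.ndarray) -> float:
    sd = g.std(ddof=1)
    return float(g.mean() / sd) if sd > 0 else np.inf


def reject_outlier_volumes(
    delta_m: np.ndarray,
    gm_mask: np.ndarray,
    mode: str = "default",
    min_gain: float = 0.01,
    max_removed_frac: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """SNR-greedy removal of outlier label-difference volumes.

    In ``optimize`` mode, frames whose exclusion most increases the
    temporal SNR (mean/SD) of the GM-mean difference signal are removed
    greedily, stopping when the relative gain falls below ``min_gain`` or
    ``max_removed_frac`` of frames have been dropped. ``default`` mode
    returns the input unchanged. Returns (reduced series, kept indices);
    the SNR after optimisation is never below the SNR before.
    """
    n = delta_m.shape[-1]
    if n < 10:
        raise ValueError("need at least 10 difference frames")
    kept = np.arange(n)
    if mode == "default":
        return delta_m, kept
    if mode != "optimize":
        raise ValueError(f"unknown mode {mode!r}")
    g = delta_m[gm_mask].mean(axis=0)
    max_removed = int(max_removed_frac * n)
    while len(kept) - 1 >= 3 and n - len(kept) < max_removed:
        snr = _snr(g[kept])
        best_gain, best_i = -np.inf, None
        for j in range(len(kept)):
            trial = np.delete(kept, j)
            gain = _snr(g[trial]) - snr
            if gain > best_gain:
                best_gain, best_i = gain, j
        if best_i is None or best_gain < min_gain * abs(snr):
            break
        kept = np.delete(kept, best_i)
    return delta_m[..., kept], kept


def quantify_cbf(mean_delta_m: np.ndarray, p: GkmParams) -> StatMap:
    """Absolute CBF (mL/100g/min) from the mean label difference.

    Single-compartment pCASL closed form (label fully arrived,
    PLD past the labeling bolus):

        f = 6000 * lambda * dM * exp(PLD/T1b)
            / (2 * alpha * T1b * M0 * (1 - exp(-tau/T1b)))

    Voxels with non-positive M0 are missing (NaN).
    """
    m0 = np.asarray(p.m0, dtype=float)
    if not np.nanmean(m0) > 0:
        raise ValueError("mean M0 must be positive")
    t1b = p.blood_t1
    denom = (2.0 * p.labeling_efficiency * t1b * m0
             * (1.0 - np.exp(-p.labeling_duration / t1b)))
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (6000.0 * p.partition_coefficient * mean_delta_m
             * np.exp(p.post_label_delay / t1b)) / denom
    f = np.where(m0 > 0, f, np.nan)
    return StatMap(f, kind="cbf_quant", units="mL/100g/min")


def delta_m_from_cbf(f: np.ndarray, p: GkmParams) -> np.ndarray:
    """Inverse of :func:`quantify_cbf`; used for round-trip validation."""
    t1b = p.blood_t1
    return (np.asarray(f, dtype=float)
            * 2.0 * p.labeling_efficiency * t1b * np.asarray(p.m0)
            * (1.0 - np.exp(-p.labeling_duration / t1b))
            / (6000.0 * p.partition_coefficient
               * np.exp(p.post_label_delay / t1b)))


def cbf_variance_map(
    cbf_signal: np.ndarray,
    gm_mask: np.ndarray,
    outlier_k: float = 5.0,
) -> StatMap:
    """Fluctuation amplitude of the CBF envelope, GM only.

    ASL difference signals in WM are too unreliable for fluctuation
    analysis, so the map is restricted to gray matter.
    """
    sm = variance_map(cbf_signal, gm_mask.astype(bool), outlier_k,
                      kind="cbf_var")
    return sm
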
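"""Shared in-memory containers for images, series and maps.

The analysis operates on plain NumPy arrays carried by small dataclasses;
covariate tables are pandas DataFrames with documented columns. On disk,
volumes are NIfTI-1 (via nibabel) and tables are CSV — see :mod:`pwvbold.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: frame-role convention: the first frame (after any discard of an even
#: number of frames) is a control frame, so control frames sit at even
#: indices and carry the +delta/2 half of the label difference.
CONTROL, TAG = "control", "tag"


def alternating_roles(n_frames: int, first: str = CONTROL) -> np.ndarray:
    """Strictly alternating tag/control labels of length ``n_frames``."""
    other = TAG if first == CONTROL else CONTROL
    roles = np.empty(n_frames, dtype=object)
    roles[0::2] = first
    roles[1::2] = other
    return roles


def role_signs(frame_role: np.ndarray) -> np.ndarray:
    """+1 for control frames, -1 for tag frames (surround-subtraction sign)."""
    return np.where(np.asarray(frame_role) == CONTROL, 1.0, -1.0)


@dataclass
class DualEchoSeries:
    """Interleaved tag/control dual-echo series for one subject.

    ``echo1`` is the short-echo (perfusion-sensitive) series and ``echo2``
    the long-echo (BOLD-sensitive) series, both shaped (x, y, z, frame).
    ``masks`` holds mutually exclusive GM/WM/CSF binary volumes on the same
    grid. Timing parameters are stored in seconds.
    """

    echo1: np.ndarray
    echo2: np.ndarray
    frame_role: np.ndarray
    tr: float = 4.0
    te_cbf: float = 10.0  # ms
    te_bold: float = 30.7  # ms
    labeling_duration: float = 1.5  # s
    post_label_delay: float = 1.0  # s
    masks: dict = field(default_factory=dict)
    truth_info: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.echo1.shape[-1]

    @property
    def dims(self) -> tuple:
        return self.echo1.shape[:3]

    def validate(self) -> None:
        if self.echo1.shape != self.echo2.shape:
            raise ValueError("echo1 and echo2 must share a grid and length")
        if len(self.frame_role) != self.n_frames:
            raise ValueError("frame_role length mismatch")
        roles = np.asarray(self.frame_role)
        if not np.all(roles[:-1] != roles[1:]):
            raise ValueError("frame_role must strictly alternate")
        tissues = [m for k, m in self.masks.items() if k in ("gm", "wm", "csf")]
        if tissues:
            overlap = np.sum(np.stack(tissues).astype(int), axis=0)
            if overlap.max() > 1:
                raise ValueError("GM/WM/CSF masks must be mutually exclusive")


@dataclass
class StatMap:
    """3D scalar map on the acquisition grid.

    ``kind`` is one of {bold_var, cbf_var, cbf_quant, icc, tstat, tfce,
    pcorr}; missing voxels are NaN, voxels outside the mask are zero.
    """

    values: np.ndarray
    kind: str
    units: str = "a.u."

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("StatMap values must be 3D")


@dataclass
class DenoisedSeries:
    """Separated BOLD / CBF time series for one subject.

    All arrays are (x, y, z, interior-frame); the first and last frame of
    the input are dropped by the surround stencils rather than padded.
    """

    bold: np.ndarray
    cbf_delta_m: np.ndarray
    cbf_signal: np.ndarray
    tr: float
    band: tuple = (0.001, 0.08)
    provenance: list = field(default_factory=list)
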
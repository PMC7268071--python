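"""File-format helpers: NIfTI-1 volumes, CSV tables, JSON sidecars."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import DualEchoSeries
from .pwv import FlowWaveform

__all__ = [
    "save_nifti", "load_nifti", "save_series", "load_series",
    "save_waveform_csv", "load_waveform_csv", "write_json", "read_json",
    "sha256_file",
]


def save_nifti(arr: np.ndarray, path, voxel_size=(3.44, 3.44, 6.0)) -> Path:
    path = Path(path)
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine)
    img.header.set_zooms(tuple(voxel_size) + ((1.0,) if arr.ndim == 4 else ()))
    nib.save(img, str(path))
    return path


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def save_series(s: DualEchoSeries, out_dir, stem: str,
                voxel_size=(3.44, 3.44, 6.0)) -> dict:
    """Write one subject's dual-echo series: two 4D NIfTIs + JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {
        "echo1": save_nifti(s.echo1, out_dir / f"{stem}_echo1.nii", voxel_size),
        "echo2": save_nifti(s.echo2, out_dir / f"{stem}_echo2.nii", voxel_size),
    }
    sidecar = {
        "frame_role": list(map(str, s.frame_role)),
        "tr": s.tr, "te_cbf": s.te_cbf, "te_bold": s.te_bold,
        "labeling_duration": s.labeling_duration,
        "post_label_delay": s.post_label_delay,
    }
    files["sidecar"] = write_json(sidecar, out_dir / f"{stem}_series.json")
    return files


def load_series(echo1_path, echo2_path, sidecar_path,
                masks: dict | None = None) -> DualEchoSeries:
    meta = read_json(sidecar_path)
    return DualEchoSeries(
        echo1=load_nifti(echo1_path),
        echo2=load_nifti(echo2_path),
        frame_role=np.asarray(meta["frame_role"], dtype=object),
        tr=meta["tr"], te_cbf=meta["te_cbf"], te_bold=meta["te_bold"],
        labeling_duration=meta["labeling_duration"],
        post_label_delay=meta["post_label_delay"],
        masks=masks or {},
    )


def save_waveform_csv(w: FlowWaveform, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_ms": w.time, "flow_ml_s": w.flow}).to_csv(
        path, index=False)
    return path


def load_waveform_csv(path, plane_label: str = "arch") -> FlowWaveform:
    df = pd.read_csv(path)
    return FlowWaveform(df["time_ms"].to_numpy(),
                        df["flow_ml_s"].to_numpy(), plane_label)


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_coerce))
    return path


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _coerce(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
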
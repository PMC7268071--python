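"""Configured, logged, resumable analysis pipeline.

Stage order: simulate -> pwv -> separate -> maps -> icc -> glm ->
vesselreg -> mediate. Each enabled stage records its outputs, checksums
and wall time in a run manifest; identical configuration and seeds give
identical checksums. The per-subject map stacks produced by ``maps`` and
``icc`` are cached on disk keyed by a configuration hash, so the
permutation stage (which dominates runtime) can be re-run without
re-simulating.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity, inference, metrics, signals, synthetic
from .errors import ConfigurationError, DependencyError
from .io import sha256_file, write_json
from .pwv import average_raters, estimate_pwv

log = logging.getLogger("pwvbold.pipeline")

ALL_STAGES = ("simulate", "pwv", "separate", "maps", "icc", "glm",
              "vesselreg", "mediate")

#: stage -> stages whose in-memory outputs it consumes
STAGE_DEPS = {
    "simulate": (),
    "pwv": ("simulate",),
    "separate": ("simulate",),
    "maps": ("separate",),
    "icc": ("separate",),
    "glm": ("maps",),
    "vesselreg": ("glm",),
    "mediate": ("maps", "glm"),
}


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the analysis protocol
    (discard 4 frames, 4 CompCor components, 0.001-0.08 Hz band, 6 mm
    FWHM, 10,000 permutations, 1,000 bootstrap iterations)."""

    out_dir: str = "pwvbold_out"
    seed: int = 0
    # cohort
    n_parent: int = 20
    n_offspring: int = 20
    dims: tuple = (12, 12, 6)
    n_frames: int = 100
    tr: float = 4.0
    path_length: float = 0.356
    waveform_noise_sd: float = 5.0
    # preprocessing
    discard: int = 4
    compcor_k: int = 4
    band: tuple = (0.001, 0.08)
    fwhm: float = 6.0
    voxel_size: tuple = (3.44, 3.44, 6.0)
    # maps
    outlier_k: float = 5.0
    gkm: dict = field(default_factory=lambda: {
        "blood_t1": 1.65, "labeling_efficiency": 0.85,
        "partition_coefficient": 0.9,
    })
    # connectivity
    icc_clip: float = 0.9999
    icc_chunk: int | None = None
    # inference
    n_perm: int = 10000
    n_boot: int = 1000
    direction: str = "negative"
    tfce: dict = field(default_factory=lambda: {
        "E": 0.5, "H": 2.0, "connectivity": 26, "n_steps": 100,
    })
    n_bins: int = 30
    glm_on_icc: bool = True
    stages: tuple = ALL_STAGES

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(raw: dict | None = None) -> PipelineConfig:
    """Fill defaults and reject contradictory settings."""
    raw = dict(raw or {})
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("dims", "band", "voxel_size", "stages"):
        if key in raw:
            raw[key] = tuple(raw[key])
    for key in ("gkm", "tfce"):
        if key in raw:
            base = PipelineConfig.__dataclass_fields__[key].default_factory()
            base.update(raw[key])
            raw[key] = base
    cfg = PipelineConfig(**raw)
    lo, hi = cfg.band
    nyquist = 1.0 / (2.0 * cfg.tr)
    if not 0 <= lo < hi:
        raise ConfigurationError(f"band must satisfy 0 <= lo < hi, got {cfg.band}")
    if hi >= nyquist:
        raise ConfigurationError(
            f"band upper edge {hi} Hz >= Nyquist {nyquist} Hz for TR={cfg.tr}")
    if cfg.discard % 2:
        raise ConfigurationError("discard count must be even")
    if cfg.n_frames % 2 or cfg.n_frames <= cfg.discard:
        raise ConfigurationError("n_frames must be even and exceed discard")
    if cfg.n_perm < 1 or cfg.n_boot < 1:
        raise ConfigurationError("n_perm and n_boot must be positive")
    unknown_stages = set(cfg.stages) - set(ALL_STAGES)
    if unknown_stages:
        raise ConfigurationError(f"unknown stages: {sorted(unknown_stages)}")
    return cfg


def _require(state: dict, stage: str, key: str, producer: str):
    if key not in state:
        raise DependencyError(stage, producer)
    return state[key]


def _stage_simulate(state, cfg, out):
    cohort = synthetic.generate_cohort(
        n_parent=cfg.n_parent, n_offspring=cfg.n_offspring, dims=cfg.dims,
        n_frames=cfg.n_frames, seed=cfg.seed, path_length=cfg.path_length,
        waveform_noise_sd=cfg.waveform_noise_sd,
    )
    state["cohort"] = cohort
    state["atlases"] = dict(cohort.atlases,
                            effect_roi=cohort.truth.effect_roi)
    files = [out / "covariates.csv"]
    cohort.covariates.to_csv(files[0], index=False)
    np.savez(out / "atlases.npz", **state["atlases"])
    files.append(out / "atlases.npz")
    truth = {k: v for k, v in asdict(cohort.truth).items()
             if not isinstance(v, np.ndarray)}
    files.append(write_json(truth, out / "ground_truth.json"))
    return files


def _stage_pwv(state, cfg, out):
    cohort = _require(state, "pwv", "cohort", "simulate")
    rows = []
    for sid, (w_arch, w_abd) in zip(cohort.covariates["subject_id"],
                                    cohort.waveforms):
        rater_a = estimate_pwv(w_arch, w_abd, cfg.path_length)
        rater_b = estimate_pwv(w_arch, w_abd, cfg.path_length,
                               baseline_ms=80.0)
        est = average_raters([rater_a, rater_b])
        rows.append({"subject_id": sid, "pwv": est.pwv,
                     "transit_time_ms": est.transit_time,
                     "rater_a": rater_a.pwv, "rater_b": rater_b.pwv})
    est_df = pd.DataFrame(rows)
    cov = cohort.covariates.merge(est_df[["subject_id", "pwv"]],
                                  on="subject_id")
    state["covariates"] = cov
    files = [out / "pwv_estimates.csv", out / "covariates_with_pwv.csv"]
    est_df.to_csv(files[0], index=False)
    cov.to_csv(files[1], index=False)
    return files


def _stage_separate(state, cfg, out):
    cohort = _require(state, "separate", "cohort", "simulate")
    state["denoised"] = [
        signals.separate(s, discard=cfg.discard, compcor_k=cfg.compcor_k,
                         band=cfg.band, fwhm=cfg.fwhm,
                         voxel_size=cfg.voxel_size)
        for s in cohort.series
    ]
    prov = state["denoised"][0].provenance if state["denoised"] else []
    return [write_json({"provenance": prov}, out / "separate_provenance.json")]


def _stage_maps(state, cfg, out):
    cohort = _require(state, "maps", "cohort", "simulate")
    den = _require(state, "maps", "denoised", "separate")
    gm = cohort.atlases["gm"]
    brain = cohort.atlases["brain"]
    bold_var, cbf_var, cbf_quant = [], [], []
    for s, d in zip(cohort.series, den):
        bold_var.append(metrics.variance_map(d.bold, brain, cfg.outlier_k).values)
        cbf_var.append(metrics.cbf_variance_map(d.cbf_signal, gm,
                                                cfg.outlier_k).values)
        dm, _ = metrics.reject_outlier_volumes(d.cbf_delta_m, gm)
        m0 = np.maximum(s.echo1.mean(axis=-1), 1e-6)
        p = metrics.GkmParams(labeling_duration=s.labeling_duration,
                              post_label_delay=s.post_label_delay,
                              m0=m0, **cfg.gkm)
        cbf_quant.append(metrics.quantify_cbf(dm.mean(axis=-1), p).values)
    state["bold_var"] = np.stack(bold_var, axis=-1)
    state["cbf_var"] = np.stack(cbf_var, axis=-1)
    state["cbf_quant"] = np.stack(cbf_quant, axis=-1)
    path = out / "map_stacks.npz"
    np.savez(path, bold_var=state["bold_var"], cbf_var=state["cbf_var"],
             cbf_quant=state["cbf_quant"])
    return [path]


def _stage_icc(state, cfg, out):
    cohort = _require(state, "icc", "cohort", "simulate")
    den = _require(state, "icc", "denoised", "separate")
    gm = cohort.atlases["gm"]
    maps = [connectivity.icc_map(d.bold, gm, clip=cfg.icc_clip,
                                 chunk=cfg.icc_chunk) for d in den]
    stack, _ = connectivity.group_icc_stack(
        maps, list(cohort.covariates["subject_id"]), cohort.covariates)
    state["icc"] = stack
    path = out / "icc_stack.npz"
    np.savez(path, icc=stack)
    return [path]


def _stage_glm(state, cfg, out):
    cov = _require(state, "glm", "covariates", "pwv")
    bold_var = _require(state, "glm", "bold_var", "maps")
    atlases = _require(state, "glm", "atlases", "simulate")
    mask = atlases["gm"].astype(bool)
    design = np.column_stack([np.ones(len(cov)), cov["pwv"], cov["age"]])
    contrast = np.array([0.0, 1.0, 0.0])
    files = []
    targets = {"bold_var": bold_var}
    if cfg.glm_on_icc:
        targets["icc"] = _require(state, "glm", "icc", "icc")
    for name, stack in targets.items():
        res = inference.permutation_correct(
            stack, design, contrast, n_perm=cfg.n_perm, seed=cfg.seed,
            direction=cfg.direction, mask=mask, tfce_opts=cfg.tfce)
        state[f"glm_{name}"] = res
        path = out / f"glm_{name}.npz"
        np.savez(path, t=res.tmap.values, tfce=res.tfce_map.values,
                 pcorr=res.pcorr_map.values, max_null=res.max_null)
        files.append(path)
    return files


def _stage_vesselreg(state, cfg, out):
    res = _require(state, "vesselreg", "glm_bold_var", "glm")
    atlases = _require(state, "vesselreg", "atlases", "simulate")
    sig = res.significant()
    record: dict = {"n_significant": int(sig.sum())}
    if sig.any():
        vp = atlases["vessel_prob"]
        try:
            fit = inference.vessel_bin_regression(res.tmap, vp, sig,
                                                 n_bins=cfg.n_bins)
            record.update(slope=fit["slope"], intercept=fit["intercept"])
            fit["bins"].to_csv(out / "vessel_bins.tsv", sep="\t", index=False)
        except inference.ModelError as exc:
            record["regression_error"] = str(exc)
        record["overlap_pct"] = inference.overlap_fraction(sig, vp > 0)
    state["vesselreg"] = record
    return [write_json(record, out / "vesselreg.json"),
            *( [out / "vessel_bins.tsv"] if "slope" in record else [] )]


def _stage_mediate(state, cfg, out):
    cov = _require(state, "mediate", "covariates", "pwv")
    bold_var = _require(state, "mediate", "bold_var", "maps")
    cbf_var = _require(state, "mediate", "cbf_var", "maps")
    atlases = _require(state, "mediate", "atlases", "simulate")
    glm_res = state.get("glm_bold_var")
    roi = None
    if glm_res is not None:
        sig = glm_res.significant() & atlases["gm"].astype(bool)
        if sig.any():
            roi = sig
    if roi is None:
        roi = atlases["effect_roi"].astype(bool)
    x = cov["pwv"].to_numpy(float)
    m = np.array([metrics.roi_mean(metrics.StatMap(cbf_var[..., i],
                                                   "cbf_var"), roi)
                  for i in range(cbf_var.shape[-1])])
    y = np.array([metrics.roi_mean(metrics.StatMap(bold_var[..., i],
                                                   "bold_var"), roi)
                  for i in range(bold_var.shape[-1])])
    res = inference.mediate(x, m, y, n_boot=cfg.n_boot, seed=cfg.seed)
    state["mediation"] = res
    record = {
        "a": res.a, "b": res.b, "c": res.c, "c_prime": res.c_prime,
        "indirect": res.indirect, "ci95": list(res.ci95),
        "p_boot": res.p_boot, "n_boot": res.n_boot,
        "roi_n_voxels": int(np.asarray(roi).sum()),
    }
    return [write_json(record, out / "mediation.json")]


_STAGE_FUNCS = {
    "simulate": _stage_simulate, "pwv": _stage_pwv,
    "separate": _stage_separate, "maps": _stage_maps, "icc": _stage_icc,
    "glm": _stage_glm, "vesselreg": _stage_vesselreg,
    "mediate": _stage_mediate,
}


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute the enabled stages in dependency order; return the manifest.

    With ``resume=True``, the cached ``maps``/``icc`` stacks and the
    covariate table are reloaded from ``out_dir`` when a previous manifest
    with an identical configuration hash exists, so downstream stages
    (permutation, mediation) can be re-run without re-simulation.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest = {"config_hash": chash, "stages": {}}
    state: dict = {}

    if resume:
        prev_path = out / "manifest.json"
        if prev_path.exists():
            prev = json.loads(prev_path.read_text())
            if prev.get("config_hash") == chash:
                _reload_cached(state, out)
                log.info("resume: reloaded cached stage outputs")

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        if resume and _cached_satisfies(state, stage):
            manifest["stages"][stage] = {"cached": True}
            log.info("stage %s: cached", stage)
            continue
        t0 = time.perf_counter()
        files = _STAGE_FUNCS[stage](state, config, out)
        manifest["stages"][stage] = {
            "outputs": [str(f) for f in files],
            "sha256": {Path(f).name: sha256_file(f) for f in files},
            "wall_time_s": round(time.perf_counter() - t0, 3),
        }
        log.info("stage %s: %d output(s) in %.2fs", stage, len(files),
                 manifest["stages"][stage]["wall_time_s"])
    resolved = asdict(config)
    write_json(resolved, out / "config_resolved.json")
    write_json(manifest, out / "manifest.json")
    return manifest


def _reload_cached(state: dict, out: Path) -> None:
    atl_path = out / "atlases.npz"
    if atl_path.exists():
        with np.load(atl_path) as z:
            state["atlases"] = {k: z[k] for k in z.files}
    maps_path = out / "map_stacks.npz"
    if maps_path.exists():
        with np.load(maps_path) as z:
            state.update({k: z[k] for k in z.files})
    icc_path = out / "icc_stack.npz"
    if icc_path.exists():
        with np.load(icc_path) as z:
            state["icc"] = z["icc"]
    cov_path = out / "covariates_with_pwv.csv"
    if cov_path.exists():
        state["covariates"] = pd.read_csv(cov_path)


def _cached_satisfies(state: dict, stage: str) -> bool:
    # a stage counts as cached when everything its downstream consumers
    # need from it (directly or indirectly) is already in memory
    provided = {
        "simulate": ("atlases", "covariates"),
        "pwv": ("covariates",),
        "separate": ("bold_var", "cbf_var", "icc"),
        "maps": ("bold_var", "cbf_var", "cbf_quant"),
        "icc": ("icc",),
    }
    keys = provided.get(stage)
    return bool(keys) and all(k in state for k in keys)
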
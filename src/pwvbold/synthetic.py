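"""Seeded synthetic cohorts: covariates, aortic waveforms, dual-echo pCASL.

The generator encodes the data-generating structure the downstream analysis
assumes, so that every stage — foot detection, signal separation, variance
mapping, group inference, mediation — can be exercised and validated without
access to the original cohort:

* Covariates follow the generative regression
  ``pwv = intercept + beta_age*age + beta_sbp*sbp + beta_height*height
  + sex_offset + noise``, i.e. exactly the fixed-effect structure of the
  PWV mixed model, with a random intercept per sex level.
* Flow waveforms at the aortic arch and abdominal aorta are the same
  analytic pulse (flat diastolic baseline + raised-cosine systolic
  upstroke) separated by the true transit delay ``path_length / pwv``,
  realised on the analytic waveform before sampling so sub-sample delays
  are exact.
* The dual-echo series per voxel v, echo e, frame i is

  ``s = M0(v,e) * (1 + beta(v)*b_i) + (-1)^i * (delta(v,e)/2) * (1 + gamma(v)*c_i) + eps``

  where ``b_i`` is a band-limited (0.01-0.08 Hz) BOLD-like process,
  ``c_i`` a slower CBF-fluctuation process, ``delta`` the perfusion label
  amplitude (larger at the short echo), and frame 0 is a control frame.
  Inside the designated effect ROI the amplitudes follow the mediation
  chain PWV -> gamma (slope ``a_path``) -> beta (slope ``b_path``), each
  with its own subject-level noise.

Identical seeds give bit-identical outputs everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import DualEchoSeries, alternating_roles
from .errors import ConfigurationError
from .pwv import FlowWaveform

__all__ = [
    "GroundTruth",
    "GROUP_TARGETS",
    "Cohort",
    "generate_covariates",
    "generate_flow_waveforms",
    "generate_pcasl_series",
    "generate_atlases",
    "generate_cohort",
    "default_effect_roi",
]

#: Generator targets for the two generations of the cohort design
#: (means +/- SD as printed for the study sample; female_frac is the
#: fraction of women). Ages of the two groups lie in disjoint ranges.
GROUP_TARGETS = {
    "parent": {
        "age": (55.0, 6.5), "age_range": (43.0, 67.0),
        "height": (169.7, 8.2),
        "sbp": (122.5, 13.2), "dbp": (67.5, 8.3),
        "heart_rate": (69.0, 11.3),
        "female_frac": 0.64,
    },
    "offspring": {
        "age": (25.4, 5.8), "age_range": (19.0, 39.0),
        "height": (171.3, 10.9),
        "sbp": (119.8, 14.8), "dbp": (65.8, 5.8),
        "heart_rate": (69.3, 8.5),
        "female_frac": 0.70,
    },
}


@dataclass
class GroundTruth:
    """All generator parameters, stored with the seed for reproducibility.

    ``intercept``/``beta_*`` define the PWV generative regression (m/s per
    unit covariate); ``a_path`` is the slope of the CBF-fluctuation
    amplitude gamma on PWV (per m/s) inside the effect ROI, ``b_path`` the
    slope of the BOLD amplitude beta on gamma. The defaults place the
    parent/offspring PWV means near 5.7 and 4.2 m/s.
    """

    intercept: float = 1.70
    beta_age: float = 0.05  # m/s per year
    beta_sbp: float = 0.01  # m/s per mmHg
    beta_height: float = 0.0  # m/s per cm
    sex_offset_sd: float = 0.10  # m/s, one draw per sex level
    pwv_noise_sd: float = 0.55  # m/s, age-independent PWV heterogeneity

    a_path: float = -0.10  # gamma units per m/s
    b_path: float = 0.05  # beta units per gamma unit
    gamma0: float = 0.50
    beta0: float = 0.010
    gamma_noise_sd: float = 0.05
    beta_noise_sd: float = 0.0005
    pwv_ref: float = 5.0  # m/s, centring for the a-path

    thermal_noise_sd: float = 2.0  # signal units, white per frame/voxel
    nuisance_scale: float = 1.0  # shared physiological nuisance amplitude
    effect_roi: np.ndarray | None = None
    seed: int = 0


def generate_covariates(
    n_parent: int,
    n_offspring: int,
    truth: GroundTruth | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject covariate table with the generative PWV regression.

    Returns a DataFrame with columns subject_id, group, age, sex, height,
    sbp, dbp, pp, heart_rate, cortical_thickness and pwv_true. The pulse
    pressure column satisfies pp = sbp - dbp row by row.
    """
    if n_parent < 2 or n_offspring < 2:
        raise ValueError("need at least 2 subjects per group")
    truth = truth or GroundTruth()
    if truth.pwv_noise_sd < 0 or truth.sex_offset_sd < 0:
        raise ValueError("noise SDs must be non-negative")
    rng = np.random.default_rng(seed)
    sex_offsets = {
        "F": rng.normal(0.0, truth.sex_offset_sd),
        "M": rng.normal(0.0, truth.sex_offset_sd),
    }
    rows = []
    for group, n in (("parent", n_parent), ("offspring", n_offspring)):
        t = GROUP_TARGETS[group]
        age = np.clip(rng.normal(*t["age"], n), *t["age_range"])
        height = rng.normal(*t["height"], n)
        sbp = rng.normal(*t["sbp"], n)
        dbp = rng.normal(*t["dbp"], n)
        hr = rng.normal(*t["heart_rate"], n)
        sex = np.where(rng.random(n) < t["female_frac"], "F", "M")
        thick = rng.normal(2.5, 0.12, n)
        rows.append(pd.DataFrame({
            "group": group, "age": age, "sex": sex, "height": height,
            "sbp": sbp, "dbp": dbp, "pp": sbp - dbp, "heart_rate": hr,
            "cortical_thickness": thick,
        }))
    cov = pd.concat(rows, ignore_index=True)
    cov.insert(0, "subject_id", [f"sub-{i:04d}" for i in range(len(cov))])
    offsets = cov["sex"].map(sex_offsets).to_numpy(dtype=float)
    cov["pwv_true"] = (
        truth.intercept
        + truth.beta_age * cov["age"]
        + truth.beta_sbp * cov["sbp"]
        + truth.beta_height * cov["height"]
        + offsets
        + rng.normal(0.0, truth.pwv_noise_sd, len(cov))
    )
    if (cov["pwv_true"] <= 0).any():
        cov["pwv_true"] = cov["pwv_true"].clip(lower=0.5)
    return cov


def _analytic_pulse(t, onset_ms, rise_ms, fall_ms, amplitude, baseline):
    """Flat baseline + raised-cosine upstroke and downstroke, vectorised."""
    t = np.asarray(t, dtype=float)
    rel = t - onset_ms
    out = np.full_like(t, baseline)
    up = (rel >= 0) & (rel < rise_ms)
    out[up] = baseline + 0.5 * amplitude * (1 - np.cos(np.pi * rel[up] / rise_ms))
    down = (rel >= rise_ms) & (rel < rise_ms + fall_ms)
    out[down] = baseline + 0.5 * amplitude * (
        1 + np.cos(np.pi * (rel[down] - rise_ms) / fall_ms)
    )
    return out


def generate_flow_waveforms(
    pwv_true: float,
    path_length: float = 0.356,
    heart_rate: float = 69.0,
    sampling_dt: float = 5.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    onset_ms: float = 250.0,
    rise_ms: float = 120.0,
    fall_ms: float = 250.0,
    amplitude: float = 400.0,
    baseline: float = 5.0,
) -> tuple[FlowWaveform, FlowWaveform]:
    """Arch and abdominal waveforms separated by path_length / pwv_true.

    The delay is applied to the analytic waveform before sampling, so it is
    exact to machine precision even when it is not a multiple of
    ``sampling_dt``. Additive white Gaussian noise is independent per plane.
    """
    if pwv_true <= 0 or path_length <= 0:
        raise ValueError("pwv_true and path_length must be positive")
    if sampling_dt > 25.0:
        raise ValueError("sampling_dt must be <= 25 ms")
    period_ms = 60000.0 / heart_rate
    delay_ms = 1000.0 * path_length / pwv_true
    if delay_ms >= period_ms:
        raise ConfigurationError(
            f"transit delay {delay_ms:.0f} ms exceeds cardiac period "
            f"{period_ms:.0f} ms"
        )
    rng = np.random.default_rng(seed)
    # record at least one full cycle, extended if the delayed upstroke
    # would otherwise run past the end of the window
    duration = max(period_ms,
                   onset_ms + delay_ms + rise_ms + fall_ms + 100.0)
    t = np.arange(0.0, duration, sampling_dt)
    meta = {
        "onset_ms": onset_ms, "rise_ms": rise_ms, "fall_ms": fall_ms,
        "amplitude": amplitude, "baseline": baseline,
        "true_delay_ms": delay_ms, "period_ms": period_ms,
        "pwv_true": pwv_true, "path_length": path_length,
    }
    waves = []
    for label, shift in (("arch", 0.0), ("abdominal", delay_ms)):
        flow = _analytic_pulse(t, onset_ms + shift, rise_ms, fall_ms,
                               amplitude, baseline)
        flow = flow + rng.normal(0.0, noise_sd, flow.shape)
        waves.append(FlowWaveform(t.copy(), flow, label, dict(meta)))
    return waves[0], waves[1]


def _band_limited_process(n, tr, rng, lo, hi, k=16):
    """Unit-variance sum of k random-phase sinusoids on a fixed band comb.

    Frequencies are evenly spaced over [lo, hi] and identical across
    subjects; only the phases are random. This keeps the spectral content
    — and hence the fraction of variance surviving downstream filtering —
    essentially constant across subjects, so between-subject amplitude
    differences reflect the injected amplitudes, not a frequency lottery.
    Normalised to exactly unit sample variance over the n frames, so an
    amplitude multiplying the process is recoverable from the sample
    variance without finite-length correction.
    """
    t = np.arange(n) * tr
    freqs = np.linspace(lo, hi, k)
    phases = rng.uniform(0.0, 2 * np.pi, k)
    x = np.cos(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(0)
    x = x - x.mean()
    return x / x.std(ddof=0), freqs


def default_effect_roi(atlases: dict, n_voxels: int = 12) -> np.ndarray:
    """GM voxels nearest the grid centre; the site of the injected effect."""
    gm = atlases["gm"]
    coords = np.argwhere(gm)
    centre = (np.array(gm.shape) - 1) / 2.0
    order = np.argsort(np.linalg.norm(coords - centre, axis=1), kind="stable")
    roi = np.zeros_like(gm, dtype=bool)
    for i, j, k in coords[order[:n_voxels]]:
        roi[i, j, k] = True
    return roi


def generate_pcasl_series(
    cov_row,
    truth: GroundTruth,
    dims: tuple = (12, 12, 6),
    n_frames: int = 100,
    seed: int = 0,
    masks: dict | None = None,
    tr: float = 4.0,
) -> DualEchoSeries:
    """One subject's interleaved dual-echo series (frame 0 = control).

    ``cov_row`` is a row of the covariate table (needs ``pwv_true``).
    ``masks`` should be shared across a cohort; when omitted a fresh atlas
    set is generated from ``seed``.
    """
    if n_frames % 2 or n_frames < 20:
        raise ValueError("n_frames must be even and >= 20")
    if any(d < 4 for d in dims):
        raise ValueError("each grid dimension must be >= 4")
    rng = np.random.default_rng(seed)
    if masks is None:
        masks = generate_atlases(dims, seed=seed)
    gm, wm, csf = masks["gm"], masks["wm"], masks["csf"]
    roi = truth.effect_roi
    if roi is None:
        roi = default_effect_roi(masks)
    pwv = float(cov_row["pwv_true"])

    # subject-level amplitudes along the mediation chain
    gamma_roi = truth.gamma0 + truth.a_path * (pwv - truth.pwv_ref) \
        + rng.normal(0.0, truth.gamma_noise_sd)
    gamma_roi = max(gamma_roi, 0.0)
    beta_roi = truth.beta0 + truth.b_path * (gamma_roi - truth.gamma0) \
        + rng.normal(0.0, truth.beta_noise_sd)
    beta_roi = max(beta_roi, 0.0)

    beta_map = np.zeros(dims)
    beta_map[gm] = truth.beta0
    beta_map[wm] = 0.3 * truth.beta0
    beta_map[roi] = beta_roi
    gamma_map = np.zeros(dims)
    gamma_map[gm] = truth.gamma0
    gamma_map[wm] = 0.5 * truth.gamma0
    gamma_map[roi] = gamma_roi

    m0 = {1: np.zeros(dims), 2: np.zeros(dims)}
    delta = {1: np.zeros(dims), 2: np.zeros(dims)}
    for tissue, m01, m02, d1, d2 in (
        (gm, 1000.0, 500.0, 10.0, 3.0),
        (wm, 800.0, 400.0, 3.0, 1.0),
        (csf, 1200.0, 300.0, 0.0, 0.0),
    ):
        m0[1][tissue], m0[2][tissue] = m01, m02
        delta[1][tissue], delta[2][tissue] = d1, d2

    # tissue-specific fluctuation processes: the GM signal of interest is
    # independent of the WM/CSF content, so the noise-ROI principal
    # components do not alias it; a shared physiological nuisance course
    # (strong in CSF/WM, weaker in GM) is what CompCor should remove
    b_gm, b_gm_freqs = _band_limited_process(n_frames, tr, rng, 0.01, 0.08)
    b_wm, _ = _band_limited_process(n_frames, tr, rng, 0.01, 0.08)
    c_gm, c_gm_freqs = _band_limited_process(n_frames, tr, rng, 0.01, 0.05)
    c_wm, _ = _band_limited_process(n_frames, tr, rng, 0.01, 0.05)
    b_proc = {"gm": b_gm, "wm": b_wm}  # BOLD-like, 0.01-0.08 Hz
    c_proc = {"gm": c_gm, "wm": c_wm}  # CBF fluctuation, slower band
    nuisance, _ = _band_limited_process(n_frames, tr, rng, 0.01, 0.10)
    ns = truth.nuisance_scale
    nuis_amp = {"gm": 1.5 * ns, "wm": 4.0 * ns, "csf": 6.0 * ns}

    b_series = np.zeros(dims + (n_frames,))
    c_series = np.zeros(dims + (n_frames,))
    nuis_series = np.zeros(dims + (n_frames,))
    for name, tissue in (("gm", gm), ("wm", wm), ("csf", csf)):
        if name in b_proc:
            b_series[tissue] = b_proc[name]
            c_series[tissue] = c_proc[name]
        nuis_series[tissue] = nuis_amp[name] * nuisance

    sign = (-1.0) ** np.arange(n_frames)  # +1 on control (even) frames
    te_scale = {1: 10.0 / 30.7, 2: 1.0}  # BOLD sensitivity ~ echo time
    echoes = {}
    for e in (1, 2):
        bold_amp = m0[e][..., None] * (
            1.0 + te_scale[e] * beta_map[..., None] * b_series
        )
        label = sign[None, None, None, :] * (delta[e][..., None] / 2.0) * (
            1.0 + gamma_map[..., None] * c_series
        )
        noise = rng.normal(0.0, truth.thermal_noise_sd, dims + (n_frames,))
        echoes[e] = bold_amp + label + nuis_series + noise

    return DualEchoSeries(
        echo1=echoes[1],
        echo2=echoes[2],
        frame_role=alternating_roles(n_frames),
        tr=tr,
        masks=dict(masks),
        truth_info={
            "pwv_true": pwv,
            "gamma_roi": gamma_roi,
            "beta_roi": beta_roi,
            "beta0": truth.beta0,
            "gamma0": truth.gamma0,
            "delta_gm_echo1": 10.0,
            "effect_roi": roi,
            "b_gm_freqs": b_gm_freqs,
            "c_gm_freqs": c_gm_freqs,
        },
    )


def generate_atlases(
    dims: tuple,
    seed: int = 0,
    vessel_fraction: float = 0.10,
) -> dict:
    """Tissue partition plus a sparse tree-like vessel-probability volume.

    GM/WM/CSF are a mutually exclusive, exhaustive partition of the brain
    mask (here the full grid). Vessel probabilities lie in [0, 1]; the set
    of strictly positive voxels is grown by branching random walks until it
    covers ``vessel_fraction`` of the brain. Arterial and venous submasks
    are disjoint halves of the vessel set.
    """
    rng = np.random.default_rng(seed)
    brain = np.ones(dims, dtype=bool)

    fields = gaussian_filter(rng.normal(size=(3,) + tuple(dims)),
                             sigma=(0, 1.5, 1.5, 1.5))
    fields[0] += 0.45  # bias towards GM
    fields[1] += 0.25
    labels = np.argmax(fields, axis=0)
    gm, wm, csf = labels == 0, labels == 1, labels == 2
    # guarantee non-empty tissue classes on tiny grids
    for i, mask in enumerate((gm, wm, csf)):
        if not mask.any():
            free = np.argwhere(gm if i else wm)
            x, y, z = free[0]
            gm[x, y, z] = wm[x, y, z] = csf[x, y, z] = False
            mask[x, y, z] = True

    n_target = max(1, round(vessel_fraction * brain.sum()))
    vessel = np.zeros(dims, dtype=bool)
    shape = np.array(dims)
    pos = rng.integers(0, shape)
    while vessel.sum() < n_target:
        vessel[tuple(pos)] = True
        step = np.zeros(3, dtype=int)
        axis = rng.integers(0, 3)
        step[axis] = rng.choice([-1, 1])
        pos = np.clip(pos + step, 0, shape - 1)
        if rng.random() < 0.05:  # branch: jump to a fresh start
            pos = rng.integers(0, shape)
    vessel_prob = np.zeros(dims)
    vessel_prob[vessel] = rng.uniform(0.1, 1.0, vessel.sum())

    half = dims[0] // 2
    arterial = vessel.copy()
    arterial[half:, :, :] = False
    venous = vessel & ~arterial
    return {
        "brain": brain, "gm": gm, "wm": wm, "csf": csf,
        "vessel_prob": vessel_prob, "arterial": arterial, "venous": venous,
    }


@dataclass
class Cohort:
    """A full synthetic study: covariates, shared atlases, per-subject data."""

    covariates: pd.DataFrame
    atlases: dict
    truth: GroundTruth
    series: list = field(default_factory=list)
    waveforms: list = field(default_factory=list)  # (arch, abdominal) pairs


def generate_cohort(
    truth: GroundTruth | None = None,
    n_parent: int = 20,
    n_offspring: int = 20,
    dims: tuple = (12, 12, 6),
    n_frames: int = 100,
    seed: int = 0,
    path_length: float = 0.356,
    waveform_noise_sd: float = 5.0,
    with_series: bool = True,
) -> Cohort:
    """Generate a complete seeded cohort sharing one atlas set."""
    truth = truth or GroundTruth()
    truth = replace(truth, seed=seed)
    cov = generate_covariates(n_parent, n_offspring, truth, seed=seed)
    atlases = generate_atlases(dims, seed=seed)
    if truth.effect_roi is None:
        truth.effect_roi = default_effect_roi(atlases)
    rng = np.random.default_rng(seed + 1)
    subseeds = rng.integers(0, 2**31 - 1, len(cov))
    series, waveforms = [], []
    for (_, row), s in zip(cov.iterrows(), subseeds):
        waveforms.append(generate_flow_waveforms(
            pwv_true=float(row["pwv_true"]), path_length=path_length,
            heart_rate=float(row["heart_rate"]), seed=int(s),
            noise_sd=waveform_noise_sd,
        ))
        if with_series:
            series.append(generate_pcasl_series(
                row, truth, dims=dims, n_frames=n_frames,
                seed=int(s), masks=atlases,
            ))
    return Cohort(covariates=cov, atlases=atlases, truth=truth,
                  series=series, waveforms=waveforms)
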
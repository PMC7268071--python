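"""Cross-subject statistics.

* PWV mixed-effects models: PWV ~ 1 + age + height + {SBP|DBP|PP} with a
  random intercept by sex (REML); with only two sex levels the variance
  component often degenerates, in which case the fit falls back to OLS
  with sex as a fixed covariate (recorded on the result).
* Voxelwise GLM across subjects with threshold-free cluster enhancement
  (TFCE) and family-wise-error correction by Freedman-Lane permutation of
  reduced-model residuals, using the max-TFCE null distribution.
* Vessel-probability regression: mean t statistic per equidistant
  vessel-probability bin, regressed on bin-mean probability (or voxelwise
  without binning), plus the significant-mask/vessel-mask overlap fraction.
* Mediation: indirect effect ab with a case-resampling bootstrap
  (percentile CI), after Preacher & Hayes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import ndimage

from .core import StatMap
from .errors import ModelError

__all__ = [
    "MixedModelResult",
    "PermutationResult",
    "MediationResult",
    "fit_pwv_mixed_model",
    "voxelwise_glm",
    "tfce",
    "permutation_correct",
    "vessel_bin_regression",
    "overlap_fraction",
    "mediate",
]


# ---------------------------------------------------------------------------
# mixed-effects PWV models


@dataclass
class MixedModelResult:
    fixed_effects: pd.DataFrame  # index: term; columns: estimate, se, p
    random_intercept_var: float
    n: int
    bp_term: str
    used_ols_fallback: bool


def fit_pwv_mixed_model(
    cov: pd.DataFrame,
    bp_term: str = "sbp",
    pwv_col: str = "pwv_true",
) -> MixedModelResult:
    """PWV ~ 1 + age + height + bp_term, random intercept by sex.

    Fitted by restricted maximum likelihood. A two-level grouping factor
    gives a fragile variance component; if it degenerates to ~0 or the fit
    fails, the model is refitted by OLS with sex as a fixed covariate and
    the fallback is flagged.
    """
    bp_term = bp_term.lower()
    if bp_term not in ("sbp", "dbp", "pp"):
        raise ValueError("bp_term must be one of sbp, dbp, pp")
    terms = ["age", "height", bp_term]
    cols = terms + [pwv_col, "sex"]
    if cov[cols].isna().any().any():
        raise ModelError("missing covariates in the table")
    if cov["sex"].nunique() < 2:
        raise ModelError("need at least 2 sex levels for the grouping factor")
    design = cov[terms].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(cov)), design])) \
            < len(terms) + 1:
        raise ModelError("singular fixed-effects design")

    formula = f"{pwv_col} ~ age + height + {bp_term}"
    fallback = False
    re_var = 0.0
    result = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mm = smf.mixedlm(formula, cov, groups=cov["sex"]).fit(reml=True)
        re_var = float(np.asarray(mm.cov_re)[0, 0])
        if np.isfinite(re_var) and re_var > 1e-8 and mm.converged:
            result = pd.DataFrame({
                "estimate": mm.fe_params,
                "se": mm.bse_fe,
                "p": mm.pvalues[mm.fe_params.index],
            })
    except Exception:
        result = None
    if result is None:
        fallback = True
        ols = smf.ols(formula + " + C(sex)", cov).fit()
        keep = [ix for ix in ols.params.index if not ix.startswith("C(sex)")]
        result = pd.DataFrame({
            "estimate": ols.params[keep],
            "se": ols.bse[keep],
            "p": ols.pvalues[keep],
        })
    result = result.rename(index={"Intercept": "intercept"})
    return MixedModelResult(
        fixed_effects=result,
        random_intercept_var=0.0 if fallback else re_var,
        n=len(cov),
        bp_term=bp_term,
        used_ols_fallback=fallback,
    )


# ---------------------------------------------------------------------------
# voxelwise GLM + TFCE + permutation


def _tmap_2d(Y: np.ndarray, X: np.ndarray, contrast: np.ndarray,
             pinvX: np.ndarray, cvc: float) -> np.ndarray:
    """t statistics for V voxels: Y is V x N, X is N x p."""
    B = Y @ pinvX.T  # V x p
    resid = Y - B @ X.T
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=1) / dof
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (B @ contrast) / np.sqrt(sigma2 * cvc)
    return np.nan_to_num(t)


def voxelwise_glm(
    stack: np.ndarray,
    design: np.ndarray,
    contrast: np.ndarray,
    mask: np.ndarray | None = None,
) -> StatMap:
    """Per-voxel OLS t map for a contrast of regression coefficients.

    ``stack`` is (x, y, z, subject); ``design`` is subjects x p and must be
    full rank; ``contrast`` has length p. A zero contrast returns zeros.
    """
    X = np.asarray(design, dtype=float)
    c = np.asarray(contrast, dtype=float)
    if X.shape[0] != stack.shape[-1]:
        raise ValueError("design rows must equal the subject dimension")
    if c.shape != (X.shape[1],):
        raise ValueError("contrast length must equal design columns")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("rank-deficient design matrix")
    if mask is None:
        mask = np.ones(stack.shape[:3], dtype=bool)
    pinvX = np.linalg.pinv(X)
    cvc = float(c @ np.linalg.inv(X.T @ X) @ c)
    Y = stack[mask]
    t = _tmap_2d(Y, X, c, pinvX, cvc) if cvc > 0 else np.zeros(Y.shape[0])
    out = np.zeros(stack.shape[:3])
    out[mask] = t
    return StatMap(out, kind="tstat", units="t")


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def tfce(
    tmap: np.ndarray | StatMap,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    connectivity: int = 26,
    n_steps: int = 100,
) -> np.ndarray:
    """Threshold-free cluster enhancement of the positive part of a map.

    TFCE(v) = sum over thresholds h = dh, 2dh, ... <= t(v) of
    e_h(v)^E * h^H * dh, where e_h(v) is the voxel count of the connected
    component containing v in {t >= h}. ``dh`` defaults to max(t)/n_steps.
    Apply to -t for the negative direction.
    """
    t = tmap.values if isinstance(tmap, StatMap) else np.asarray(tmap, float)
    if dh is not None and dh <= 0:
        raise ValueError("dh must be positive")
    structure = _STRUCTURES[connectivity]
    hmax = float(t.max(initial=0.0))
    if hmax <= 0:
        return np.zeros_like(t)
    step = dh if dh is not None else hmax / n_steps
    out = np.zeros_like(t, dtype=float)
    h = step
    while h <= hmax + 1e-12 * hmax:
        supra = t >= h
        labels, n_lab = ndimage.label(supra, structure=structure)
        if n_lab == 0:
            break
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        out += np.where(supra, sizes[labels] ** float(E) * h ** float(H)
                        * step, 0.0)
        h += step
    return out


@dataclass
class PermutationResult:
    tmap: StatMap
    tfce_map: StatMap
    pcorr_map: StatMap
    n_perm: int
    seed: int
    direction: str
    max_null: np.ndarray = field(default=None, repr=False)

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return np.isfinite(self.pcorr_map.values) \
            & (self.pcorr_map.values < alpha) \
            & (self.pcorr_map.values > 0)


def permutation_correct(
    stack: np.ndarray,
    design: np.ndarray,
    contrast: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    direction: str = "negative",
    mask: np.ndarray | None = None,
    tfce_opts: dict | None = None,
) -> PermutationResult:
    """FWE-corrected voxelwise inference via Freedman-Lane permutation.

    The nuisance-only model (columns with zero contrast weight) is fitted,
    its residuals are permuted (seeded whole-row shuffles), the full model
    is refitted on each permuted dataset, and the maximum TFCE score over
    the mask forms the null distribution. pcorr(v) = (1 + #{max* >=
    TFCE_obs(v)}) / (n_perm + 1), so p-values are bounded below by
    1/(n_perm+1). Tests are one-sided in the requested ``direction``.
    """
    X = np.asarray(design, dtype=float)
    c = np.asarray(contrast, dtype=float)
    if not np.any(c != 0):
        raise ModelError("contrast selects no column (all nuisance)")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value floor",
                      stacklevel=2)
    if direction not in ("negative", "positive"):
        raise ValueError("direction must be 'negative' or 'positive'")
    if mask is None:
        mask = np.ones(stack.shape[:3], dtype=bool)
    tfce_opts = dict(tfce_opts or {})
    sgn = -1.0 if direction == "negative" else 1.0

    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ModelError("rank-deficient design matrix")
    pinvX = np.linalg.pinv(X)
    cvc = float(c @ np.linalg.inv(X.T @ X) @ c)
    Y = stack[mask]  # V x N

    t_obs = _tmap_2d(Y, X, c, pinvX, cvc)
    tvol = np.zeros(stack.shape[:3])
    tvol[mask] = t_obs
    tfce_obs_vol = tfce(sgn * tvol, **tfce_opts)
    tfce_obs = tfce_obs_vol[mask]

    nuisance = np.flatnonzero(c == 0)
    Z = X[:, nuisance]
    if Z.size:
        pinvZ = np.linalg.pinv(Z)
        fitted = (Y @ pinvZ.T) @ Z.T  # V x N
    else:
        fitted = np.zeros_like(Y)
    resid = Y - fitted

    rng = np.random.default_rng(seed)
    max_null = np.empty(n_perm)
    pvol = np.zeros(stack.shape[:3])
    exceed = np.zeros(Y.shape[0])
    for b in range(n_perm):
        perm = rng.permutation(n)
        t_b = _tmap_2d(fitted + resid[:, perm], X, c, pinvX, cvc)
        pvol[mask] = t_b
        m = tfce(sgn * pvol, **tfce_opts).max()
        max_null[b] = m
        exceed += m >= tfce_obs
    pcorr = (1.0 + exceed) / (n_perm + 1.0)
    pvol = np.ones(stack.shape[:3])
    pvol[mask] = pcorr

    return PermutationResult(
        tmap=StatMap(tvol, "tstat", "t"),
        tfce_map=StatMap(tfce_obs_vol, "tfce", "a.u."),
        pcorr_map=StatMap(pvol, "pcorr", "p"),
        n_perm=n_perm, seed=seed, direction=direction, max_null=max_null,
    )


# ---------------------------------------------------------------------------
# vessel-probability regression and overlap


def vessel_bin_regression(
    tmap: np.ndarray | StatMap,
    vessel_prob: np.ndarray,
    sig_mask: np.ndarray,
    n_bins: int = 30,
    binned: bool = True,
) -> dict:
    """Regress (binned) t statistics on vessel probability.

    Within the significant mask, vessel probabilities are split into
    ``n_bins`` equidistant bins over their range; the regression uses
    bin-mean t against bin-mean probability over non-empty bins. With
    ``binned=False`` (the arterial/venous case) the regression is
    voxelwise. Returns slope, intercept, and the per-bin table.
    """
    t = tmap.values if isinstance(tmap, StatMap) else np.asarray(tmap, float)
    sig_mask = np.asarray(sig_mask, dtype=bool)
    if not sig_mask.any():
        raise ValueError("significant mask is empty")
    p = vessel_prob[sig_mask]
    tv = t[sig_mask]
    if binned:
        lo, hi = p.min(), p.max()
        if hi <= lo:
            raise ModelError("vessel probability is constant: <2 bins")
        edges = np.linspace(lo, hi, n_bins + 1)
        which = np.clip(np.digitize(p, edges) - 1, 0, n_bins - 1)
        rows = [(p[which == b].mean(), tv[which == b].mean(),
                 int((which == b).sum()))
                for b in range(n_bins) if (which == b).any()]
        table = pd.DataFrame(rows, columns=["mean_prob", "mean_t", "n_vox"])
        if len(table) < 2:
            raise ModelError("fewer than 2 non-empty bins")
        xs, ys = table["mean_prob"].to_numpy(), table["mean_t"].to_numpy()
    else:
        if np.ptp(p) == 0:
            raise ModelError("vessel probability is constant")
        xs, ys = p, tv
        table = pd.DataFrame({"mean_prob": xs, "mean_t": ys, "n_vox": 1})
    slope, intercept = np.polyfit(xs, ys, 1)
    return {"slope": float(slope), "intercept": float(intercept),
            "bins": table, "binned": binned}


def overlap_fraction(sig_mask: np.ndarray, vessel_mask: np.ndarray) -> float:
    """Percentage of significant voxels lying inside the vessel mask."""
    sig = np.asarray(sig_mask, dtype=bool)
    if not sig.any():
        raise ValueError("significant mask is empty")
    vessel = np.asarray(vessel_mask, dtype=bool)
    return 100.0 * float((sig & vessel).sum()) / float(sig.sum())


# ---------------------------------------------------------------------------
# bootstrap mediation


@dataclass
class MediationResult:
    a: float  # X -> M
    b: float  # M -> Y | X
    c: float  # total X -> Y
    c_prime: float  # direct X -> Y | M
    indirect: float  # ab
    ci95: tuple
    p_boot: float
    boot_distribution: np.ndarray = field(repr=False, default=None)
    n_boot: int = 0
    seed: int = 0


def _paths_no_cov(x, m, y):
    """Closed-form a, b, c, c' for the unadjusted linear mediation model.

    Supports leading batch dimensions (each row one bootstrap sample).
    """
    xc = x - x.mean(axis=-1, keepdims=True)
    mc = m - m.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    sxx = (xc * xc).sum(-1)
    sxm = (xc * mc).sum(-1)
    smm = (mc * mc).sum(-1)
    sxy = (xc * yc).sum(-1)
    smy = (mc * yc).sum(-1)
    det = sxx * smm - sxm ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        a = sxm / sxx
        b = (sxx * smy - sxm * sxy) / det
        c_prime = (smm * sxy - sxm * smy) / det
        c = sxy / sxx
    return a, b, c, c_prime


def _residualize(v, C):
    return v - C @ np.linalg.lstsq(C, v, rcond=None)[0]


def mediate(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Indirect effect of X on Y through M, with a bootstrap CI.

    a is the slope of M ~ X (+ covariates); b and c' come from
    Y ~ X + M (+ covariates); c from Y ~ X (+ covariates); the indirect
    effect is ab, with c = c' + ab exactly for the linear model. The
    sampling distribution of ab is obtained by case-resampling bootstrap
    (seeded); the CI is the 2.5-97.5 percentile interval and p_boot =
    2 * min(P(ab* <= 0), P(ab* >= 0)) with the +1 small-sample correction.
    """
    x = np.asarray(x, float).ravel()
    m = np.asarray(m, float).ravel()
    y = np.asarray(y, float).ravel()
    n = len(x)
    if not (len(m) == len(y) == n) or n < 10:
        raise ValueError("x, m, y must have equal length >= 10")
    for name, v in (("x", x), ("m", m), ("y", y)):
        if np.ptp(v) == 0:
            raise ModelError(f"{name} is constant")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))

    if covariates is None:
        a, b, c, c_prime = _paths_no_cov(x, m, y)
        ab_boot = _paths_no_cov(x[idx], m[idx], y[idx])
        ab_boot = ab_boot[0] * ab_boot[1]
    else:
        C = np.column_stack([np.ones(n), np.asarray(covariates, float)])

        def paths(xi, mi, yi, Ci):
            xr, mr, yr = (_residualize(v, Ci) for v in (xi, mi, yi))
            return _paths_no_cov(xr, mr, yr)

        a, b, c, c_prime = paths(x, m, y, C)
        ab_boot = np.empty(n_boot)
        for i in range(n_boot):
            s = idx[i]
            ai, bi, _, _ = paths(x[s], m[s], y[s], C[s])
            ab_boot[i] = ai * bi
    ab_boot = np.asarray(ab_boot, float)
    ab_boot = ab_boot[np.isfinite(ab_boot)]
    if ab_boot.size < max(10, n_boot // 2):
        raise ModelError("bootstrap produced too few valid resamples")
    lo, hi = np.percentile(ab_boot, [2.5, 97.5])
    nb = ab_boot.size
    p_le = (1 + np.sum(ab_boot <= 0)) / (nb + 1)
    p_ge = (1 + np.sum(ab_boot >= 0)) / (nb + 1)
    p_boot = min(1.0, 2.0 * min(p_le, p_ge))
    return MediationResult(
        a=float(a), b=float(b), c=float(c), c_prime=float(c_prime),
        indirect=float(a * b), ci95=(float(lo), float(hi)),
        p_boot=float(p_boot), boot_distribution=ab_boot,
        n_boot=n_boot, seed=seed,
    )
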
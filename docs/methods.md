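# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the limitations of `pwvbold`. It describes what the
code computes; every number quoted here is produced by the test suite or
by `scripts/acceptance.py` at run time.

## Signal model and separation

A dual-echo pCASL acquisition interleaves magnetically tagged and control
frames; frame 0 (after discarding an even number of equilibration frames,
default 4) is a control frame by package convention. The per-voxel model is

    s(v, e, i) = M0(v, e) · (1 + β(v)·b_i)                (slow, BOLD-weighted)
               + (−1)^i · (δ(v, e)/2) · (1 + γ(v)·c_i)     (alternating, perfusion)
               + n(v, i) + ε                               (nuisance + noise)

with echo e ∈ {1, 2} (short echo perfusion-sensitive, long echo
BOLD-sensitive), b a band-limited (0.01–0.08 Hz) BOLD-like process, c a
slower CBF-fluctuation process, and δ the label difference
(control − tag). The two sliding 3-frame stencils are exact complements on
locally linear components:

- surround averaging `s_i/2 + (s_{i−1}+s_{i+1})/4` cancels any pure
  alternating component and passes constants and linear drifts unchanged;
- surround subtraction `σ_i·(s_i − (s_{i−1}+s_{i+1})/2)`, σ = +1 on
  control and −1 on tag frames, cancels the slow part and returns δ.

Both drop the first and last frame rather than pad — no data are
fabricated, and frame counts are recorded in the provenance list.

The CBF-fluctuation envelope is alternatively obtained from the first echo
by demodulation: the tag/control alternation is a carrier at the Nyquist
frequency (1/(2·TR) = 0.125 Hz at TR = 4 s), amplitude-modulated by the
perfusion fluctuations. Each voxel is high-pass filtered above 1/(4·TR)
(removing BOLD-band content; the cutoff is a config option since no single
standard exists), multiplied by the carrier sign, and low-pass filtered
below 0.08 Hz.

**Filters.** The band-pass default is 0.001–0.08 Hz. Its lower edge is
realised by regression: all discrete-cosine components below the cutoff
(for 0.001 Hz on a ~380 s series, just the mean) are projected out. A
recursive high-pass at a cutoff whose period is ~3× the series duration is
dominated by its own transient — on identical unit-variance inputs it
inflated output variance with a ~25% subject-to-subject spread — whereas
the projection removes exactly the unresolvable slow subspace. The upper
edge, and the high-/low-pass filters of the demodulation path, are
zero-phase forward–backward Butterworth of order 4 (second-order
sections); forward–backward filtering squares the magnitude response,
which the amplitude-recovery tests account for spectrally.

**CompCor.** Physiological noise is removed per stream (tag frames and
control frames separately, since their noise structure differs): the top-k
(default 4) principal components of the temporally centred WM+CSF signal
are projected out of every voxel's stream. The projection removes only
centred components, so each voxel's temporal mean — including the
control−tag perfusion offset needed for CBF quantification — is retained,
and k = 0 is the identity. Consequence: a nuisance signal's *stream-mean*
contribution is unidentifiable from per-stream-centred components and
survives denoising; only its fluctuating part is removed. Numerically null
components (singular value < 1e−8 of the leading one) are dropped, which
makes re-application a no-op once the noise ROI is fully explained.

**Smoothing.** Gaussian, σ = FWHM/(2√(2 ln 2)) per axis in mm, `nearest`
boundary handling so constant images are unchanged. The protocol default
is 6 mm FWHM, applied to the series before variance mapping (whether
variance should precede or follow smoothing is genuinely open; the order
is configurable). For the synthetic cohort analyses the package's own runs
use FWHM = 0: the synthetic fields carry no spatial autocorrelation and
voxels are already 3.44 × 3.44 × 6 mm, so smoothing only dilutes the
injected ROI effect.

## Fluctuation metrics and CBF quantification

Fluctuation amplitude is the per-voxel unbiased temporal variance after
rejecting time points beyond k·1.4826·MAD (default k = 5) of the voxel
median — a robust, scale-free rule chosen because the upstream protocol
specifies outlier rejection without a criterion; k = ∞ disables it.
Voxels with fewer than 3 surviving points are NaN. CBF-fluctuation maps
are restricted to gray matter (ASL difference signals in WM are too
unreliable).

Outlier *volumes* of the ΔM series can be removed by a greedy SNR
criterion: repeatedly drop the frame whose exclusion most increases the
GM-mean temporal SNR, stopping below 1% relative gain or after 20% of
frames; the default mode is a no-op, matching the convention of reporting
both a default and an SNR-optimised CBF map.

Absolute CBF uses the single-compartment pCASL closed form

    f = 6000 · λ · ΔM · exp(PLD/T1b) / (2 · α · T1b · M0 · (1 − exp(−τ/T1b)))

with defaults λ = 0.9 mL/g, α = 0.85, T1b = 1.65 s, τ = 1.5 s,
PLD = 1.0 s. The acquisition's 1.0 s post-label delay is short for full
label arrival; quantification fidelity is therefore judged by algebraic
round-trip recovery (exact to 1e−9), not physiological accuracy.

## PWV estimation

The foot of the systolic upstroke is located by the intersecting-tangent
method: baseline = median flow over the 100 ms (configurable) preceding
the upstroke onset (first sample whose upslope exceeds 20% of the maximum
upslope); tangent through the maximum-upslope point, whose time is refined
to sub-sample precision by parabolic interpolation of the discrete
derivative while the slope value is taken from the sampled maximum (exact
for piecewise-linear upstrokes, slightly conservative for smooth ones).
PWV = x/t with the aortic path length x a scalar input (default 0.356 m,
the cohort mean) and t the foot-time difference. Estimates from
independent raters are combined by the arithmetic mean. For noisy
waveforms a Savitzky–Golay pre-smoothing window (e.g. 11 samples at 5 ms)
stabilises the derivative; it defaults to off because synthetic waveforms
are noise-free by default.

## Intrinsic connectivity

IC(v) = Σ_{u≠v} atanh(clip(r_uv)) over all brain voxels, Pearson r on the
band-passed denoised BOLD series. Negative correlations enter as negative
z (the literal definition; a magnitude threshold is available but off by
default). |r| is clipped at 0.9999 before atanh so degenerate series
cannot produce infinities; zero-variance voxels are excluded with a
warning. The computation is block-wise with results independent of the
block size (verified against an O(V²) pairwise oracle).

## Group inference

**Mixed models.** PWV ~ 1 + age + height + {SBP|DBP|PP} with a random
intercept by sex, fitted by REML. With only two grouping levels the
variance component is fragile; when it degenerates (≤ 1e−8) or the fit
fails, the model falls back to OLS with sex as a fixed covariate and the
result records the fallback. The three blood-pressure variants are fitted
without multiplicity correction, mirroring standard practice for such
exploratory models.

**Voxelwise GLM + TFCE + permutation.** Per-voxel OLS t statistics for a
contrast (typically PWV adjusted for age);
TFCE(v) = Σ_h e_h(v)^E · h^H · dh with the field-standard E = 0.5, H = 2,
26-connectivity and dh = max(t)/n_steps (default 100 steps; simulation
studies here use 32 for speed — the FWE guarantee is threshold-count
invariant because observed and permuted maps are treated identically).
FWE correction uses Freedman–Lane permutation: fit the nuisance-only
model, permute its residuals with seeded whole-row shuffles, refit, and
compare the observed TFCE to the max-TFCE null;
pcorr = (1 + #{max* ≥ obs})/(n_perm + 1) ≥ 1/(n_perm+1). Tests are
one-sided in the requested direction (associations of interest are
directional). Family structure (parent/offspring pairs) is not used as an
exchangeability block; a config hook exists but whole-cohort shuffling is
the default.

**Vessel-probability regression.** Within the significant mask, vessel
probabilities are split into equidistant bins (default 30) and bin-mean t
is regressed on bin-mean probability; arterial/venous submasks are
regressed voxelwise without binning. The overlap fraction is
100·|sig ∩ vessel|/|sig|.

**Mediation.** a from M ~ X, b and c′ from Y ~ X + M, c from Y ~ X
(optionally all adjusted for covariates via residualisation); indirect
effect ab with c = c′ + ab exactly. Inference by case-resampling bootstrap
(default 1000 iterations, seeded), percentile 95% CI — the basic
Preacher–Hayes recommendation; bias-corrected intervals are not
implemented — and p = 2·min(P(ab* ≤ 0), P(ab* ≥ 0)) with the +1
correction. Note the known conservativeness of product-of-coefficients
inference when a and b are both zero: coverage calibration is meaningful
under the single null (a = 0, b ≠ 0), which is what the validation
simulates. The pipeline's mediation test (CBF-variance mediating the
PWV→BOLD-variance association) is unadjusted by default; age adjustment
is available through the covariate argument.

## Synthetic cohort

The generator realises the statistical structure the analysis assumes, so
parameter recovery is a well-posed test:

- **Covariates.** Group targets: parents age 55.0 ± 6.5 y (range 43–67),
  SBP 122.5 ± 13.2, DBP 67.5 ± 8.3 mmHg (so PP averages 55.0), height
  169.7 ± 8.2 cm, 64% female; offspring age 25.4 ± 5.8 y (range 19–39),
  SBP 119.8 ± 14.8, DBP 65.8 ± 5.8, height 171.3 ± 10.9, 70% female.
  PWV = 1.70 + 0.05·age + 0.01·SBP + 0·height + sex offset
  (SD 0.10 m/s, one draw per level — the random-intercept structure) +
  N(0, 0.55) m/s. These defaults put the group means near 5.7 and
  4.2 m/s. The residual SD is a homoscedastic compromise: the cohort's
  printed within-group SDs (0.53 offspring, 1.05 parents) imply
  heteroscedastic age-independent heterogeneity, but the mixed model is
  required to be a correctly specified estimator on this data, so a single
  residual SD between the two is used. Reported group means also differ
  slightly between sections of the source cohort description; all are
  targets, not constants.
- **Waveforms.** Flat diastolic baseline (5 mL/s) + raised-cosine upstroke
  (onset 250 ms, rise 120 ms, fall 250 ms, amplitude 400 mL/s), sampled at
  5 ms (must be ≤ 25 ms); the abdominal waveform is the arch waveform
  delayed by exactly x/PWV on the analytic curve before sampling, with
  independent additive white noise per plane.
- **Series.** M0 and δ are tissue constants (GM/WM/CSF; δ larger at the
  short echo); b and c are unit-sample-variance sums of 16 random-phase
  sinusoids on fixed, evenly spaced frequency combs (0.01–0.08 Hz and
  0.01–0.05 Hz). Fixing the comb across subjects keeps the fraction of
  process variance surviving the stencil and band-pass essentially
  constant (subject-to-subject spread ~4% instead of ~17% with random
  frequencies), so between-subject amplitude differences reflect the
  injected amplitudes rather than a spectral lottery — random frequencies
  acted as a global variance confound shared across all GM. The GM and WM
  processes are independent draws and CSF carries none, so the WM+CSF
  CompCor components cannot alias the GM signal; a shared physiological
  nuisance course (0.01–0.10 Hz, amplitude 6/4/1.5 in CSF/WM/GM) is what
  CompCor legitimately removes. Inside the effect ROI (the 12 GM voxels
  nearest the grid centre by default) the mediation chain is
  γ = 0.50 − 0.10·(PWV − 5) + N(0, 0.05) and
  β = 0.010 + 0.05·(γ − 0.50) + N(0, 0.0005), i.e. a negative a-path and
  positive b-path giving a negative indirect effect; thermal noise SD 2
  signal units. These amplitudes emulate the salience of the reported
  cohort effects (corrected-significant maps and mediation p of order
  1e−4 at n = 59): across repeated 40-subject cohorts the mediation is
  significant essentially always and the ROI attains corrected
  significance in roughly four out of five cohorts.
- **Atlases.** GM/WM/CSF from biased smoothed random fields (argmax →
  exhaustive, mutually exclusive partition); the vessel-probability volume
  grows branching random walks until 10% (±2%) of brain voxels are
  vascular, with probabilities uniform on [0.1, 1]; arterial/venous are
  disjoint spatial halves of the vessel set.

What the generator does **not** emulate: spatial autocorrelation of the
noise, head motion, slice timing, cardiac/respiratory aliasing, T1
relaxation kinetics (amplitude scaling only), or nonlinear PWV–age
relationships. Passing tests therefore demonstrate correctness of the
estimators under the assumed model, not robustness to real-data artifacts;
real data must arrive motion-corrected and spatially registered.

## Problem sizes used in validation

Chosen for deterministic desk-scale runs: FWE null calibration — 20
subjects, 6×6×3 grid, 500 permutations, 200 replicates (100 in the
acceptance script); power — 1.5-SD effect in an 8-voxel ROI, n = 40, 50
replicates (25 in the script); mixed-model coverage — 100 replicate fits
at n = 2000; mediation calibration — 200 replicates of n = 100 with 1000
bootstrap iterations; end-to-end — 40 subjects, 12×12×6 grid, 100 frames,
500 permutations, FWHM 0. Protocol-scale defaults (10,000 permutations,
1,000 bootstrap iterations, 6 mm FWHM) remain the `PipelineConfig`
defaults.

## Degenerate inputs and tie-breaking

Non-positive transit times raise (mislabeled planes); waveforms without a
positive upslope raise; constant mediation inputs raise; rank-deficient
GLM designs raise; zero-variance IC voxels are dropped with a warning;
MAD = 0 voxels keep points equal to the median; empty significant masks
skip the vessel regression with a recorded reason rather than failing the
pipeline. The TFCE threshold ladder starts at dh (not 0), so an all-zero
or all-negative map scores zero everywhere.
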
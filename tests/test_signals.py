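"""Signal separation: stencils, denoising, filters, smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pwvbold as p
from pwvbold.core import DualEchoSeries, alternating_roles
from pwvbold.errors import ConfigurationError
from pwvbold.signals import (bandpass, bandpass_sos, compcor_denoise,
                             demodulate_first_echo, discard_initial_frames,
                             separate, spatial_smooth, surround_average,
                             surround_subtract)


def _series_from(echo1, echo2=None, masks=None):
    echo2 = echo1 if echo2 is None else echo2
    n = echo1.shape[-1]
    return DualEchoSeries(echo1=echo1, echo2=echo2,
                          frame_role=alternating_roles(n),
                          masks=masks or {})


class TestDiscard:
    def test_100_frames_minus_4(self):
        s = _series_from(np.zeros((2, 2, 2, 100)))
        out = discard_initial_frames(s, 4)
        assert out.n_frames == 96
        roles = np.asarray(out.frame_role)
        assert np.all(roles[:-1] != roles[1:])
        assert roles[0] == "control"

    def test_zero_is_identity(self):
        s = _series_from(np.random.default_rng(0).normal(size=(2, 2, 2, 10)))
        out = discard_initial_frames(s, 0)
        assert np.array_equal(out.echo1, s.echo1)

    def test_odd_discard_rejected(self):
        s = _series_from(np.zeros((2, 2, 2, 10)))
        with pytest.raises(ValueError):
            discard_initial_frames(s, 3)


class TestSurroundStencils:
    def test_average_cancels_alternation(self):
        s = np.array([10.0, 6, 10, 6, 10])[None, None, None, :]
        assert np.allclose(surround_average(s)[0, 0, 0], [8, 8, 8])

    def test_average_preserves_drift(self):
        i = np.arange(9.0)[None, None, None, :]
        assert np.allclose(surround_average(i)[0, 0, 0], np.arange(1.0, 8.0))

    def test_subtract_recovers_difference(self):
        s = np.array([10.0, 6, 10, 6, 10])[None, None, None, :]
        assert np.allclose(surround_subtract(s)[0, 0, 0], [4, 4, 4])

    def test_subtract_cancels_drift(self):
        i = np.arange(9.0)[None, None, None, :]
        assert np.allclose(surround_subtract(i), 0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(c=st.floats(-100, 100), d=st.floats(0, 50),
           drift=st.floats(-1, 1))
    def test_complementary_projections_exact(self, c, d, drift):
        """s_i = c + drift*i + (-1)^i * d/2: averaging returns the slow
        part, subtraction returns d, both exactly."""
        i = np.arange(12.0)
        s = (c + drift * i + ((-1.0) ** i) * d / 2)[None, None, None, :]
        slow = surround_average(s)[0, 0, 0]
        diff = surround_subtract(s)[0, 0, 0]
        assert np.allclose(slow, c + drift * i[1:-1], atol=1e-9)
        assert np.allclose(diff, d, atol=1e-9)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            surround_average(np.zeros((1, 1, 1, 2)))
        with pytest.raises(ValueError):
            surround_subtract(np.zeros((1, 1, 1, 2)))


def _compcor_testbed(roi_noise_sd=0.0, seed=0):
    """A shared nuisance course in all CSF voxels and half of GM; white
    noise lives in GM only, so the noise ROI is exactly low-rank when
    ``roi_noise_sd`` is 0."""
    rng = np.random.default_rng(seed)
    dims, n = (6, 6, 2), 40
    gm = np.zeros(dims, bool)
    gm[:, :3, :] = True
    csf = np.zeros(dims, bool)
    csf[:3, 3:, :] = True
    wm = ~gm & ~csf
    nuis = rng.normal(size=n)
    data = np.full(dims + (n,), 100.0)
    data[gm] += rng.normal(0, 0.5, (gm.sum(), n))
    data[csf] += 5.0 * nuis
    data[csf] += rng.normal(0, 1.0, (csf.sum(), n)) * roi_noise_sd
    gm_idx = np.argwhere(gm)
    half = gm_idx[: len(gm_idx) // 2]
    for x, y, z in half:
        data[x, y, z] += 3.0 * nuis
    masks = {"gm": gm, "wm": wm, "csf": csf}
    return _series_from(data.copy(), data.copy(), masks), nuis, half


class TestCompCor:
    def test_injected_nuisance_removed_from_gm(self):
        """After denoising, the time-varying nuisance is gone from GM.

        Correlations are computed on per-stream-centred series: the
        projection deliberately retains stream means (the perfusion offset
        lives there), so only the fluctuating nuisance can be removed.
        """
        s, nuis, contaminated = _compcor_testbed(roi_noise_sd=0.2)
        out = compcor_denoise(s, k=1, noise_mask=s.masks["csf"])
        roles = np.asarray(s.frame_role)

        def stream_centred(v):
            v = v.astype(float).copy()
            for r in np.unique(roles):
                ix = roles == r
                v[ix] -= v[ix].mean()
            return v

        nc = stream_centred(nuis)
        for x, y, z in contaminated[:5]:
            before = np.corrcoef(stream_centred(s.echo1[x, y, z]), nc)[0, 1]
            after = np.corrcoef(stream_centred(out.echo1[x, y, z]), nc)[0, 1]
            assert abs(before) > 0.9  # contamination was real
            assert abs(after) < 0.1

    def test_projection_idempotent_when_roi_explained(self):
        s, _, _ = _compcor_testbed(roi_noise_sd=0.0)
        once = compcor_denoise(s, k=1, noise_mask=s.masks["csf"])
        twice = compcor_denoise(once, k=1, noise_mask=s.masks["csf"])
        assert np.allclose(once.echo1, twice.echo1, atol=1e-8)

    def test_k0_is_identity_and_means_retained(self):
        s, _, _ = _compcor_testbed()
        out = compcor_denoise(s, k=0, noise_mask=s.masks["csf"])
        assert np.array_equal(out.echo1, s.echo1)
        out1 = compcor_denoise(s, k=1, noise_mask=s.masks["csf"])
        assert np.allclose(out1.echo1.mean(-1), s.echo1.mean(-1), atol=1e-9)

    def test_k_too_large_rejected(self):
        s, _, _ = _compcor_testbed()
        with pytest.raises(ValueError):
            compcor_denoise(s, k=25, noise_mask=s.masks["csf"])


class TestDemodulation:
    def test_constant_label_amplitude_recovered(self):
        n, d = 96, 4.0
        s = (((-1.0) ** np.arange(n)) * d)[None, None, None, :]
        out = demodulate_first_echo(s, tr=4.0)
        interior = out[0, 0, 0, 10:-10]
        assert np.allclose(np.abs(interior), d, rtol=0.02)

    def test_bold_band_content_suppressed(self):
        n, tr = 96, 4.0
        t = np.arange(n) * tr
        s = np.sin(2 * np.pi * 0.02 * t)[None, None, None, :]
        out = demodulate_first_echo(s, tr=tr)
        assert np.abs(out).max() < 0.05

    def test_zero_in_zero_out(self):
        out = demodulate_first_echo(np.zeros((1, 1, 1, 32)), tr=4.0)
        assert np.allclose(out, 0.0)

    def test_bad_cutoff_rejected(self):
        with pytest.raises(ConfigurationError):
            demodulate_first_echo(np.zeros((1, 1, 1, 32)), tr=4.0,
                                  lp_cutoff=0.2)


class TestBandpass:
    def test_in_band_amplitude_preserved(self):
        # steady-state gain at 0.04 Hz, away from the filtfilt edge
        # transients of the very low 0.001 Hz band edge
        tr, n = 4.0, 4000
        t = np.arange(n) * tr
        x = np.sin(2 * np.pi * 0.04 * t)
        y = bandpass(x, tr)[1500:2500]
        tm = t[1500:2500]
        amp = np.hypot(2 * np.mean(y * np.sin(2 * np.pi * 0.04 * tm)),
                       2 * np.mean(y * np.cos(2 * np.pi * 0.04 * tm)))
        assert 0.98 <= amp <= 1.02

    def test_dc_removed(self):
        y = bandpass(np.full(200, 7.0), tr=4.0)
        assert np.abs(y).max() < 7.0 * 1e-3

    def test_out_of_band_attenuated(self):
        tr, n = 1.0, 600  # fs=1 Hz so 0.2 Hz is representable
        t = np.arange(n) * tr
        x = np.sin(2 * np.pi * 0.04 * t) + np.sin(2 * np.pi * 0.2 * t)
        y = bandpass(x, tr)
        # isolate 0.2 Hz residual by correlating with the carrier
        carrier = np.sin(2 * np.pi * 0.2 * t)
        resid_amp = 2 * np.abs(y @ carrier) / n
        assert resid_amp < 0.1

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            bandpass_sos(tr=4.0, lo=0.001, hi=0.2)
        with pytest.raises(ConfigurationError):
            bandpass_sos(tr=4.0, lo=0.08, hi=0.001)


class TestSpatialSmooth:
    def test_delta_has_requested_fwhm(self):
        vol = np.zeros((31, 31, 31))
        vol[15, 15, 15] = 1.0
        out = spatial_smooth(vol, fwhm=6.0, voxel_size=2.0)
        profile = out[:, 15, 15]
        half = profile.max() / 2
        x = np.arange(31) * 2.0  # mm
        # interpolated half-maximum crossings on either side of the peak
        left = np.interp(half, profile[:16], x[:16])
        right = np.interp(half, profile[15:][::-1], x[15:][::-1])
        width = right - left
        assert abs(width - 6.0) <= 1.0  # half a voxel

    def test_constant_unchanged_and_zero_fwhm_identity(self):
        vol = np.full((8, 8, 4), 3.3)
        assert np.allclose(spatial_smooth(vol, 6.0, 2.0), 3.3)
        rng = np.random.default_rng(0)
        v = rng.normal(size=(5, 5, 5))
        assert np.array_equal(spatial_smooth(v, 0.0), v)

    def test_mass_conserved_for_interior_blob(self):
        vol = np.zeros((24, 24, 24))
        vol[10:14, 10:14, 10:14] = 1.0
        out = spatial_smooth(vol, fwhm=4.0, voxel_size=2.0)
        assert out.sum() == pytest.approx(vol.sum(), rel=1e-6)


class TestSeparatePipeline:
    def test_shapes_and_provenance(self, small_cohort):
        s = small_cohort.series[0]
        den = separate(s, discard=4, compcor_k=2, fwhm=0.0)
        n_interior = s.n_frames - 4 - 2
        assert den.bold.shape[-1] == n_interior
        assert den.cbf_delta_m.shape[-1] == n_interior
        assert den.cbf_signal.shape[-1] == n_interior
        steps = [step.split("(")[0] for step in den.provenance]
        assert steps == ["discard_initial_frames", "compcor_denoise",
                         "surround_average", "surround_subtract",
                         "bandpass", "demodulate_first_echo"]

    def test_rerun_bit_identical(self, small_cohort):
        s = small_cohort.series[1]
        a = separate(s, fwhm=0.0)
        b = separate(s, fwhm=0.0)
        assert np.array_equal(a.bold, b.bold)
        assert np.array_equal(a.cbf_signal, b.cbf_signal)

    def test_bold_variance_tracks_known_amplitude(self):
        """Band-passed BOLD variance equals beta^2 M0^2 times the variance
        of the (stencil- and filter-transformed) unit process, within 10%.

        The oracle extracts the latent process by analytic inversion of the
        noise-free generative model at one voxel, then applies the stencil
        and filter to that pure component directly.
        """
        truth = p.GroundTruth(thermal_noise_sd=0.0, nuisance_scale=0.0,
                              gamma_noise_sd=0.0, beta_noise_sd=0.0,
                              a_path=0.0, b_path=0.0, gamma0=0.0)
        cov = p.generate_covariates(2, 2, truth, seed=2)
        atlases = p.generate_atlases((6, 6, 4), seed=2)
        from pwvbold.synthetic import default_effect_roi
        truth.effect_roi = default_effect_roi(atlases)
        tr, m0, delta = 4.0, 500.0, 3.0  # GM constants at echo 2
        s = p.generate_pcasl_series(cov.iloc[0], truth, dims=(6, 6, 4),
                                    n_frames=100, seed=2, masks=atlases,
                                    tr=tr)
        den = separate(s, discard=4, compcor_k=0, fwhm=0.0)
        gm_outside = atlases["gm"] & ~truth.effect_roi
        measured = den.bold[gm_outside].var(axis=-1, ddof=0).mean()

        voxel = s.echo2[gm_outside][0]
        signs = (-1.0) ** np.arange(s.n_frames)
        b = (voxel - signs * delta / 2 - m0) / (m0 * truth.beta0)
        b = b[4:]  # discard, then the stencil and the band-pass
        slow = b[1:-1] / 2 + (b[:-2] + b[2:]) / 4
        filt = bandpass(slow, tr)
        expected = (m0 * truth.beta0) ** 2 * filt.var(ddof=0)
        assert measured == pytest.approx(expected, rel=0.10)
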
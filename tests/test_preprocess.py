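"""Optical-density conversion, Beer-Lambert inversion, QC, TDDR, filters."""

import time

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fnirspeech.io import RawRecording
from fnirspeech.preprocess import (
    EXTINCTION_COEFFS,
    PreprocessConfig,
    QCConfig,
    dct_highpass,
    extinction_matrix,
    hrf_lowpass,
    intensity_to_od,
    mbll,
    preprocess_recording,
    sliding_window_qc,
    tddr,
)

FS = 10.0


class TestOpticalDensity:
    def test_constant_intensity_gives_zero_od(self):
        rec = RawRecording(np.full((50, 2, 2), 3.7), fs=FS)
        np.testing.assert_allclose(intensity_to_od(rec), 0.0, atol=1e-14)

    def test_tenfold_drop_gives_od_one(self):
        data = np.ones((50, 1, 2))
        data[10, 0, 0] = 0.1
        rec = RawRecording(data, fs=FS)
        od = intensity_to_od(rec, baseline_window_s=(0.0, 1.0))
        assert od[10, 0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_elementwise_recomputation(self, rng):
        data = rng.uniform(0.2, 5.0, size=(40, 3, 2))
        rec = RawRecording(data, fs=FS)
        od = intensity_to_od(rec, baseline_window_s=(0.0, 2.0))
        ref = data[:20].mean(axis=0)
        expected = -np.log10(data / ref)  # brute-force per-sample formula
        np.testing.assert_allclose(od, expected, rtol=1e-12)


class TestMBLL:
    def test_zero_od_gives_zero_hb(self):
        hb = mbll(np.zeros((10, 2, 2)), fs=FS)
        assert np.all(hb.hbo == 0) and np.all(hb.hbr == 0) and np.all(hb.thb == 0)

    def test_forward_model_inverts_exactly(self, rng):
        """Project known concentrations through the extinction matrix and
        recover them to machine precision."""
        hbo = rng.standard_normal((30, 4)) * 0.05
        hbr = rng.standard_normal((30, 4)) * 0.02
        E = extinction_matrix((695.0, 830.0))
        od = np.stack([hbo, hbr], axis=-1) @ E.T
        out = mbll(od, fs=FS)
        np.testing.assert_allclose(out.hbo, hbo, rtol=1e-10, atol=1e-14)
        np.testing.assert_allclose(out.hbr, hbr, rtol=1e-10, atol=1e-14)
        np.testing.assert_allclose(out.thb, hbo + hbr, rtol=1e-10, atol=1e-14)

    def test_linearity_in_od(self, rng):
        od = rng.standard_normal((20, 2, 2)) * 0.01
        one = mbll(od, fs=FS)
        two = mbll(2 * od, fs=FS)
        np.testing.assert_allclose(two.hbo, 2 * one.hbo, rtol=1e-12)
        np.testing.assert_allclose(two.hbr, 2 * one.hbr, rtol=1e-12)

    def test_singular_extinction_table_rejected(self):
        bad = {695.0: (1.0, 2.0), 830.0: (2.0, 4.0)}
        with pytest.raises(np.linalg.LinAlgError):
            mbll(np.zeros((5, 1, 2)), extinction_table=bad, fs=FS)

    def test_shipped_table_covers_both_wavelengths(self):
        assert set(EXTINCTION_COEFFS) == {695.0, 830.0}


class TestSlidingWindowQC:
    def test_constant_channel_retained(self):
        rep = sliding_window_qc(np.ones((200, 1)), FS)
        assert rep.artifact_fraction[1] == 0.0
        assert rep.excluded_channels == set()

    def test_six_percent_contamination_excludes_channel(self, rng):
        """A channel with >5% of samples flagged is low quality."""
        T = 1000
        x = rng.normal(0, 1.0, size=(T, 1))
        # plant 3 huge samples in each of the 20 windows (60/1000 = 6%)
        spike_idx = np.concatenate([np.arange(w * 50, w * 50 + 3) for w in range(20)])
        x[spike_idx, 0] = 500.0
        rep = sliding_window_qc(x, FS)
        assert rep.artifact_fraction[1] > 0.05
        assert rep.excluded_channels == {1}

    def test_flags_match_independent_window_scan(self, rng):
        """Spiked samples flagged exactly as a brute-force recomputation."""
        T, k = 600, 3.0
        x = rng.normal(0, 1.0, size=T)
        spikes = rng.choice(T, size=20, replace=False)
        x[spikes] += 10.0 * np.sign(rng.standard_normal(20))
        rep = sliding_window_qc(x[:, None], FS, QCConfig())
        # independent per-window recomputation of the same rule
        win = int(5 * FS)
        expected = np.zeros(T, dtype=bool)
        for s in range(0, T, win):
            seg = x[s : s + win]
            mu, sd = seg.mean(), seg.std()
            expected[s : s + win] = np.abs(seg - mu) > k * sd
        np.testing.assert_array_equal(rep.artifact_mask[:, 0], expected)
        assert set(spikes) <= set(np.flatnonzero(rep.artifact_mask[:, 0]))

    def test_translation_invariance(self, rng):
        x = rng.normal(0, 1, size=(300, 2))
        a = sliding_window_qc(x, FS)
        b = sliding_window_qc(x + 42.0, FS)
        np.testing.assert_array_equal(a.artifact_mask, b.artifact_mask)

    def test_series_shorter_than_window_errors(self):
        with pytest.raises(ValueError, match="window"):
            sliding_window_qc(np.zeros((10, 1)), FS, QCConfig(window_s=5.0))


class TestTDDR:
    def test_preserves_length_and_zeros(self):
        assert tddr(np.zeros(100), FS).shape == (100,)
        np.testing.assert_allclose(tddr(np.zeros(100), FS), 0.0, atol=1e-14)

    def test_nan_rejected(self):
        x = np.zeros(50)
        x[3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            tddr(x, FS)

    def test_matches_published_reference_implementation(self, rng):
        """Output equals the independent reference implementation of the
        algorithm (iteratively reweighted robust derivative repair)."""
        mne = pytest.importorskip("mne")
        from mne.preprocessing.nirs._tddr import _TDDR

        t = np.arange(0, 120, 1 / FS)
        clean = np.sin(2 * np.pi * 0.05 * t) + 0.001 * t
        noisy = clean + 0.05 * rng.standard_normal(t.size)
        stepped = noisy.copy()
        stepped[600:] += 10 * noisy.std()
        for sig in (clean, noisy, stepped):
            np.testing.assert_allclose(tddr(sig, FS), _TDDR(sig.copy(), FS), atol=1e-6)

    def test_step_artifact_reduced_by_80_percent(self, rng):
        t = np.arange(0, 120, 1 / FS)
        x = np.sin(2 * np.pi * 0.05 * t) + 0.05 * rng.standard_normal(t.size)
        x[600:] += 10 * x.std()
        out = tddr(x, FS)
        step_before = x[600:].mean() - x[:600].mean()
        step_after = out[600:].mean() - out[:600].mean()
        assert abs(step_after) < 0.2 * abs(step_before)

    def test_clean_series_nearly_unchanged(self):
        """A clean oscillation above the repair band plus a small drift
        passes through with < 1% RMS change."""
        t = np.arange(0, 120, 1 / FS)
        x = np.sin(2 * np.pi * 2.0 * t) + 1e-5 * t
        out = tddr(x, FS)
        rms_change = np.sqrt(np.mean((out - x) ** 2))
        assert rms_change < 0.01


class TestDCTHighpass:
    def test_constant_removed_entirely(self):
        out = dct_highpass(np.full(500, 3.0), FS)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_slow_drift_removed(self):
        t = np.arange(0, 600, 1 / FS)
        x = np.sin(2 * np.pi * 0.002 * t)
        out = dct_highpass(x, FS, 0.0078)
        assert np.sqrt(np.mean(out**2)) < 0.1 * np.sqrt(np.mean(x**2))

    def test_passband_preserved(self):
        t = np.arange(0, 600, 1 / FS)
        x = np.sin(2 * np.pi * 0.1 * t)
        out = dct_highpass(x, FS, 0.0078)
        assert np.sqrt(np.mean(out**2)) == pytest.approx(np.sqrt(np.mean(x**2)), rel=0.05)

    def test_idempotent_projection(self, rng):
        x = rng.standard_normal(400)
        once = dct_highpass(x, FS)
        twice = dct_highpass(once, FS)
        np.testing.assert_allclose(twice, once, atol=1e-10)

    def test_matches_explicit_basis_projection(self, rng):
        """Equals brute-force projection onto the retained DCT basis."""
        n = 200
        x = rng.standard_normal(n)
        cutoff = 0.05
        # explicit orthonormal DCT-II basis
        k = np.arange(n)
        basis = np.cos(np.pi * np.outer(k, (2 * np.arange(n) + 1)) / (2 * n))
        basis[0] /= np.sqrt(n)
        basis[1:] *= np.sqrt(2 / n)
        freqs = k * FS / (2 * n)
        proj = basis[freqs >= cutoff].T @ (basis[freqs >= cutoff] @ x)
        np.testing.assert_allclose(dct_highpass(x, FS, cutoff), proj, atol=1e-9)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            dct_highpass(np.zeros(100), FS, cutoff_hz=5.0)


class TestHRFLowpass:
    def test_constant_unchanged(self):
        out = hrf_lowpass(np.full(400, 2.5), FS)
        np.testing.assert_allclose(out, 2.5, rtol=1e-12)

    def test_4hz_attenuated_95_percent(self):
        """Transfer-function magnitude of the kernel at 4 Hz is < 5%."""
        from fnirspeech.hrf import canonical_hrf

        kernel = canonical_hrf(FS, norm="sum")
        freqs = np.fft.rfftfreq(8192, 1 / FS)
        H = np.abs(np.fft.rfft(kernel, 8192))
        gain_4hz = H[np.argmin(np.abs(freqs - 4.0))]
        assert gain_4hz < 0.05
        # and on an actual series
        t = np.arange(0, 60, 1 / FS)
        x = np.sin(2 * np.pi * 4.0 * t)
        out = hrf_lowpass(x, FS)
        assert np.sqrt(np.mean(out[350:] ** 2)) < 0.05 * np.sqrt(0.5)

    def test_white_noise_variance_reduced(self, rng):
        x = rng.standard_normal(2000)
        assert hrf_lowpass(x, FS).var() < x.var()


class TestPipelineProperties:
    def test_linear_stages_commute_with_scaling(self, rng):
        x = rng.standard_normal((300, 2))
        for f in (lambda y: dct_highpass(y, FS), lambda y: hrf_lowpass(y, FS)):
            np.testing.assert_allclose(f(3.0 * x), 3.0 * f(x), rtol=1e-9, atol=1e-12)

    @given(scale=st.floats(0.1, 10.0))
    @settings(deadline=None, max_examples=10)
    def test_mbll_scales_linearly(self, scale):
        rng = np.random.default_rng(7)
        od = rng.standard_normal((20, 2, 2)) * 0.01
        np.testing.assert_allclose(
            mbll(scale * od, fs=FS).hbo, scale * mbll(od, fs=FS).hbo, rtol=1e-9
        )

    def test_thb_identity_after_full_chain(self, mini_sim):
        hb, _ = preprocess_recording(mini_sim.recordings[0], PreprocessConfig())
        np.testing.assert_allclose(hb.thb, hb.hbo + hb.hbr, rtol=1e-12)

    def test_full_preprocess_of_full_length_block_under_30s(self):
        """A 19-minute, 44-channel recording preprocesses in well under 30 s."""
        from fnirspeech.simulate import full_config, simulate_participant

        cfg = full_config()
        cfg.n_blocks = 1
        sim = simulate_participant(cfg, seed=3)
        t0 = time.time()
        hb, qc = preprocess_recording(sim.recordings[0], PreprocessConfig())
        elapsed = time.time() - t0
        assert hb.n_samples == sim.recordings[0].n_samples
        assert elapsed < 30.0
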
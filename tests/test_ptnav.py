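"""Navigator extraction: carrier estimation, filtering, source separation."""

import dataclasses

import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from haptic.io_core import AcquisitionSet, ExtractConfig, SimConfig
from haptic import simulate as sim
from haptic import ptnav
from haptic.ptnav import (ExtractionError, PTChannelWaveforms, bandpass,
                          build_waveforms, detrend_by_angle, estimate_carrier,
                          extract_cardiac, extract_navigators,
                          extract_respiratory, select_channels, sgolay_denoise)


def _tone_acq(freq_hz, amps, n_lines=8, n_samples=64, dwell=1e-6, noise=0.0,
              seed=0):
    """Acquisition whose every line is a pure complex tone per coil."""
    rng = np.random.default_rng(seed)
    tau = np.arange(n_samples) * dwell
    amps = np.asarray(amps, dtype=float)
    samples = amps[None, :, None] * np.exp(2j * np.pi * freq_hz * tau)[None, None, :]
    samples = np.repeat(samples, n_lines, axis=0).astype(complex)
    samples += noise * (rng.standard_normal(samples.shape)
                        + 1j * rng.standard_normal(samples.shape))
    roles = np.array(["imaging"] * len(amps), dtype=object)
    return AcquisitionSet(
        samples=samples, line_time=np.arange(n_lines) * 0.005,
        arm_angle=np.zeros(n_lines), dwell_time=dwell, tr=0.005,
        center_freq_offset_nominal=400e3, coil_role=roles,
        trajectory=np.zeros((n_lines, n_samples, 2)))


class TestEstimateCarrier:
    def test_on_grid_tone_exact(self):
        # 400 kHz is bin 25.6 of a 64-sample/1 MHz readout; use an exact
        # bin inside the search band instead: 406.25 kHz = bin 26
        f = 26 / (64 * 1e-6)
        acq = _tone_acq(f, [1.5, 0.3])
        est = estimate_carrier(acq)
        np.testing.assert_allclose(est.amp[:, 0], 1.5, rtol=1e-10)
        np.testing.assert_allclose(est.amp[:, 1], 0.3, rtol=1e-10)
        np.testing.assert_allclose(est.freq, f, atol=1e-6)

    def test_between_bin_tone_against_bruteforce_grid(self):
        bin_hz = 1 / (64e-6)          # native bin spacing
        f = 400e3 + 0.5 * bin_hz      # exactly between two native bins
        acq = _tone_acq(f, [1.0])
        est = estimate_carrier(acq)
        # oracle: magnitude of the tapered projection on a 1000x
        # oversampled frequency grid
        from scipy.signal.windows import hann
        taper = hann(64, sym=False)
        tau = np.arange(64) * 1e-6
        grid = 400e3 + np.linspace(-1, 1, 2001) * bin_hz
        resp = np.abs((acq.samples[0, 0] * taper)
                      @ np.exp(-2j * np.pi * np.outer(tau, grid)))
        f_oracle = grid[np.argmax(resp)]
        assert abs(f_oracle - f) < 0.02 * bin_hz  # oracle sanity
        assert abs(est.freq[0] - f) < 0.02 * bin_hz

    def test_zero_signal_line_flagged_lost(self):
        acq = _tone_acq(406.25e3, [1.0], n_lines=6, noise=1e-3)
        acq.samples[3] = 1e-3 * (np.random.default_rng(1)
                                 .standard_normal(acq.samples[3].shape))
        est = estimate_carrier(acq)
        assert est.lost[3]
        assert not est.lost[[0, 1, 2, 4, 5]].any()

    def test_lost_lines_interpolated_in_waveform(self):
        acq = _tone_acq(406.25e3, [1.0], n_lines=6, noise=1e-3)
        acq.samples[3] = 0.001
        est = estimate_carrier(acq)
        wf = build_waveforms(est, acq)
        assert wf.value[3, 0] == pytest.approx(
            0.5 * (wf.value[2, 0] + wf.value[4, 0]), rel=1e-9)


class TestDetrendByAngle:
    def _wf(self, values, tr=0.00532):
        t = np.arange(values.shape[0]) * tr
        return PTChannelWaveforms(t=t, value=values, stage="raw")

    def test_pure_angle_function_removed(self, acq):
        theta = acq.arm_angle
        g = np.cos(2 * theta + 0.3) + 0.5 * np.cos(3 * theta)
        wf = self._wf(g[:, None].copy())
        out = detrend_by_angle(wf, theta, max_harmonic=8)
        assert out.value.std() < 0.05 * wf.value.std()

    def test_broadband_motion_preserved(self, truth):
        n = truth.t.size
        theta = np.mod(np.arange(n) * np.deg2rad(137.507764), 2 * np.pi)
        motion = truth.card - truth.card.mean()
        wf = self._wf(motion[:, None].copy())
        out = detrend_by_angle(wf, theta, max_harmonic=8)
        assert np.sqrt(np.mean((out.value - wf.value) ** 2)) \
            < 0.05 * wf.value.std()

    def test_zero_cutoff_is_identity(self, acq):
        rng = np.random.default_rng(3)
        wf = self._wf(rng.standard_normal((acq.n_lines, 2)))
        out = detrend_by_angle(wf, acq.arm_angle, max_harmonic=0)
        np.testing.assert_array_equal(out.value, wf.value)

    def test_sort_unsort_identity_under_disabled_filter(self):
        # the reorder/restore permutation must be exact
        rng = np.random.default_rng(4)
        theta = rng.uniform(0, 2 * np.pi, 500)
        wf = self._wf(rng.standard_normal((500, 3)))
        out = detrend_by_angle(wf, theta, max_harmonic=0)
        np.testing.assert_array_equal(out.value, wf.value)


class TestSavitzkyGolay:
    def test_cubic_polynomial_reproduced(self):
        t = np.arange(400) * 0.005
        y = 2.0 - t + 0.5 * t ** 2 - 0.1 * t ** 3
        wf = PTChannelWaveforms(t=t, value=y[:, None], stage="raw")
        out = sgolay_denoise(wf, 21, 3)
        np.testing.assert_allclose(out.value[10:-10, 0], y[10:-10], atol=1e-9)

    def test_constant_preserved(self):
        t = np.arange(100) * 0.005
        wf = PTChannelWaveforms(t=t, value=np.full((100, 1), 3.7), stage="raw")
        out = sgolay_denoise(wf, 21, 3)
        np.testing.assert_allclose(out.value, 3.7, rtol=1e-12)

    def test_white_noise_variance_matches_analytic_gain(self):
        rng = np.random.default_rng(5)
        t = np.arange(50000) * 0.005
        wf = PTChannelWaveforms(t=t, value=rng.standard_normal((50000, 1)),
                                stage="raw")
        out = sgolay_denoise(wf, 21, 3)
        gain = np.sum(savgol_coeffs(21, 3) ** 2)  # analytic variance gain
        assert out.value.var() == pytest.approx(gain, rel=0.10)

    def test_window_longer_than_record_rejected(self):
        t = np.arange(10) * 0.005
        wf = PTChannelWaveforms(t=t, value=np.zeros((10, 1)), stage="raw")
        with pytest.raises(Exception):
            sgolay_denoise(wf, 21, 3)


class TestBandpass:
    def _tone(self, f, n=16917, tr=0.00532, dc=0.0):
        t = np.arange(n) * tr
        return PTChannelWaveforms(t=t, value=(np.sin(2 * np.pi * f * t) + dc)[:, None],
                                  stage="denoised")

    def test_dc_removed_by_resp_band(self):
        out = bandpass(self._tone(0.5, dc=3.0), (0.05, 0.9))
        assert abs(out.value.mean()) < 1e-6

    def test_half_hertz_tone_passes_resp_blocked_by_card(self):
        tone = self._tone(0.5)
        resp = bandpass(tone, (0.05, 0.9))
        card = bandpass(tone, (1.0, 20.0))
        # amplitude read out by projection onto the tone (the max would
        # include boundary ripple of the whole-record mask)
        t = tone.t[2000:-2000]
        basis = np.exp(2j * np.pi * 0.5 * t)

        def amp(x):
            return 2 * np.abs(np.vdot(basis, x[2000:-2000, 0])) / t.size

        assert 0.99 < amp(resp.value) < 1.01
        assert amp(card.value) < 0.05

    def test_five_hertz_tone_passes_card_band(self):
        card = bandpass(self._tone(5.0), (1.0, 20.0))
        assert 0.99 < np.abs(card.value[2000:-2000, 0]).max() < 1.01

    def test_band_above_nyquist_clipped_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="haptic.ptnav"):
            bandpass(self._tone(5.0, n=4000), (1.0, 200.0))
        assert any("Nyquist" in r.message for r in caplog.records)


class TestSelectChannels:
    def _wf(self, values, tr=0.00532):
        t = np.arange(values.shape[0]) * tr
        return PTChannelWaveforms(t=t, value=values, stage="resp_band")

    def test_identical_channels_all_accepted(self):
        rng = np.random.default_rng(6)
        s = np.sin(2 * np.pi * 0.25 * np.arange(5000) * 0.005)
        x = s[:, None] + 0.01 * rng.standard_normal((5000, 5))
        idx = select_channels(self._wf(x), "resp")
        assert set(idx) == set(range(5))

    def test_noise_channel_excluded(self):
        rng = np.random.default_rng(7)
        s = np.sin(2 * np.pi * 0.25 * np.arange(5000) * 0.005)
        x = s[:, None] * np.ones((1, 5)) + 0.05 * rng.standard_normal((5000, 5))
        x[:, 2] = rng.standard_normal(5000)
        idx = select_channels(self._wf(x), "resp")
        assert 2 not in idx
        assert len(idx) == 4

    def test_cardiac_threshold_sweep_stops_at_085(self):
        # two channels correlate ~0.87 with the seed: rejected at 0.90,
        # accepted at 0.85, so the sweep stops there with 3 channels
        rng = np.random.default_rng(8)
        n = 20000
        s = rng.standard_normal(n)
        r = 0.87
        x = np.empty((n, 4))
        x[:, 0] = s
        for j in (1, 2):
            x[:, j] = r * s + np.sqrt(1 - r * r) * rng.standard_normal(n)
        x[:, 3] = rng.standard_normal(n)       # unrelated
        cfg = ExtractConfig(zero_lag_only=True)
        idx = select_channels(self._wf(x), "card", cfg, seed_channel=0)
        assert set(idx) == {0, 1, 2}

    def test_insufficient_cardiac_channels_raises(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((5000, 3))     # mutually uncorrelated
        cfg = ExtractConfig(zero_lag_only=True)
        with pytest.raises(ExtractionError, match="insufficient"):
            select_channels(self._wf(x), "card", cfg, seed_channel=0)


class TestSourceSeparation:
    def test_sobi_separates_sinusoid_from_noise(self):
        rng = np.random.default_rng(10)
        n, fs = 8000, 100.0
        t = np.arange(n) / fs
        s1 = np.sin(2 * np.pi * 0.25 * t)
        s2 = rng.standard_normal(n)
        mix = np.c_[s1, s2] @ rng.standard_normal((2, 4))
        wf = PTChannelWaveforms(t=t, value=mix, stage="resp_band")
        nav = extract_respiratory(wf, band=(0.05, 0.9))
        assert abs(np.corrcoef(nav, s1)[0, 1]) > 0.99

    def test_rank_one_source_recovered(self):
        rng = np.random.default_rng(11)
        t = np.arange(4000) * 0.01
        s = np.sin(2 * np.pi * 0.2 * t) + 0.3 * np.sin(2 * np.pi * 0.05 * t)
        mix = np.outer(s, [1.0, 0.4, -0.7]) + 1e-4 * rng.standard_normal((4000, 3))
        wf = PTChannelWaveforms(t=t, value=mix, stage="resp_band")
        nav = extract_respiratory(wf, band=(0.05, 0.9))
        assert abs(np.corrcoef(nav, s)[0, 1]) > 0.999

    def test_identical_channels_return_common_waveform(self):
        t = np.arange(3000) * 0.01
        s = np.sin(2 * np.pi * 0.3 * t)
        wf = PTChannelWaveforms(t=t, value=np.tile(s[:, None], (1, 4)),
                                stage="resp_band")
        nav = extract_respiratory(wf, band=(0.05, 0.9))
        assert np.corrcoef(nav, s)[0, 1] > 0.9999
        assert nav.std() == pytest.approx(1.0, rel=1e-9)

    def test_pca_cardiac_rank_one_plus_noise(self):
        rng = np.random.default_rng(12)
        t = np.arange(6000) * 0.005
        s = np.sin(2 * np.pi * 1.2 * t)
        x = np.outer(s, [0.9, 0.5, 1.4]) + 0.05 * rng.standard_normal((6000, 3))
        wf = PTChannelWaveforms(t=t, value=x, stage="card_band")
        nav = extract_cardiac(wf, seed_col=0)
        assert np.corrcoef(nav, s)[0, 1] > 0.99  # seed-oriented positive

    def test_pca_deterministic_on_tied_eigenvalues(self):
        t = np.arange(4000) * 0.005
        a = np.sin(2 * np.pi * 1.0 * t)
        b = np.cos(2 * np.pi * 1.0 * t)   # orthogonal, equal variance
        x = np.c_[a, b]
        wf = PTChannelWaveforms(t=t, value=x, stage="card_band")
        n1 = extract_cardiac(wf, seed_col=0)
        n2 = extract_cardiac(wf, seed_col=0)
        np.testing.assert_array_equal(n1, n2)

    def test_all_zero_channels_rejected(self):
        t = np.arange(1000) * 0.005
        wf = PTChannelWaveforms(t=t, value=np.zeros((1000, 3)), stage="card_band")
        with pytest.raises(ExtractionError):
            extract_cardiac(wf)


class TestEndToEnd:
    def test_scale_invariance_of_navigators_and_triggers(self, acq):
        from haptic.gating import detect_triggers

        nav1, _ = extract_navigators(acq)
        scaled = acq.copy()
        scaled.samples = scaled.samples * 7.3
        nav2, _ = extract_navigators(scaled)
        np.testing.assert_allclose(nav1.card, nav2.card, atol=1e-7)
        np.testing.assert_allclose(nav1.resp, nav2.resp, atol=1e-7)
        fs = 1.0 / acq.tr
        t1 = detect_triggers(nav1.card, fs).event_time
        t2 = detect_triggers(nav2.card, fs).event_time
        np.testing.assert_array_equal(t1, t2)

    def test_channels_reported_as_original_coil_indices(self, acq):
        nav, diag = extract_navigators(acq)
        assert set(diag["resp_channels"]) <= set(acq.imaging_coils.tolist())
        assert set(diag["card_channels"]) <= set(acq.imaging_coils.tolist())
        assert len(diag["card_channels"]) >= 2
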
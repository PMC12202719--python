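"""Interference cancellation: EDITER and the sinusoid-model baseline."""

import dataclasses

import numpy as np
import pytest

from haptic.io_core import AcquisitionSet, CancelConfig, SimConfig, ValidationError
from haptic import simulate as sim
from haptic import cancel as cn


def _acq_from_samples(samples, roles, dwell=1e-6, tr=0.005, f0=400e3):
    n_lines, _, ns = samples.shape
    return AcquisitionSet(
        samples=samples, line_time=np.arange(n_lines) * tr,
        arm_angle=np.zeros(n_lines), dwell_time=dwell, tr=tr,
        center_freq_offset_nominal=f0,
        coil_role=np.array(roles, dtype=object),
        trajectory=np.zeros((n_lines, ns, 2)))


class TestEditerFit:
    def test_proportional_interference_single_tap(self):
        rng = np.random.default_rng(0)
        snif = rng.standard_normal((40, 1, 64)) + 1j * rng.standard_normal((40, 1, 64))
        acq = _acq_from_samples(np.concatenate([2.5 * snif, snif], axis=1),
                                ["imaging", "sniffer"])
        cfg = CancelConfig(window_lines=50, kernel_halfwidth=0, fit_taper=False)
        model = cn.editer_fit(acq, cfg)
        assert abs(model.kernels[0][0][0] - 2.5) < 1e-10
        clean, rep = cn.editer_apply(model, acq)
        resid = np.sum(np.abs(clean.samples[:, 0]) ** 2)
        assert resid / np.sum(np.abs(acq.samples[:, 0]) ** 2) < 1e-10

    def test_known_fir_kernel_suppression(self):
        rng = np.random.default_rng(1)
        snif = rng.standard_normal((60, 1, 64)) + 1j * rng.standard_normal((60, 1, 64))
        h = np.array([0.5 + 0.2j, 1.2 - 0.4j, -0.3 + 0.1j])
        intf = np.stack([np.convolve(snif[l, 0], h, mode="same")
                         for l in range(60)])
        phantom = 0.3 * (rng.standard_normal((60, 64))
                         + 1j * rng.standard_normal((60, 64)))
        acq = _acq_from_samples(np.stack([intf + phantom, snif[:, 0]], axis=1),
                                ["imaging", "sniffer"])
        cfg = CancelConfig(window_lines=60, kernel_halfwidth=3, fit_taper=False)
        model = cn.editer_fit(acq, cfg)
        clean, _ = cn.editer_apply(model, acq)
        resid_int = clean.samples[:, 0] - phantom
        supp = np.sum(np.abs(resid_int) ** 2) / np.sum(np.abs(intf) ** 2)
        assert 10 * np.log10(supp) < -20.0

    def test_two_coupling_states_give_two_clusters(self):
        rng = np.random.default_rng(2)
        snif = rng.standard_normal((100, 1, 64)) + 1j * rng.standard_normal((100, 1, 64))
        img = np.concatenate([2.0 * snif[:50], 5.0 * snif[50:]], axis=0)
        acq = _acq_from_samples(np.concatenate([img, snif], axis=1),
                                ["imaging", "sniffer"])
        cfg = CancelConfig(window_lines=25, kernel_halfwidth=0,
                           group_corr_threshold=0.99, fit_taper=False)
        model = cn.editer_fit(acq, cfg)
        assert model.group_id.max() + 1 == 2
        # and the two clusters correspond to the two halves
        assert len(set(model.group_id[:2])) == 1
        assert len(set(model.group_id[2:])) == 1
        assert model.group_id[0] != model.group_id[2]

    def test_no_sniffer_coils_rejected(self):
        rng = np.random.default_rng(3)
        s = rng.standard_normal((10, 1, 64)) + 0j
        acq = _acq_from_samples(s, ["imaging"])
        with pytest.raises(ValidationError, match="sniffer"):
            cn.editer_fit(acq, CancelConfig())

    def test_unidentifiable_window_rejected(self):
        rng = np.random.default_rng(4)
        s = rng.standard_normal((4, 2, 64)) + 0j
        acq = _acq_from_samples(s, ["imaging", "sniffer"])
        with pytest.raises(ValidationError, match="identify"):
            cn.editer_fit(acq, CancelConfig(window_lines=1, kernel_halfwidth=31,
                                            delta_lines=2))


class TestEditerApply:
    def test_zero_kernels_are_identity(self, acq):
        cfg = CancelConfig()
        model = cn.editer_fit(acq, cfg)
        model.kernels[:] = 0
        clean, rep = cn.editer_apply(model, acq)
        np.testing.assert_array_equal(clean.samples, acq.samples)
        assert np.allclose(rep.residual_db, 0.0)

    def test_zero_sniffer_data_is_identity(self):
        rng = np.random.default_rng(5)
        img = rng.standard_normal((30, 1, 64)) + 1j * rng.standard_normal((30, 1, 64))
        samples = np.concatenate([img, np.zeros_like(img)], axis=1)
        acq = _acq_from_samples(samples, ["imaging", "sniffer"])
        model = cn.editer_fit(acq, CancelConfig(window_lines=30, fit_taper=False))
        clean, _ = cn.editer_apply(model, acq)
        np.testing.assert_allclose(clean.samples, acq.samples, atol=1e-12)

    def test_sniffer_channels_pass_through(self, acq):
        model = cn.editer_fit(acq, CancelConfig())
        clean, _ = cn.editer_apply(model, acq)
        sn = acq.sniffer_coils
        np.testing.assert_array_equal(clean.samples[:, sn], acq.samples[:, sn])

    def test_partition_mismatch_rejected(self, acq):
        model = cn.editer_fit(acq, CancelConfig())
        model.windows = model.windows[:-1]
        with pytest.raises(ValidationError, match="cover"):
            cn.editer_apply(model, acq)

    def test_residual_energy_never_exceeds_input(self, acq):
        """Least-squares projection: per-window residual power <= input
        power on the fitted data."""
        model = cn.editer_fit(acq, CancelConfig())
        _, rep = cn.editer_apply(model, acq)
        assert np.all(rep.residual_db <= 1e-6)


class TestModelSubtract:
    def test_pure_tone_removed_exactly(self):
        tau = np.arange(64) * 1e-6
        tone = 0.8 * np.exp(2j * np.pi * 402e3 * tau + 0.4j)
        samples = np.tile(tone, (30, 1, 1)).astype(complex)
        # include a passthrough sniffer so roles exist
        samples = np.concatenate([samples, samples * 0.5], axis=1)
        acq = _acq_from_samples(samples, ["imaging", "sniffer"])
        clean, rep = cn.model_subtract(acq)
        resid = np.sum(np.abs(clean.samples[:, 0]) ** 2)
        assert resid / np.sum(np.abs(acq.samples[:, 0]) ** 2) < 1e-12

    def test_agrees_with_editer_on_static_tone(self, truth, coupling):
        """Cross-method: both remove a static carrier to numerical noise."""
        cfg = dataclasses.replace(SimConfig(), duration_s=20.0, noise_sd=0.0,
                                  saturation_noise_frac=0.0, phantom_scale=0.0,
                                  m_resp=0.0, m_card=0.0, eddy_amp=0.0,
                                  f_drift_amp_hz=0.0)
        coup = sim.CouplingModel.from_config(cfg, seed=2)
        acq = sim.simulate_acquisitions(truth, coup, cfg, seed=3)
        p_in = np.sum(np.abs(acq.samples[:, acq.imaging_coils]) ** 2)
        model = cn.editer_fit(acq, CancelConfig())
        ce, _ = cn.editer_apply(model, acq)
        cm, _ = cn.model_subtract(acq)
        for clean in (ce, cm):
            p = np.sum(np.abs(clean.samples[:, acq.imaging_coils]) ** 2)
            assert p / p_in < 1e-10

    def test_modulated_tone_leaves_more_residual_than_static(self, truth):
        base = dataclasses.replace(SimConfig(), duration_s=20.0, noise_sd=0.0,
                                   saturation_noise_frac=0.0, phantom_scale=0.0,
                                   eddy_amp=0.0, f_drift_amp_hz=0.0)
        static_cfg = dataclasses.replace(base, m_resp=0.0, m_card=0.0)
        mod_cfg = dataclasses.replace(base, m_resp=0.3, m_card=0.05)
        resid = {}
        for name, cfg in (("static", static_cfg), ("mod", mod_cfg)):
            coup = sim.CouplingModel.from_config(cfg, seed=2)
            acq = sim.simulate_acquisitions(truth, coup, cfg, seed=3)
            clean, _ = cn.model_subtract(acq)
            resid[name] = (np.sum(np.abs(clean.samples[:, acq.imaging_coils]) ** 2)
                           / np.sum(np.abs(acq.samples[:, acq.imaging_coils]) ** 2))
        assert resid["mod"] > 100 * resid["static"]

    def test_lost_lines_left_unmodified(self):
        tau = np.arange(64) * 1e-6
        tone = np.exp(2j * np.pi * 402e3 * tau)
        samples = np.tile(tone, (10, 2, 1)).astype(complex)
        acq = _acq_from_samples(samples, ["imaging", "sniffer"])
        lost = np.zeros(10, dtype=bool)
        lost[4] = True
        clean, rep = cn.model_subtract(acq, lost_mask=lost)
        assert rep.skipped_lines == 1
        np.testing.assert_array_equal(clean.samples[4], acq.samples[4])
        assert np.abs(clean.samples[5, 0]).max() < 1e-6
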
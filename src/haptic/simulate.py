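"""Synthetic golden-angle spiral acquisitions with a pilot-tone carrier.

Every downstream stage (carrier estimation, detrending, source
separation, interference cancellation, trigger detection, gating,
reconstruction) is exercised against data from this module, which
carries full physiological ground truth.

Physical model
--------------
Each readout line ``l`` of coil ``c`` receives

``x_c(l, tau) = phantom_c(l, tau) + A_c(t_l) * exp(i*(2*pi*f(t)*(t_l+tau) + phi_c)) + n``

where the per-coil carrier amplitude is modulated by respiration and
the cardiac cycle plus a smooth spiral-angle-dependent (eddy-current
like) deviation::

    A_c(t) = V * a0_c * (1 + m_resp_c * r(t) + m_card_c * card(t) + eddy * g(theta))

``V`` is the transmit-amplitude analog of the signal-generator voltage
setting.  The carrier frequency ``f(t)`` drifts slowly because the
generator is not synchronised to the receiver clock; the carrier phase
is coherent (the integral of the instantaneous frequency) but is never
used downstream — only amplitude modulations are.

Sniffer coils see the carrier through their coupling gains and receiver
noise, but no phantom signal and (being distant) no motion modulation.
High transmit amplitudes additionally raise a receiver-local noise
floor (saturation/quantisation leakage), modelled as white complex
noise with SD proportional to ``V * a0_c`` per coil.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.special import j1

from .io_core import AcquisitionSet, SimConfig, TriggerSeries, ValidationError

__all__ = [
    "PhysioTruth",
    "CouplingModel",
    "Ellipse",
    "gen_physio",
    "simulate_acquisitions",
    "gen_phantom",
    "default_phantom",
    "phantom_kspace",
    "phantom_image",
    "spiral_trajectory",
]


# ---------------------------------------------------------------------------
# Physiological ground truth
# ---------------------------------------------------------------------------


@dataclass
class PhysioTruth:
    """Ground-truth motion waveforms sampled on the TR grid.

    ``resp`` is a unitless respiratory waveform in [-1, 1]; ``card`` is
    the unitless cardiac waveform built from per-beat pulse templates
    placed at ``beat_time``.
    """

    t: np.ndarray
    resp: np.ndarray
    card: np.ndarray
    beat_time: np.ndarray
    rhythm: str = "regular"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.resp = np.asarray(self.resp, dtype=np.float64)
        self.card = np.asarray(self.card, dtype=np.float64)
        self.beat_time = np.asarray(self.beat_time, dtype=np.float64)
        if self.resp.shape != self.t.shape or self.card.shape != self.t.shape:
            raise ValidationError("waveform/grid shape mismatch")
        if np.max(np.abs(self.resp), initial=0.0) > 1.0 + 1e-12:
            raise ValidationError("respiratory waveform must lie in [-1, 1]")

    @property
    def beat_triggers(self) -> TriggerSeries:
        return TriggerSeries(event_time=self.beat_time, source="truth")

    def cardiac_phase(self, t: np.ndarray) -> np.ndarray:
        """True cardiac phase in [0, 1) per time point; NaN outside any
        RR interval."""
        t = np.asarray(t)
        phase = np.full(t.shape, np.nan)
        k = np.searchsorted(self.beat_time, t, side="right") - 1
        ok = (k >= 0) & (k < len(self.beat_time) - 1)
        kk = k[ok]
        rr = self.beat_time[kk + 1] - self.beat_time[kk]
        phase[ok] = (t[ok] - self.beat_time[kk]) / rr
        return phase


def _cardiac_template(tau: np.ndarray, t_peak: float = 0.08, order: float = 2.0
                      ) -> np.ndarray:
    """Asymmetric gamma-like pulse: fast upstroke peaking at ``t_peak``
    seconds after beat onset, slow decay, unit peak amplitude."""
    out = np.zeros_like(tau)
    pos = tau > 0
    x = tau[pos] / t_peak
    out[pos] = x ** order * np.exp(order * (1.0 - x))
    return out


def gen_physio(duration_s: float, tr_s: float, heart_rate_bpm: float = 60.0,
               hr_jitter_frac: float = 0.03, resp_rate_hz: float = 0.25,
               resp_amplitude: float = 1.0, rhythm: str = "regular",
               arrhythmia_rate: float = 0.15, seed: int | np.random.SeedSequence = 0,
               ) -> PhysioTruth:
    """Generate respiratory and cardiac ground truth.

    The cardiac waveform is a train of gamma-like pulse templates at
    beat onsets with fractional RR jitter; arrhythmic mode inserts
    skipped and ectopic beats at rate ``arrhythmia_rate`` per beat.
    The respiratory waveform is a quasi-sinusoid with slow amplitude
    drift, bounded in [-1, 1].  Identical seeds give identical output.
    """
    if duration_s < 10:
        raise ValidationError("duration must be >= 10 s")
    if not (30.0 <= heart_rate_bpm <= 162.0):
        raise ValidationError("heart rate outside the 0.5-2.7 Hz design range")
    if not (0.05 <= resp_rate_hz <= 0.9):
        raise ValidationError("respiratory rate outside the 0.05-0.9 Hz band")
    if rhythm not in ("regular", "arrhythmic"):
        raise ValidationError(f"unknown rhythm {rhythm!r}")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s / tr_s))
    t = np.arange(n) * tr_s

    base_rr = 60.0 / heart_rate_bpm
    beats = []
    t_beat = rng.uniform(0.2, 0.6)
    while t_beat < duration_s:
        beats.append(t_beat)
        rr = base_rr * (1.0 + hr_jitter_frac * rng.standard_normal())
        rr = max(rr, 0.40)
        if rhythm == "arrhythmic":
            u = rng.uniform()
            if u < arrhythmia_rate / 2:
                rr *= 2.0            # skipped beat
            elif u < arrhythmia_rate:
                rr *= 0.55           # ectopic (early) beat
                rr = max(rr, 0.40)
        t_beat += rr
    beat_time = np.array(beats)

    card = np.zeros(n)
    half_window = 1.2  # template support after onset, seconds
    for tb in beat_time:
        i0 = max(0, int(np.ceil(tb / tr_s)))
        i1 = min(n, int(np.ceil((tb + half_window) / tr_s)))
        card[i0:i1] += _cardiac_template(t[i0:i1] - tb)

    phi0, phi1 = rng.uniform(0, 2 * np.pi, size=2)
    envelope = 0.85 + 0.10 * np.sin(2 * np.pi * 0.013 * t + phi1)
    resp = resp_amplitude * envelope * np.sin(2 * np.pi * resp_rate_hz * t + phi0)
    resp += resp_amplitude * 0.04 * np.sin(2 * np.pi * 0.011 * t + phi1 / 2)
    resp = np.clip(resp, -1.0, 1.0)

    return PhysioTruth(t=t, resp=resp, card=card, beat_time=beat_time, rhythm=rhythm)


# ---------------------------------------------------------------------------
# Coupling model
# ---------------------------------------------------------------------------


@dataclass
class CouplingModel:
    """Per-coil coupling of the pilot-tone carrier and motion.

    ``a0`` is the per-coil baseline carrier gain (unitless; the
    transmit-amplitude analog multiplies it), ``m_resp``/``m_card`` are
    per-coil modulation depths, ``phase`` the per-coil carrier phase.
    ``eddy_amp`` scales a zero-mean band-limited periodic function of
    the spiral arm angle (harmonics 1..``eddy_order``) shared by all
    coils, emulating trajectory-dependent amplitude deviations.
    """

    a0: np.ndarray
    m_resp: np.ndarray
    m_card: np.ndarray
    phase: np.ndarray
    coil_role: np.ndarray
    eddy_amp: float = 0.0
    eddy_order: int = 3
    eddy_phases: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.a0 = np.asarray(self.a0, dtype=np.float64)
        self.m_resp = np.asarray(self.m_resp, dtype=np.float64)
        self.m_card = np.asarray(self.m_card, dtype=np.float64)
        self.phase = np.asarray(self.phase, dtype=np.float64)
        self.coil_role = np.asarray(self.coil_role, dtype=object)
        self.eddy_phases = np.asarray(self.eddy_phases, dtype=np.float64)
        if np.any(np.abs(self.m_resp) + np.abs(self.m_card) >= 1.0):
            raise ValidationError("|m_resp| + |m_card| must stay below 1")

    @property
    def n_coils(self) -> int:
        return self.a0.size

    def eddy(self, theta: np.ndarray) -> np.ndarray:
        """Zero-mean smooth periodic angle deviation g(theta), unit scale."""
        theta = np.asarray(theta)
        g = np.zeros_like(theta, dtype=float)
        for k in range(1, self.eddy_order + 1):
            g += np.cos(k * theta + self.eddy_phases[(k - 1) % len(self.eddy_phases)]) / k
        return g / max(self.eddy_order, 1)

    @classmethod
    def from_config(cls, cfg: SimConfig, seed: int | np.random.SeedSequence = 0
                    ) -> "CouplingModel":
        """Draw a realistic coupling: imaging coils share the modulation
        sign with coil-to-coil depth variation; sniffer coils carry the
        carrier but no motion modulation."""
        rng = np.random.default_rng(seed)
        n = cfg.n_imaging + cfg.n_sniffer
        role = np.array(["imaging"] * cfg.n_imaging + ["sniffer"] * cfg.n_sniffer,
                        dtype=object)
        # sniffer elements sit nearest the rear-mounted transmit antenna,
        # so they couple to the carrier more strongly than imaging coils;
        # strong sniffer coupling keeps the cancellation kernels small and
        # limits sniffer-noise injection into the cleaned data
        a0 = np.where(role == "imaging",
                      rng.uniform(0.7, 1.3, size=n),
                      rng.uniform(1.5, 2.5, size=n))
        m_resp = np.where(role == "imaging",
                          cfg.m_resp * rng.uniform(0.6, 1.4, size=n), 0.0)
        m_card = np.where(role == "imaging",
                          cfg.m_card * rng.uniform(0.6, 1.4, size=n), 0.0)
        phase = rng.uniform(0, 2 * np.pi, size=n)
        return cls(a0=a0, m_resp=m_resp, m_card=m_card, phase=phase,
                   coil_role=role, eddy_amp=cfg.eddy_amp, eddy_order=cfg.eddy_order,
                   eddy_phases=rng.uniform(0, 2 * np.pi, size=max(cfg.eddy_order, 1)))


# ---------------------------------------------------------------------------
# Analytic ellipse phantom
# ---------------------------------------------------------------------------


@dataclass
class Ellipse:
    """One phantom ellipse: intensity, semi-axes and centre in FOV
    units (metres), rotation in radians."""

    intensity: float
    a: float
    b: float
    x0: float = 0.0
    y0: float = 0.0
    theta: float = 0.0


def default_phantom(fov: float = 0.3) -> list[Ellipse]:
    """A Shepp-Logan-like torso stand-in: body ellipse, a 'heart' disc
    and two smaller features."""
    s = fov / 2
    return [
        Ellipse(1.0, 0.75 * s, 0.55 * s, 0.0, 0.0, 0.2),
        Ellipse(0.8, 0.22 * s, 0.20 * s, -0.15 * s, 0.10 * s, 0.0),
        Ellipse(-0.4, 0.10 * s, 0.16 * s, 0.25 * s, -0.05 * s, 0.5),
        Ellipse(0.5, 0.07 * s, 0.07 * s, 0.05 * s, -0.30 * s, 0.0),
    ]


def _jinc(rho: np.ndarray) -> np.ndarray:
    """2*J1(2*pi*rho)/(2*pi*rho) with the rho -> 0 limit of 1."""
    out = np.ones_like(rho)
    nz = rho > 1e-12
    x = 2 * np.pi * rho[nz]
    out[nz] = 2.0 * j1(x) / x
    return out


def phantom_kspace(ellipses: list[Ellipse], k: np.ndarray) -> np.ndarray:
    """Analytic Fourier transform of the ellipse set at k-space points.

    ``k``: (..., 2) in cycles per metre.  The DC value equals the total
    integrated intensity ``sum(rho * pi * a * b)``.
    """
    k = np.asarray(k, dtype=np.float64)
    kx, ky = k[..., 0], k[..., 1]
    out = np.zeros(kx.shape, dtype=np.complex128)
    for e in ellipses:
        c, s = np.cos(e.theta), np.sin(e.theta)
        kxp = c * kx + s * ky
        kyp = -s * kx + c * ky
        rho = np.sqrt((e.a * kxp) ** 2 + (e.b * kyp) ** 2)
        area = np.pi * e.a * e.b
        out += (e.intensity * area * _jinc(rho)
                * np.exp(-2j * np.pi * (kx * e.x0 + ky * e.y0)))
    return out


def phantom_image(ellipses: list[Ellipse], grid_size: int, fov: float) -> np.ndarray:
    """Rasterised reference image of the ellipse set (pixel centres)."""
    x = (np.arange(grid_size) - grid_size / 2 + 0.5) * (fov / grid_size)
    X, Y = np.meshgrid(x, x, indexing="xy")
    img = np.zeros((grid_size, grid_size))
    for e in ellipses:
        c, s = np.cos(e.theta), np.sin(e.theta)
        xp = c * (X - e.x0) + s * (Y - e.y0)
        yp = -s * (X - e.x0) + c * (Y - e.y0)
        img += e.intensity * ((xp / e.a) ** 2 + (yp / e.b) ** 2 <= 1.0)
    return img


def gen_phantom(cfg: SimConfig) -> tuple[np.ndarray, list[Ellipse]]:
    """Reference image and ellipse list for the configured geometry."""
    ell = default_phantom(cfg.fov)
    return phantom_image(ell, cfg.grid_size, cfg.fov), ell


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------


def spiral_trajectory(n_lines: int, n_samples: int, fov: float, grid_size: int,
                      turns: float, golden_angle_deg: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Golden-angle rotated Archimedean spiral arms.

    Returns ``(trajectory, arm_angle)`` with trajectory in cycles per
    metre, shape (n_lines, n_samples, 2), radius growing linearly to
    ``grid_size / (2 * fov)``.
    """
    kmax = grid_size / (2.0 * fov)
    s = np.arange(n_samples) / max(n_samples - 1, 1)
    radius = kmax * s
    base_ang = 2 * np.pi * turns * s
    ga = np.deg2rad(golden_angle_deg)
    arm_angle = np.mod(np.arange(n_lines) * ga, 2 * np.pi)
    ang = arm_angle[:, None] + base_ang[None, :]
    traj = np.stack([radius[None, :] * np.cos(ang),
                     radius[None, :] * np.sin(ang)], axis=-1)
    return traj, arm_angle


# ---------------------------------------------------------------------------
# Acquisition synthesis
# ---------------------------------------------------------------------------


def carrier_amplitude(truth: PhysioTruth, coupling: CouplingModel,
                      arm_angle: np.ndarray, pt_amplitude: float,
                      tau_offset: float = 0.0) -> np.ndarray:
    """Closed-form noiseless per-line, per-coil carrier amplitude
    A_c(t): the quantity carrier estimation must recover.

    ``tau_offset`` evaluates the physiological modulation that far into
    the readout (the simulator evolves it linearly between TR samples;
    the eddy term is trajectory-locked and constant within a readout).
    """
    g = coupling.eddy(arm_angle)
    resp, card = truth.resp, truth.card
    if tau_offset != 0.0:
        tr = truth.t[1] - truth.t[0] if truth.t.size > 1 else 1.0
        frac = tau_offset / tr
        resp = resp + frac * np.diff(resp, append=resp[-1:])
        card = card + frac * np.diff(card, append=card[-1:])
    mod = (1.0
           + coupling.m_resp[None, :] * resp[:, None]
           + coupling.m_card[None, :] * card[:, None]
           + coupling.eddy_amp * g[:, None])
    return pt_amplitude * coupling.a0[None, :] * mod


def simulate_acquisitions(truth: PhysioTruth, coupling: CouplingModel,
                          cfg: SimConfig, noise_only: bool = False,
                          pt_amplitude: float | None = None,
                          seed: int | np.random.SeedSequence = 0,
                          ) -> AcquisitionSet:
    """Synthesise a raw multi-coil acquisition.

    ``noise_only`` drops the phantom signal (no excitation) while the
    carrier and noise remain, emulating a noise-only scan with the same
    acquisition parameters.  ``pt_amplitude`` overrides the configured
    transmit-amplitude analog (0 disables the carrier entirely).
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    amp = cfg.pt_amplitude if pt_amplitude is None else float(pt_amplitude)

    n_lines = truth.t.size
    n_coils = coupling.n_coils
    n_samples = cfg.n_samples
    tau = np.arange(n_samples) * cfg.dwell_time_s

    traj, arm_angle = spiral_trajectory(
        n_lines, n_samples, cfg.fov, cfg.grid_size, cfg.spiral_turns,
        cfg.golden_angle_deg)

    samples = np.zeros((n_lines, n_coils, n_samples), dtype=np.complex128)

    # -- desired phantom signal on imaging coils ----------------------
    imaging = np.flatnonzero(coupling.coil_role == "imaging")
    if not noise_only and cfg.phantom_scale > 0:
        _, ellipses = gen_phantom(cfg)
        ksig = phantom_kspace(ellipses, traj) * cfg.phantom_scale
        gains = rng.uniform(0.8, 1.2, size=imaging.size)
        for g_c, c in zip(gains, imaging):
            samples[:, c, :] += g_c * ksig

    # -- pilot-tone carrier -------------------------------------------
    if amp > 0:
        # physiological amplitude modulation evolves continuously: linear
        # within each readout between the TR-grid samples
        a_start = carrier_amplitude(truth, coupling, arm_angle, amp)
        a_end = carrier_amplitude(truth, coupling, arm_angle, amp,
                                  tau_offset=cfg.tr_s)
        frac = tau / cfg.tr_s
        a_line = (a_start[:, :, None]
                  + (a_end - a_start)[:, :, None] * frac[None, None, :])
        # slowly drifting carrier frequency; phase coherent across lines
        drift = cfg.f_drift_amp_hz * np.sin(
            2 * np.pi * cfg.f_drift_cycles * truth.t / max(truth.t[-1], 1e-9))
        f_inst = cfg.f_offset_hz + drift
        # carrier phase at readout start: integral of instantaneous freq
        phase0 = 2 * np.pi * np.concatenate(
            [[0.0], np.cumsum(f_inst[:-1] * np.diff(truth.t))])
        phase = (phase0[:, None, None]
                 + 2 * np.pi * f_inst[:, None, None] * tau[None, None, :]
                 + coupling.phase[None, :, None])
        samples += a_line * np.exp(1j * phase)

    # -- noise ---------------------------------------------------------
    if cfg.noise_sd > 0:
        samples += cfg.noise_sd * (
            rng.standard_normal(samples.shape)
            + 1j * rng.standard_normal(samples.shape))
    if amp > 0 and cfg.saturation_noise_frac > 0:
        # receiver-local PT-induced noise floor (uncancellable)
        sd = cfg.saturation_noise_frac * amp * coupling.a0
        samples += sd[None, :, None] * (
            rng.standard_normal(samples.shape)
            + 1j * rng.standard_normal(samples.shape))

    return AcquisitionSet(
        samples=samples,
        line_time=truth.t.copy(),
        arm_angle=arm_angle,
        dwell_time=cfg.dwell_time_s,
        tr=cfg.tr_s,
        center_freq_offset_nominal=cfg.f_offset_hz,
        coil_role=coupling.coil_role.copy(),
        trajectory=traj,
    )
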
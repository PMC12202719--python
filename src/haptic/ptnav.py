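"""Pilot-tone navigator extraction.

Turns raw multi-coil readouts into one respiratory and one cardiac
navigator: per-line carrier frequency/amplitude estimation, spiral-angle
reordering with an angular low-pass detrend, Savitzky-Golay denoising,
whole-record band-pass splitting, cross-correlation channel selection,
SOBI (respiratory) and PCA (cardiac) source separation.

All filtering here is retrospective (non-causal): band-pass masks act on
the Fourier transform of the whole record, and the source separations
use the full time span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter
from scipy.signal.windows import hann

from .io_core import AcquisitionSet, ExtractConfig, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CarrierEstimate",
    "PTChannelWaveforms",
    "PhysioNavigators",
    "ExtractionError",
    "estimate_carrier",
    "build_waveforms",
    "detrend_by_angle",
    "sgolay_denoise",
    "bandpass",
    "select_channels",
    "extract_respiratory",
    "extract_cardiac",
    "extract_navigators",
]


class ExtractionError(RuntimeError):
    """Navigator extraction cannot proceed (e.g. too few usable coils)."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class CarrierEstimate:
    """Per-line refined carrier frequency and per-coil amplitude.

    ``lost`` flags lines where no spectral peak cleared the SNR floor
    inside the search band; their amplitudes are interpolated from
    neighbours when the raw waveform is built.
    """

    freq: np.ndarray          # (n_lines,) Hz
    amp: np.ndarray           # (n_lines, n_coils), >= 0
    lost: np.ndarray          # (n_lines,) bool


@dataclass
class PTChannelWaveforms:
    """Per-coil pilot-tone amplitude time series, one sample per TR."""

    t: np.ndarray             # (n,) seconds, strictly increasing
    value: np.ndarray         # (n, n_channels)
    stage: str = "raw"        # raw | detrended | denoised | resp_band | card_band
    coil_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.value = np.atleast_2d(np.asarray(self.value, dtype=np.float64))
        if self.value.shape[0] != self.t.size:
            raise ValidationError("waveform/time length mismatch")
        if not np.all(np.isfinite(self.value)):
            raise ValidationError("waveform values must be finite")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("waveform times must be strictly increasing")
        if self.coil_indices.size == 0:
            self.coil_indices = np.arange(self.value.shape[1])

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    def with_values(self, value: np.ndarray, stage: str) -> "PTChannelWaveforms":
        return PTChannelWaveforms(t=self.t, value=value, stage=stage,
                                  coil_indices=self.coil_indices.copy())


@dataclass
class PhysioNavigators:
    """Unit-variance respiratory and cardiac navigators with the coil
    sets they were extracted from."""

    t: np.ndarray
    resp: np.ndarray
    card: np.ndarray
    resp_channels: np.ndarray
    card_channels: np.ndarray


# ---------------------------------------------------------------------------
# Carrier estimation
# ---------------------------------------------------------------------------


def _parabolic_refine(logmag: np.ndarray, idx: int) -> float:
    """Sub-bin peak offset from quadratic interpolation of log-magnitude."""
    if idx <= 0 or idx >= logmag.size - 1:
        return 0.0
    y0, y1, y2 = logmag[idx - 1], logmag[idx], logmag[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return 0.0
    delta = 0.5 * (y0 - y2) / denom
    return float(np.clip(delta, -0.5, 0.5))


def estimate_carrier(acq: AcquisitionSet,
                     search_halfwidth_hz: float = 50e3,
                     zero_pad_factor: int = 4,
                     snr_floor: float = 5.0,
                     chunk_lines: int = 2048) -> CarrierEstimate:
    """Estimate the carrier per k-space line: first frequency, then
    amplitude.

    Frequency: the coil-combined (summed per-coil magnitude) zero-padded
    spectrum of each line is peak-searched inside
    ``nominal +/- search_halfwidth_hz`` and refined to sub-bin precision
    by quadratic interpolation of the log-magnitude.  Amplitude: the
    magnitude of each coil's single-frequency correlation with the
    refined complex exponential, normalised by the sample count.

    Lines whose in-band peak fails to exceed ``snr_floor`` times the
    median in-band level are flagged ``lost``.

    Both the spectrum and the amplitude correlation use a Hann taper:
    the desired imaging signal occupies the low-frequency part of each
    readout, and the taper's sidelobe suppression keeps its leakage out
    of the carrier estimate (a rectangular window would fold
    angle-dependent imaging content into the navigator as broadband
    noise).
    """
    if acq.n_samples < 32:
        raise ValidationError("need >= 32 samples per readout")
    n_samples = acq.n_samples
    nfft = int(zero_pad_factor) * n_samples
    freqs = np.fft.fftfreq(nfft, d=acq.dwell_time)
    f0 = acq.center_freq_offset_nominal
    band = np.flatnonzero(np.abs(freqs - f0) <= search_halfwidth_hz)
    if band.size < 3:
        raise ValidationError("search band does not contain the nominal offset")
    tau = acq.sample_times
    bin_hz = 1.0 / (nfft * acq.dwell_time)
    taper = hann(n_samples, sym=False)
    taper_sum = taper.sum()

    freq = np.empty(acq.n_lines)
    amp = np.empty((acq.n_lines, acq.n_coils))
    lost = np.zeros(acq.n_lines, dtype=bool)

    for start in range(0, acq.n_lines, chunk_lines):
        sl = slice(start, min(start + chunk_lines, acq.n_lines))
        spec = np.abs(np.fft.fft(acq.samples[sl] * taper[None, None, :],
                                 n=nfft, axis=-1))
        combined = spec.sum(axis=1)               # (chunk, nfft)
        in_band = combined[:, band]
        peak_rel = np.argmax(in_band, axis=1)
        peak_idx = band[peak_rel]
        floor = np.median(in_band, axis=1)
        lost[sl] = in_band[np.arange(in_band.shape[0]), peak_rel] < snr_floor * floor

        logmag = np.log(np.maximum(combined, 1e-300))
        f_chunk = np.empty(in_band.shape[0])
        for i, pidx in enumerate(peak_idx):
            delta = _parabolic_refine(logmag[i], int(pidx))
            f_chunk[i] = freqs[pidx] + delta * bin_hz
        freq[sl] = f_chunk

        basis = taper[None, :] * np.exp(-2j * np.pi * f_chunk[:, None] * tau[None, :])
        amp[sl] = np.abs(np.einsum("lcs,ls->lc", acq.samples[sl], basis)) / taper_sum

    return CarrierEstimate(freq=freq, amp=amp, lost=lost)


def build_waveforms(est: CarrierEstimate, acq: AcquisitionSet,
                    coils: np.ndarray | None = None) -> PTChannelWaveforms:
    """Raw pilot-tone waveforms: the per-TR carrier amplitude per coil.

    Carrier-lost lines are linearly interpolated so the uniform-TR
    sampling assumed by the filters downstream holds.
    """
    coils = np.asarray(coils if coils is not None else np.arange(acq.n_coils))
    value = est.amp[:, coils].copy()
    if est.lost.any():
        good = ~est.lost
        if not good.any():
            raise ExtractionError("carrier lost on every line")
        idx = np.arange(value.shape[0])
        for j in range(value.shape[1]):
            value[est.lost, j] = np.interp(idx[est.lost], idx[good], value[good, j])
    return PTChannelWaveforms(t=acq.line_time.copy(), value=value, stage="raw",
                              coil_indices=coils)


# ---------------------------------------------------------------------------
# Detrending / denoising / band splitting
# ---------------------------------------------------------------------------


def detrend_by_angle(wf: PTChannelWaveforms, arm_angle: np.ndarray,
                     max_harmonic: int = 8) -> PTChannelWaveforms:
    """Remove spiral-angle-dependent amplitude deviations.

    Samples are reordered by arm angle (stable; ties broken by time), a
    zero-phase angular low-pass — a Fourier mask keeping harmonics
    ``1..max_harmonic`` of the angle-ordered axis — estimates the
    angle-dependent component, which is subtracted before restoring
    chronological order.  The mean (harmonic 0) is preserved, and
    ``max_harmonic = 0`` disables the filter entirely (identity).
    """
    arm_angle = np.asarray(arm_angle)
    if arm_angle.shape[0] != wf.t.size:
        raise ValidationError("arm_angle must cover every line")
    if max_harmonic <= 0:
        return wf.with_values(wf.value.copy(), "detrended")

    n = wf.t.size
    n_distinct = np.unique(arm_angle).size
    k = min(int(max_harmonic), max((n_distinct - 1) // 2, 0))
    if k < max_harmonic:
        logger.warning("angular low-pass shortened to %d harmonics "
                       "(only %d distinct angles)", k, n_distinct)
    order = np.lexsort((np.arange(n), arm_angle))

    out_sorted = np.empty_like(wf.value)
    for j in range(wf.value.shape[1]):
        y = wf.value[order, j]
        spec = np.fft.rfft(y)
        mask = np.zeros(spec.size)
        mask[1:k + 1] = 1.0          # remove harmonics 1..k only; DC preserved
        eddy_sorted = np.fft.irfft(spec * mask, n=n)
        out_sorted[:, j] = y - eddy_sorted
    out = np.empty_like(out_sorted)
    out[order] = out_sorted           # back to chronological order
    return wf.with_values(out, "detrended")


def sgolay_denoise(wf: PTChannelWaveforms, window_length: int = 21,
                   polyorder: int = 3) -> PTChannelWaveforms:
    """Savitzky-Golay least-squares polynomial smoothing per coil."""
    if window_length % 2 == 0 or window_length <= polyorder:
        raise ValidationError("window_length must be odd and exceed polyorder")
    if window_length >= wf.t.size:
        raise ValidationError("window_length must be shorter than the record")
    out = savgol_filter(wf.value, window_length, polyorder, axis=0, mode="interp")
    return wf.with_values(out, "denoised")


def band_mask(n: int, fs: float, band: tuple[float, float],
              transition_frac: float = 0.2) -> np.ndarray:
    """Raised-cosine band-pass mask over rfft frequencies; DC always 0."""
    f_lo, f_hi = band
    nyq = fs / 2
    if f_hi > nyq:
        logger.warning("band upper edge %.3g Hz clipped to Nyquist %.3g Hz",
                       f_hi, nyq)
        f_hi = nyq
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    tw_lo = transition_frac * f_lo
    tw_hi = transition_frac * f_hi
    # rising edge centred at f_lo, falling edge centred at f_hi
    if tw_lo > 0:
        up = np.clip((freqs - (f_lo - tw_lo)) / (2 * tw_lo), 0, 1)
        mask = 0.5 * (1 - np.cos(np.pi * up))
    else:
        mask = (freqs >= f_lo).astype(float)
    if tw_hi > 0:
        down = np.clip((freqs - (f_hi - tw_hi)) / (2 * tw_hi), 0, 1)
        mask *= 0.5 * (1 + np.cos(np.pi * down))
    else:
        mask *= (freqs <= f_hi).astype(float)
    mask[0] = 0.0
    return mask


def bandpass(wf: PTChannelWaveforms, band: tuple[float, float],
             transition_frac: float = 0.2, stage: str | None = None
             ) -> PTChannelWaveforms:
    """Whole-record frequency-domain band-pass (zero-phase, mean
    removed): a raised-cosine mask applied to the Fourier transform of
    the full waveform.

    The record is mirror-extended before the transform so the periodic
    wrap is continuous; without this, the strong low-frequency
    respiratory component leaks broadband tails into the cardiac band
    at a level comparable to the (much weaker) cardiac modulation.
    """
    f_lo, _ = band
    n = wf.t.size
    if n / wf.fs < 10.0 / max(f_lo, 1e-9):
        logger.warning("record length %.1f s is short for a %.3g Hz low edge",
                       n / wf.fs, f_lo)
    ext = np.concatenate([wf.value, wf.value[::-1]], axis=0)
    mask = band_mask(2 * n, wf.fs, band, transition_frac)
    spec = np.fft.rfft(ext, axis=0)
    out = np.fft.irfft(spec * mask[:, None], n=2 * n, axis=0)[:n]
    return wf.with_values(out, stage or f"band_{band[0]:g}_{band[1]:g}")


# ---------------------------------------------------------------------------
# Channel selection
# ---------------------------------------------------------------------------


def _lagged_corr_matrix(x: np.ndarray, max_lag: int, zero_lag_only: bool = False
                        ) -> np.ndarray:
    """Pairwise peak normalised cross-correlation within +/- max_lag
    samples (signed maximum over lags)."""
    n, c = x.shape
    xs = x - x.mean(axis=0)
    sd = xs.std(axis=0)
    sd[sd == 0] = np.inf
    xs = xs / sd
    if zero_lag_only or max_lag == 0:
        return (xs.T @ xs) / n
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    X = np.fft.rfft(xs, n=nfft, axis=0)
    corr = np.empty((c, c))
    lags = np.r_[np.arange(0, max_lag + 1), np.arange(nfft - max_lag, nfft)]
    for i in range(c):
        cc = np.fft.irfft(X[:, i:i + 1].conj() * X, n=nfft, axis=0) / n
        corr[i] = cc[lags].max(axis=0)
    return corr


def select_channels(wf: PTChannelWaveforms, mode: str,
                    cfg: ExtractConfig | None = None,
                    seed_channel: int | str | None = None) -> np.ndarray:
    """Pick the coil subset carrying coherent physiological modulation.

    Respiratory mode: the channel with the highest total correlation to
    the others seeds the set; channels correlating above the threshold
    (default 0.9) with it are accepted.  Cardiac mode: a seed channel
    (given, or ``"auto"`` = highest band-limited power) is fixed and the
    threshold sweeps 0.90 down to 0.50 in 0.05 steps, stopping at the
    first threshold accepting at least ``card_min_channels`` channels;
    if never reached, the final-threshold set is returned provided it
    has at least ``card_final_min_channels`` members.

    Returns positional indices into ``wf.value`` columns.
    """
    cfg = cfg or ExtractConfig()
    x = wf.value
    n, c = x.shape
    if c < 2:
        raise ExtractionError("channel selection needs >= 2 coils")
    fs = wf.fs

    if mode == "resp":
        max_lag = int(round(cfg.resp_max_lag_s * fs))
        corr = _lagged_corr_matrix(x, max_lag, cfg.zero_lag_only)
        np.fill_diagonal(corr, 0.0)
        initial = int(np.argmax(corr.sum(axis=1)))
        accepted = np.flatnonzero(corr[initial] > cfg.resp_corr_threshold)
        return np.union1d(accepted, [initial])

    if mode == "card":
        max_lag = int(round(cfg.card_max_lag_s * fs))
        if seed_channel is None:
            seed_channel = cfg.seed_channel
        if seed_channel == "auto":
            seed = int(np.argmax(x.var(axis=0)))
        else:
            seed = int(seed_channel)
            if not (0 <= seed < c):
                raise ExtractionError(f"seed channel {seed} out of range")
        corr = _lagged_corr_matrix(x, max_lag, cfg.zero_lag_only)
        thresholds = np.arange(cfg.card_thresh_start,
                               cfg.card_thresh_stop - 1e-9,
                               -cfg.card_thresh_step)
        accepted = np.array([seed])
        for tau in thresholds:
            accepted = np.union1d(np.flatnonzero(corr[seed] > tau), [seed])
            if accepted.size >= cfg.card_min_channels:
                return accepted
        if accepted.size >= cfg.card_final_min_channels:
            return accepted
        raise ExtractionError("insufficient cardiac channels at the final "
                              f"threshold ({accepted.size} accepted)")

    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Source separation
# ---------------------------------------------------------------------------


def _joint_diagonalize(mats: np.ndarray, tol: float, max_sweeps: int) -> np.ndarray:
    """Jacobi joint diagonalisation of symmetric matrices (Givens sweeps).

    Returns the orthogonal matrix V maximising the joint diagonality of
    ``V.T M V`` over the stack."""
    m = mats.shape[1]
    V = np.eye(m)
    M = mats.copy()
    for _ in range(max_sweeps):
        changed = False
        for p in range(m - 1):
            for q in range(p + 1, m):
                ton = M[:, p, p] - M[:, q, q]
                toff = M[:, p, q] + M[:, q, p]
                num = (ton * toff).sum() * 2
                den = (ton ** 2 - toff ** 2).sum()
                theta = 0.25 * np.arctan2(num, den)
                c, s = np.cos(theta), np.sin(theta)
                if abs(s) > tol:
                    changed = True
                    rot = np.array([[c, -s], [s, c]])
                    M[:, :, [p, q]] = M[:, :, [p, q]] @ rot
                    M[:, [p, q], :] = np.swapaxes(
                        np.swapaxes(M[:, [p, q], :], 1, 2) @ rot, 1, 2)
                    V[:, [p, q]] = V[:, [p, q]] @ rot
        if not changed:
            break
    return V


def sobi(x: np.ndarray, n_lags: int = 50, tol: float = 1e-8,
         max_sweeps: int = 100) -> np.ndarray:
    """Second-Order Blind Identification.

    Whitens the mean-removed channels via eigendecomposition of the
    sample covariance, then jointly diagonalises the symmetrised
    time-lagged covariance matrices at lags ``1..n_lags``.  Returns the
    recovered sources, shape (n, n_components), each unit variance.
    """
    x = np.asarray(x, dtype=float)
    n, c = x.shape
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / n
    evals, evecs = np.linalg.eigh(cov)
    keep = evals > max(evals.max(), 1e-300) * 1e-10
    if keep.sum() < 2:
        raise np.linalg.LinAlgError("covariance rank < 2")
    evals, evecs = evals[keep], evecs[:, keep]
    W = evecs / np.sqrt(evals)        # whitening: z = xc @ W
    z = xc @ W
    k = z.shape[1]

    lags = range(1, min(n_lags, n - 1) + 1)
    mats = np.empty((len(lags), k, k))
    for i, lag in enumerate(lags):
        r = z[:-lag].T @ z[lag:] / (n - lag)
        mats[i] = 0.5 * (r + r.T)
    V = _joint_diagonalize(mats, tol, max_sweeps)
    sources = z @ V
    sd = sources.std(axis=0)
    sd[sd == 0] = 1.0
    return sources / sd


def _in_band_power_fraction(s: np.ndarray, fs: float, band: tuple[float, float]
                            ) -> np.ndarray:
    spec = np.abs(np.fft.rfft(s - s.mean(axis=0), axis=0)) ** 2
    freqs = np.fft.rfftfreq(s.shape[0], d=1.0 / fs)
    inb = (freqs >= band[0]) & (freqs <= band[1])
    total = spec[1:].sum(axis=0)
    total[total == 0] = np.inf
    return spec[inb].sum(axis=0) / total


def extract_respiratory(wf: PTChannelWaveforms,
                        band: tuple[float, float] = (0.05, 0.9),
                        n_lags: int = 50, tol: float = 1e-8,
                        max_sweeps: int = 100) -> np.ndarray:
    """Respiratory navigator via SOBI on the accepted channels.

    Of the recovered sources the one with the largest spectral power
    fraction inside the respiratory band is returned, oriented so its
    correlation with the mean accepted-channel waveform is positive,
    and scaled to unit variance.  Falls back to the first principal
    component if the channel covariance has rank < 2.
    """
    x = wf.value
    if x.shape[1] < 2:
        raise ExtractionError("respiratory extraction needs >= 2 channels")
    try:
        sources = sobi(x, n_lags=n_lags, tol=tol, max_sweeps=max_sweeps)
    except np.linalg.LinAlgError:
        logger.warning("channel covariance rank < 2; falling back to PCA")
        return extract_cardiac(wf, seed_col=0)
    frac = _in_band_power_fraction(sources, wf.fs, band)
    pick = int(np.argmax(frac))
    nav = sources[:, pick]
    ref = x.mean(axis=1)
    if np.corrcoef(nav, ref)[0, 1] < 0:
        nav = -nav
    return nav / nav.std()


def extract_cardiac(wf: PTChannelWaveforms, seed_col: int = 0) -> np.ndarray:
    """Cardiac navigator: first principal component of the mean-removed
    accepted channels, unit variance, oriented positively with the seed
    channel."""
    x = wf.value
    if x.shape[1] < 2:
        raise ExtractionError("cardiac extraction needs >= 2 channels")
    xc = x - x.mean(axis=0)
    if not np.any(xc):
        raise ExtractionError("all channels are constant; no cardiac signal")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    pc1 = u[:, 0] * s[0]
    if pc1.std() == 0:
        raise ExtractionError("degenerate first principal component")
    ref = xc[:, seed_col]
    orient = np.dot(pc1, ref)
    if orient < 0 or (orient == 0 and vt[0, np.flatnonzero(vt[0])[0]] < 0):
        pc1 = -pc1
    return pc1 / pc1.std()


# ---------------------------------------------------------------------------
# End-to-end extraction
# ---------------------------------------------------------------------------


def extract_navigators(acq: AcquisitionSet, cfg: ExtractConfig | None = None
                       ) -> tuple[PhysioNavigators, dict]:
    """Full navigator-extraction chain on the imaging coils.

    Returns the navigators plus a diagnostics dict (accepted channels as
    original coil indices, carrier-frequency statistics, thresholds).
    """
    cfg = cfg or ExtractConfig()
    cfg.validate()
    est = estimate_carrier(acq, cfg.search_halfwidth_hz, cfg.zero_pad_factor,
                           cfg.snr_floor)
    wf = build_waveforms(est, acq, coils=acq.imaging_coils)
    wf = detrend_by_angle(wf, acq.arm_angle, cfg.detrend_max_harmonic)
    wf = sgolay_denoise(wf, cfg.sg_window, cfg.sg_polyorder)
    wf_resp = bandpass(wf, cfg.resp_band_hz, cfg.band_transition_frac, "resp_band")
    wf_card = bandpass(wf, cfg.card_band_hz, cfg.band_transition_frac, "card_band")

    resp_idx = select_channels(wf_resp, "resp", cfg)
    card_idx = select_channels(wf_card, "card", cfg, seed_channel=cfg.seed_channel)
    if resp_idx.size < 2:
        raise ExtractionError("fewer than 2 respiratory channels accepted")

    resp = extract_respiratory(
        wf_resp.with_values(wf_resp.value[:, resp_idx], "resp_band"),
        band=cfg.resp_band_hz, n_lags=cfg.sobi_n_lags, tol=cfg.sobi_tol,
        max_sweeps=cfg.sobi_max_sweeps)
    # position of the seed inside the accepted set
    if cfg.seed_channel == "auto":
        seed = int(np.argmax(wf_card.value.var(axis=0)))
    else:
        seed = int(cfg.seed_channel)
    seed_pos = int(np.flatnonzero(card_idx == seed)[0])
    card = extract_cardiac(
        wf_card.with_values(wf_card.value[:, card_idx], "card_band"),
        seed_col=seed_pos)

    nav = PhysioNavigators(
        t=wf.t.copy(), resp=resp, card=card,
        resp_channels=wf.coil_indices[resp_idx],
        card_channels=wf.coil_indices[card_idx])
    diag = {
        "n_lost_lines": int(est.lost.sum()),
        "carrier_freq_mean_hz": float(est.freq.mean()),
        "carrier_freq_sd_hz": float(est.freq.std()),
        "resp_channels": nav.resp_channels.tolist(),
        "card_channels": nav.card_channels.tolist(),
    }
    return nav, diag
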
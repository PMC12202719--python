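"""Pilot-tone interference cancellation.

Two methods operate on the raw hybrid k-space:

* EDITER (External Dynamic InTerference Estimation and Removal):
  within windows of consecutive lines, each imaging coil's samples are
  modelled as FIR-filtered combinations of the sniffer-coil samples
  (taps spanning +/-K positions along the readout, optionally
  +/-delta_lines across adjacent lines); the least-squares kernels are
  grouped across windows by similarity and refit per group on the
  pooled data, then the predicted interference is subtracted.

* Model subtraction (baseline): a single sinusoidal carrier model —
  global frequency from the combined spectrum, then per-line per-coil
  complex amplitude by projection — subtracted from every readout.

The least-squares solve truncates singular values below
``lstsq_rcond * s_max``, which confines the fit to the high-SNR
interference modes of the sniffer records and keeps the desired signal
out of the projection; a ridge variant is available via configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_core import AcquisitionSet, CancelConfig, ValidationError
from .ptnav import _parabolic_refine

logger = logging.getLogger(__name__)

__all__ = [
    "InterferenceModel",
    "CancellationReport",
    "editer_fit",
    "editer_apply",
    "model_subtract",
]


@dataclass
class InterferenceModel:
    """Windowed FIR kernels mapping sniffer coils to imaging coils.

    ``windows`` is a list of ``(start, stop)`` line ranges partitioning
    the fitted line range; ``kernels[w]`` has shape
    ``(n_imaging, n_taps)`` with ``n_taps = n_sniffer * (2K+1) * (2*delta_lines+1)``;
    ``group_id[w]`` labels the similarity cluster each window's kernel
    was refit in.
    """

    windows: list[tuple[int, int]]
    kernels: np.ndarray
    group_id: np.ndarray
    kernel_halfwidth: int
    delta_lines: int
    imaging_coils: np.ndarray
    sniffer_coils: np.ndarray

    def __post_init__(self) -> None:
        starts = [w[0] for w in self.windows]
        stops = [w[1] for w in self.windows]
        if any(b <= a for a, b in self.windows):
            raise ValidationError("empty fit window")
        if any(stops[i] != starts[i + 1] for i in range(len(self.windows) - 1)):
            raise ValidationError("windows must partition the line range")
        if not np.all(np.isfinite(self.kernels)):
            raise ValidationError("kernels must be finite")


@dataclass
class CancellationReport:
    """Diagnostics of a cancellation run."""

    residual_db: np.ndarray       # per-window residual power ratio, dB
    n_groups: int
    removed_power: np.ndarray     # per imaging coil, interference power removed
    skipped_lines: int = 0


# ---------------------------------------------------------------------------
# Design-matrix construction
# ---------------------------------------------------------------------------


def _design_matrix(sniff: np.ndarray, K: int, delta: int) -> np.ndarray:
    """Regressor matrix for one window.

    ``sniff``: (n_lines_w, n_sniffer, n_samples).  Returns
    (n_lines_w * n_samples, n_sniffer * (2K+1) * (2*delta+1)); shifts
    beyond the readout (or line range) are zero-padded.
    """
    nl, nc, ns = sniff.shape
    cols = []
    for dl in range(-delta, delta + 1):
        shifted_l = np.zeros_like(sniff)
        if dl == 0:
            shifted_l = sniff
        elif dl > 0:
            shifted_l[dl:] = sniff[:nl - dl]
        else:
            shifted_l[:nl + dl] = sniff[-dl:]
        for k in range(-K, K + 1):
            shifted = np.zeros_like(shifted_l)
            if k == 0:
                shifted = shifted_l
            elif k > 0:
                shifted[:, :, k:] = shifted_l[:, :, :ns - k]
            else:
                shifted[:, :, :ns + k] = shifted_l[:, :, -k:]
            cols.append(shifted.transpose(0, 2, 1).reshape(nl * ns, nc))
    return np.concatenate(cols, axis=1)


def _solve(A: np.ndarray, B: np.ndarray, cfg: CancelConfig) -> np.ndarray:
    """Least squares with truncated SVD (or ridge if configured)."""
    if cfg.ridge_lambda > 0:
        p = A.shape[1]
        gram = A.conj().T @ A
        lam = cfg.ridge_lambda * np.trace(gram).real / p
        return np.linalg.solve(gram + lam * np.eye(p), A.conj().T @ B)
    x, _, rank, _ = np.linalg.lstsq(A, B, rcond=cfg.lstsq_rcond)
    if rank < A.shape[1]:
        logger.debug("rank-deficient fit (rank %d of %d); truncated-SVD "
                     "minimum-norm solution used", rank, A.shape[1])
    return x


# ---------------------------------------------------------------------------
# EDITER
# ---------------------------------------------------------------------------


def _make_windows(n_lines: int, window_lines: int) -> list[tuple[int, int]]:
    starts = list(range(0, n_lines, window_lines))
    windows = [(s, min(s + window_lines, n_lines)) for s in starts]
    if len(windows) > 1 and windows[-1][1] - windows[-1][0] < window_lines // 2:
        last = windows.pop()
        prev = windows.pop()
        windows.append((prev[0], last[1]))
    return windows


def editer_fit(acq: AcquisitionSet, cfg: CancelConfig | None = None
               ) -> InterferenceModel:
    """Fit windowed sniffer-to-imaging FIR kernels and group them.

    Windows whose concatenated kernels correlate above
    ``group_corr_threshold`` are merged into clusters and one kernel per
    cluster is refit on the pooled window data.
    """
    cfg = cfg or CancelConfig()
    cfg.validate()
    sniffers = acq.sniffer_coils
    imaging = acq.imaging_coils
    if sniffers.size < 1:
        raise ValidationError("EDITER requires at least one sniffer coil")
    K, delta = cfg.kernel_halfwidth, cfg.delta_lines
    n_taps = sniffers.size * (2 * K + 1) * (2 * delta + 1)
    if cfg.window_lines * acq.n_samples < n_taps:
        raise ValidationError(
            f"window of {cfg.window_lines} lines x {acq.n_samples} samples "
            f"cannot identify {n_taps} taps")

    windows = _make_windows(acq.n_lines, cfg.window_lines)

    def _row_weights(n_lines_w: int) -> np.ndarray | None:
        if not cfg.fit_taper:
            return None
        from scipy.signal.windows import hann
        return np.tile(hann(acq.n_samples, sym=False), n_lines_w)

    kernels = np.zeros((len(windows), imaging.size, n_taps), dtype=np.complex128)
    for w, (a, b) in enumerate(windows):
        A = _design_matrix(acq.samples[a:b][:, sniffers, :], K, delta)
        B = acq.samples[a:b][:, imaging, :].transpose(0, 2, 1).reshape(
            (b - a) * acq.n_samples, imaging.size)
        wgt = _row_weights(b - a)
        if wgt is not None:
            A, B = A * wgt[:, None], B * wgt[:, None]
        kernels[w] = _solve(A, B, cfg).T

    # -- group windows by kernel similarity ---------------------------
    # concordance-normalised correlation 2|<k1,k2>| / (|k1|^2 + |k2|^2):
    # scale-sensitive, so windows in different amplitude-modulation
    # states do not merge (plain cosine similarity would merge any
    # scalar-scaled kernel pair)
    flat = kernels.reshape(len(windows), -1)
    norms2 = np.sum(np.abs(flat) ** 2, axis=1)
    denom = norms2[:, None] + norms2[None, :]
    denom[denom == 0] = 1.0
    sim = 2.0 * np.abs(flat.conj() @ flat.T) / denom
    adj = sim > cfg.group_corr_threshold
    group_id = -np.ones(len(windows), dtype=int)
    n_groups = 0
    for w in range(len(windows)):
        if group_id[w] >= 0:
            continue
        stack = [w]
        group_id[w] = n_groups
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(adj[u]):
                if group_id[v] < 0:
                    group_id[v] = n_groups
                    stack.append(v)
        n_groups += 1

    # -- refit one kernel per cluster on pooled data ------------------
    for g in range(n_groups):
        members = np.flatnonzero(group_id == g)
        if members.size == 1:
            continue
        A_parts, B_parts = [], []
        for w in members:
            a, b = windows[w]
            Aw = _design_matrix(acq.samples[a:b][:, sniffers, :], K, delta)
            Bw = acq.samples[a:b][:, imaging, :].transpose(0, 2, 1).reshape(
                (b - a) * acq.n_samples, imaging.size)
            wgt = _row_weights(b - a)
            if wgt is not None:
                Aw, Bw = Aw * wgt[:, None], Bw * wgt[:, None]
            A_parts.append(Aw)
            B_parts.append(Bw)
        x = _solve(np.concatenate(A_parts), np.concatenate(B_parts), cfg)
        kernels[members] = x.T[None, :, :]

    return InterferenceModel(windows=windows, kernels=kernels, group_id=group_id,
                             kernel_halfwidth=K, delta_lines=delta,
                             imaging_coils=imaging, sniffer_coils=sniffers)


def editer_apply(model: InterferenceModel, acq: AcquisitionSet,
                 ) -> tuple[AcquisitionSet, CancellationReport]:
    """Subtract the predicted interference from every imaging coil.

    Sniffer channels pass through unchanged.  Fit and apply must use
    the same line partition: a line outside every window is an error.
    """
    if model.windows[0][0] != 0 or model.windows[-1][1] != acq.n_lines:
        raise ValidationError("model windows do not cover the acquisition")
    out = acq.copy()
    imaging, sniffers = model.imaging_coils, model.sniffer_coils
    residual_db = np.empty(len(model.windows))
    removed = np.zeros(imaging.size)
    for w, (a, b) in enumerate(model.windows):
        A = _design_matrix(acq.samples[a:b][:, sniffers, :],
                           model.kernel_halfwidth, model.delta_lines)
        pred = A @ model.kernels[w].T           # (rows, n_imaging)
        B = acq.samples[a:b][:, imaging, :].transpose(0, 2, 1).reshape(
            (b - a) * acq.n_samples, imaging.size)
        resid = B - pred
        p_in = np.sum(np.abs(B) ** 2)
        p_out = np.sum(np.abs(resid) ** 2)
        residual_db[w] = 10 * np.log10(p_out / p_in) if p_in > 0 else 0.0
        removed += np.sum(np.abs(pred) ** 2, axis=0)
        cleaned = resid.reshape(b - a, acq.n_samples, imaging.size)
        out.samples[a:b, imaging, :] = cleaned.transpose(0, 2, 1)
    report = CancellationReport(residual_db=residual_db,
                                n_groups=int(model.group_id.max()) + 1,
                                removed_power=removed)
    return out, report


# ---------------------------------------------------------------------------
# Sinusoid-model subtraction baseline
# ---------------------------------------------------------------------------


def model_subtract(acq: AcquisitionSet, cfg: CancelConfig | None = None,
                   lost_mask: np.ndarray | None = None,
                   ) -> tuple[AcquisitionSet, CancellationReport]:
    """Baseline cancellation assuming a single static sinusoidal carrier.

    The carrier frequency is estimated once from the average magnitude
    spectrum over all lines and imaging coils (refined by quadratic
    interpolation); then, per line and imaging coil, the complex
    amplitude is the least-squares projection onto the unit complex
    exponential at that frequency, and the fitted sinusoid is
    subtracted.  Lines flagged in ``lost_mask`` are left unmodified and
    counted.
    """
    cfg = cfg or CancelConfig()
    nfft = 4 * acq.n_samples
    freqs = np.fft.fftfreq(nfft, d=acq.dwell_time)
    band = np.abs(freqs - acq.center_freq_offset_nominal) <= cfg.search_halfwidth_hz
    if not band.any():
        raise ValidationError("search band is empty")
    spec = np.zeros(nfft)
    chunk = 4096
    for start in range(0, acq.n_lines, chunk):
        sl = slice(start, min(start + chunk, acq.n_lines))
        spec += np.abs(
            np.fft.fft(acq.samples[sl][:, acq.imaging_coils, :], n=nfft, axis=-1)
        ).sum(axis=(0, 1))
    masked = np.where(band, spec, -np.inf)
    peak = int(np.argmax(masked))
    delta = _parabolic_refine(np.log(np.maximum(spec, 1e-300)), peak)
    bin_hz = 1.0 / (nfft * acq.dwell_time)
    f_hat = freqs[peak] + delta * bin_hz

    # refine to machine precision: maximise total projection power over a
    # line subsample within one bin of the interpolated peak
    from scipy.optimize import minimize_scalar
    tau0 = acq.sample_times
    step = max(acq.n_lines // 200, 1)
    sub = acq.samples[::step][:, acq.imaging_coils, :]

    def neg_power(f):
        e0 = np.exp(-2j * np.pi * f * tau0)
        return -np.sum(np.abs(sub @ e0) ** 2)

    res = minimize_scalar(neg_power, bounds=(f_hat - bin_hz, f_hat + bin_hz),
                          method="bounded",
                          options={"xatol": 1e-8 * bin_hz, "maxiter": 200})
    f_hat = float(res.x)

    tau = acq.sample_times
    e = np.exp(2j * np.pi * f_hat * tau)
    out = acq.copy()
    process = np.ones(acq.n_lines, dtype=bool)
    skipped = 0
    if lost_mask is not None:
        process = ~np.asarray(lost_mask, dtype=bool)
        skipped = int((~process).sum())
    img = acq.imaging_coils
    coeff = acq.samples[process][:, img, :] @ e.conj() / acq.n_samples
    pred = coeff[:, :, None] * e[None, None, :]
    sel = np.flatnonzero(process)
    out.samples[sel[:, None], img[None, :], :] -= pred
    removed = np.sum(np.abs(pred) ** 2, axis=(0, 2))
    p_in = np.sum(np.abs(acq.samples[process][:, img, :]) ** 2)
    p_out = np.sum(np.abs(out.samples[process][:, img, :]) ** 2)
    report = CancellationReport(
        residual_db=np.array([10 * np.log10(p_out / p_in) if p_in > 0 else 0.0]),
        n_groups=1, removed_power=removed, skipped_lines=skipped)
    return out, report
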
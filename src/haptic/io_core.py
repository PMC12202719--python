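"""Domain types and file I/O for pilot-tone raw acquisitions.

The raw-acquisition container is a single HDF5 file with an
ISMRMRD-style layout so generic HDF5 tooling can open it::

    /acquisitions/data        complex128 (n_lines, n_coils, n_samples)
    /acquisitions/line_time   float64 (n_lines,)      start-of-readout [s]
    /acquisitions/arm_angle   float64 (n_lines,)      spiral arm angle [rad]
    /acquisitions/trajectory  float64 (n_lines, n_samples, 2)  [cycles/FOV-unit]
    /acquisitions/coil_role   ascii strings, one of {"imaging", "sniffer"}
    /acquisitions@dwell_time  float [s]
    /acquisitions@tr          float [s]
    /acquisitions@center_freq_offset_nominal  float [Hz]

Trigger series are plain CSV: a ``# source: <name>`` comment line, a
``time_s`` header, then one event time (seconds) per row.

All quantities are SI internally (seconds, Hz); files store SI.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AcquisitionSet",
    "TriggerSeries",
    "RunConfig",
    "FormatError",
    "ValidationError",
    "read_acquisitions",
    "write_acquisitions",
    "read_triggers",
    "write_triggers",
    "read_navigators",
    "write_navigators",
]

GOLDEN_ANGLE_DEG = 137.507764
"""Default golden-angle increment between spiral arms, degrees."""


class FormatError(ValueError):
    """A file does not conform to the documented layout."""


class ValidationError(ValueError):
    """A domain-type invariant is violated."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class AcquisitionSet:
    """Multi-coil raw readouts with timing, trajectory and coil roles.

    Attributes
    ----------
    samples : complex ndarray, shape (n_lines, n_coils, n_samples)
        Raw readout samples per k-space line and coil.
    line_time : ndarray, shape (n_lines,)
        Start-of-readout timestamp of each line, seconds, strictly
        increasing.  Navigator sample ``k`` is timestamped ``line_time[k]``.
    arm_angle : ndarray, shape (n_lines,)
        Starting angle of each spiral arm, radians in ``[0, 2*pi)``.
    dwell_time : float
        Seconds per readout sample.
    tr : float
        Repetition time, seconds; sets the navigator sampling period.
    center_freq_offset_nominal : float
        Nominal pilot-tone carrier offset from the imaging center
        frequency, Hz.
    coil_role : ndarray of str, shape (n_coils,)
        ``"imaging"`` or ``"sniffer"`` per coil.
    trajectory : ndarray, shape (n_lines, n_samples, 2)
        k-space coordinates of every sample, cycles per FOV unit.
    """

    samples: np.ndarray
    line_time: np.ndarray
    arm_angle: np.ndarray
    dwell_time: float
    tr: float
    center_freq_offset_nominal: float
    coil_role: np.ndarray
    trajectory: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        self.line_time = np.asarray(self.line_time, dtype=np.float64)
        self.arm_angle = np.asarray(self.arm_angle, dtype=np.float64)
        self.coil_role = np.asarray(self.coil_role, dtype=object)
        self.trajectory = np.asarray(self.trajectory, dtype=np.float64)
        self.validate()

    # -- shape helpers ------------------------------------------------
    @property
    def n_lines(self) -> int:
        return self.samples.shape[0]

    @property
    def n_coils(self) -> int:
        return self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[2]

    @property
    def imaging_coils(self) -> np.ndarray:
        """Indices of imaging coils."""
        return np.flatnonzero(self.coil_role == "imaging")

    @property
    def sniffer_coils(self) -> np.ndarray:
        """Indices of sniffer coils."""
        return np.flatnonzero(self.coil_role == "sniffer")

    @property
    def sample_times(self) -> np.ndarray:
        """In-readout sample times relative to readout start, seconds."""
        return np.arange(self.n_samples) * self.dwell_time

    def validate(self) -> None:
        if self.samples.ndim != 3:
            raise ValidationError("samples must be (n_lines, n_coils, n_samples)")
        n_lines, n_coils, n_samples = self.samples.shape
        if n_lines < 1:
            raise ValidationError("need at least one k-space line")
        if self.line_time.shape != (n_lines,):
            raise ValidationError("line_time shape mismatch")
        if self.arm_angle.shape != (n_lines,):
            raise ValidationError("arm_angle shape mismatch")
        if self.trajectory.shape != (n_lines, n_samples, 2):
            raise ValidationError("trajectory shape mismatch")
        if self.coil_role.shape != (n_coils,):
            raise ValidationError("coil_role shape mismatch")
        bad = set(self.coil_role) - {"imaging", "sniffer"}
        if bad:
            raise ValidationError(f"unknown coil roles: {sorted(bad)}")
        if len(self.imaging_coils) < 1:
            raise ValidationError("need at least one imaging coil")
        if n_lines > 1 and not np.all(np.diff(self.line_time) > 0):
            raise ValidationError("line_time must be strictly increasing")
        if np.any(self.arm_angle < 0) or np.any(self.arm_angle >= 2 * np.pi):
            raise ValidationError("arm_angle must lie in [0, 2*pi)")
        if not self.tr > 0:
            raise ValidationError("TR must be positive")
        if not self.dwell_time > 0:
            raise ValidationError("dwell_time must be positive")

    def copy(self) -> "AcquisitionSet":
        return AcquisitionSet(
            samples=self.samples.copy(),
            line_time=self.line_time.copy(),
            arm_angle=self.arm_angle.copy(),
            dwell_time=self.dwell_time,
            tr=self.tr,
            center_freq_offset_nominal=self.center_freq_offset_nominal,
            coil_role=self.coil_role.copy(),
            trajectory=self.trajectory.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AcquisitionSet):
            return NotImplemented
        return (
            np.array_equal(self.samples, other.samples)
            and np.array_equal(self.line_time, other.line_time)
            and np.array_equal(self.arm_angle, other.arm_angle)
            and self.dwell_time == other.dwell_time
            and self.tr == other.tr
            and self.center_freq_offset_nominal == other.center_freq_offset_nominal
            and list(self.coil_role) == list(other.coil_role)
            and np.array_equal(self.trajectory, other.trajectory)
        )


@dataclass
class TriggerSeries:
    """Strictly increasing physiological event times.

    ``source`` labels the origin of the events: ``"PT"`` for pilot-tone
    derived triggers, ``"ECG"`` for reference R-waves, ``"truth"`` for
    simulator ground truth.
    """

    event_time: np.ndarray
    source: str = "PT"

    def __post_init__(self) -> None:
        self.event_time = np.asarray(self.event_time, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.event_time.ndim != 1:
            raise ValidationError("event_time must be one-dimensional")
        if self.event_time.size and np.any(self.event_time < 0):
            raise ValidationError("event times must be non-negative")
        if self.event_time.size > 1 and not np.all(np.diff(self.event_time) > 0):
            raise ValidationError("event times must be strictly increasing")

    def __len__(self) -> int:
        return self.event_time.size


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass
class SimConfig:
    """Synthetic-acquisition parameters.

    The defaults reproduce the acquisition regime the pipeline targets:
    a golden-angle spiral with TR 5.32 ms (188 Hz navigator sampling),
    a pilot-tone carrier 400 kHz off-center, 90 s of data, five imaging
    coils and three sniffer coils.
    """

    duration_s: float = 90.0
    tr_s: float = 0.00532
    n_samples: int = 64
    dwell_time_s: float = 1.0e-6
    f_offset_hz: float = 400e3
    f_drift_amp_hz: float = 500.0
    f_drift_cycles: float = 1.5
    golden_angle_deg: float = GOLDEN_ANGLE_DEG
    fov: float = 0.3  # metres
    grid_size: int = 64
    spiral_turns: float = 3.0
    n_imaging: int = 5
    n_sniffer: int = 3
    # physiology
    heart_rate_bpm: float = 60.0
    hr_jitter_frac: float = 0.03
    resp_rate_hz: float = 0.25
    resp_amplitude: float = 1.0
    rhythm: str = "regular"
    arrhythmia_rate: float = 0.15
    # coupling
    pt_amplitude: float = 0.4  # analog of the transmit voltage setting
    m_resp: float = 0.05
    m_card: float = 0.01
    eddy_amp: float = 0.02
    eddy_order: int = 3
    noise_sd: float = 0.003
    saturation_noise_frac: float = 0.0075
    noise_duration_s: float = 30.0
    phantom_scale: float = 30.0

    def validate(self) -> None:
        _check(self.duration_s >= 10, "duration must be >= 10 s")
        _check(self.tr_s > 0, "TR must be positive")
        _check(self.n_samples >= 32, "need >= 32 samples per readout")
        _check(self.dwell_time_s > 0, "dwell time must be positive")
        _check(0.5 * 60 <= self.heart_rate_bpm <= 2.7 * 60,
               "heart rate outside 0.5-2.7 Hz band-pass design range")
        _check(0.05 <= self.resp_rate_hz <= 0.9,
               "respiratory rate outside 0.05-0.9 Hz band")
        _check(self.rhythm in ("regular", "arrhythmic"), "unknown rhythm")
        _check(self.n_imaging >= 1, "need at least one imaging coil")
        _check(self.m_resp + self.m_card < 1, "modulation depths must sum below 1")
        _check(self.pt_amplitude >= 0, "pilot-tone amplitude must be >= 0")
        _check(self.noise_sd >= 0, "noise SD must be >= 0")


@dataclass
class ExtractConfig:
    """Navigator-extraction parameters (carrier estimation through
    SOBI/PCA source separation)."""

    search_halfwidth_hz: float = 50e3
    zero_pad_factor: int = 8
    snr_floor: float = 5.0
    detrend_max_harmonic: int = 8
    sg_window: int = 21
    sg_polyorder: int = 3
    resp_band_hz: tuple = (0.05, 0.9)
    card_band_hz: tuple = (1.0, 20.0)
    band_transition_frac: float = 0.2
    resp_corr_threshold: float = 0.9
    resp_max_lag_s: float = 1.0
    card_max_lag_s: float = 0.1
    card_thresh_start: float = 0.90
    card_thresh_stop: float = 0.50
    card_thresh_step: float = 0.05
    card_min_channels: int = 3
    card_final_min_channels: int = 2
    seed_channel: str | int = "auto"
    zero_lag_only: bool = False
    sobi_n_lags: int = 50
    sobi_tol: float = 1e-8
    sobi_max_sweeps: int = 100

    def validate(self) -> None:
        _check(self.sg_window % 2 == 1 and self.sg_window > self.sg_polyorder,
               "Savitzky-Golay window must be odd and exceed polyorder")
        _check(self.resp_band_hz[0] < self.resp_band_hz[1], "bad respiratory band")
        _check(self.card_band_hz[0] < self.card_band_hz[1], "bad cardiac band")
        _check(0 < self.resp_corr_threshold <= 1, "bad correlation threshold")
        _check(self.card_thresh_stop <= self.card_thresh_start,
               "cardiac threshold sweep must be decreasing")
        _check(self.sobi_n_lags >= 1, "need at least one SOBI lag")


@dataclass
class CancelConfig:
    """Interference-cancellation parameters (EDITER and the sinusoid-model
    subtraction baseline)."""

    window_lines: int = 50
    kernel_halfwidth: int = 0  # +/-K taps along the sample axis
    delta_lines: int = 0
    # kernel-similarity threshold for merging windows; 1.0 keeps every
    # window's own kernel (an amplitude-modulated carrier makes any
    # pooled kernel stale)
    group_corr_threshold: float = 1.0
    # singular values below lstsq_rcond * s_max are truncated; keeps the
    # fit on the high-SNR interference modes of the sniffer records
    lstsq_rcond: float = 0.02
    # > 0 switches to ridge regression with lambda scaled by the mean
    # squared column norm of the design matrix
    ridge_lambda: float = 0.0
    # Hann-weight the fit rows along the readout: decouples the
    # narrowband kernel estimate from spectral leakage of the desired
    # (broadband, low-frequency) imaging signal
    fit_taper: bool = True
    search_halfwidth_hz: float = 50e3

    def validate(self) -> None:
        _check(self.window_lines >= 1, "window must contain >= 1 line")
        _check(self.kernel_halfwidth >= 0, "kernel halfwidth must be >= 0")
        _check(self.delta_lines >= 0, "delta_lines must be >= 0")
        _check(0 < self.group_corr_threshold <= 1, "bad grouping threshold")


@dataclass
class GatingConfig:
    """Trigger-detection and binning parameters."""

    window_s: float = 0.375
    prominence: float = 0.5
    p_lo: float = 10.0
    p_hi: float = 98.0
    n_resp_bins: int = 12
    n_card_bins: int = 20

    def validate(self) -> None:
        _check(self.window_s > 0, "refractory window must be positive")
        _check(0 <= self.p_lo < self.p_hi <= 100, "bad percentile pair")
        _check(self.n_resp_bins >= 1 and self.n_card_bins >= 1, "bad bin counts")


@dataclass
class ReconConfig:
    """Gridding-reconstruction and noise-metric parameters."""

    grid_size: int = 64
    oversampling: float = 2.0
    kernel_width: int = 4
    roi_diameter_fraction: float = 0.53
    frame_stride_arms: int = 17
    footprint_arms: int = 55

    def validate(self) -> None:
        _check(self.grid_size >= 8, "grid too small")
        _check(self.oversampling >= 1.0, "oversampling must be >= 1")
        _check(0 < self.roi_diameter_fraction <= 1, "ROI must sit inside FOV")
        _check(self.frame_stride_arms >= 1 and self.footprint_arms >= 1,
               "bad view-sharing arm counts")


@dataclass
class RunConfig:
    """All tunables of every pipeline stage, with validation on load."""

    sim: SimConfig = field(default_factory=SimConfig)
    extract: ExtractConfig = field(default_factory=ExtractConfig)
    cancel: CancelConfig = field(default_factory=CancelConfig)
    gating: GatingConfig = field(default_factory=GatingConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    seed: int = 0

    def validate(self) -> None:
        for section in (self.sim, self.extract, self.cancel, self.gating, self.recon):
            section.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["extract"]["resp_band_hz"] = list(self.extract.resp_band_hz)
        d["extract"]["card_band_hz"] = list(self.extract.card_band_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sections = {
            "sim": SimConfig, "extract": ExtractConfig, "cancel": CancelConfig,
            "gating": GatingConfig, "recon": ReconConfig,
        }
        kwargs: dict = {}
        for name, typ in sections.items():
            sub = dict(d.get(name, {}))
            known = {f.name for f in dataclasses.fields(typ)}
            unknown = set(sub) - known
            if unknown:
                raise FormatError(f"unknown {name} config keys: {sorted(unknown)}")
            for key in ("resp_band_hz", "card_band_hz"):
                if key in sub:
                    sub[key] = tuple(sub[key])
            kwargs[name] = typ(**sub)
        cfg = cls(seed=int(d.get("seed", 0)), **kwargs)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# HDF5 acquisition I/O
# ---------------------------------------------------------------------------

_GROUP = "acquisitions"
_ATTRS = ("dwell_time", "tr", "center_freq_offset_nominal")
_DATASETS = ("data", "line_time", "arm_angle", "trajectory", "coil_role")


def write_acquisitions(acq: AcquisitionSet, path: str | Path) -> Path:
    """Write an :class:`AcquisitionSet` to the documented HDF5 layout."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        g = f.create_group(_GROUP)
        g.create_dataset("data", data=acq.samples)
        g.create_dataset("line_time", data=acq.line_time)
        g.create_dataset("arm_angle", data=acq.arm_angle)
        g.create_dataset("trajectory", data=acq.trajectory)
        roles = np.array([r.encode("ascii") for r in acq.coil_role])
        g.create_dataset("coil_role", data=roles)
        g.attrs["dwell_time"] = acq.dwell_time
        g.attrs["tr"] = acq.tr
        g.attrs["center_freq_offset_nominal"] = acq.center_freq_offset_nominal
    return path


def read_acquisitions(path: str | Path) -> AcquisitionSet:
    """Read and validate an :class:`AcquisitionSet`.

    Raises :class:`FormatError` naming the first missing dataset or
    attribute, and :class:`ValidationError` if the stored payload
    violates an invariant (e.g. non-increasing timestamps).
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        if _GROUP not in f:
            raise FormatError(f"missing group '/{_GROUP}'")
        g = f[_GROUP]
        for name in _DATASETS:
            if name not in g:
                raise FormatError(f"missing dataset '/{_GROUP}/{name}'")
        for name in _ATTRS:
            if name not in g.attrs:
                raise FormatError(f"missing attribute '/{_GROUP}@{name}'")
        roles = np.array([r.decode("ascii") for r in g["coil_role"][()]],
                         dtype=object)
        return AcquisitionSet(
            samples=g["data"][()],
            line_time=g["line_time"][()],
            arm_angle=g["arm_angle"][()],
            dwell_time=float(g.attrs["dwell_time"]),
            tr=float(g.attrs["tr"]),
            center_freq_offset_nominal=float(g.attrs["center_freq_offset_nominal"]),
            coil_role=roles,
            trajectory=g["trajectory"][()],
        )


# ---------------------------------------------------------------------------
# Trigger CSV I/O
# ---------------------------------------------------------------------------


def write_triggers(triggers: TriggerSeries, path: str | Path) -> Path:
    path = Path(path)
    lines = [f"# source: {triggers.source}", "time_s"]
    lines += [repr(float(t)) for t in triggers.event_time]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_triggers(path: str | Path) -> TriggerSeries:
    """Parse a trigger CSV; reports the line number of any bad row."""
    path = Path(path)
    source = "PT"
    times: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("source"):
                source = body.split(":", 1)[1].strip() if ":" in body else source
            continue
        if line == "time_s":
            continue
        try:
            times.append(float(line))
        except ValueError as exc:
            raise FormatError(f"{path.name}:{lineno}: non-numeric row {line!r}") from exc
    return TriggerSeries(event_time=np.array(times), source=source)


# ---------------------------------------------------------------------------
# Navigator CSV I/O
# ---------------------------------------------------------------------------


def write_navigators(t: np.ndarray, resp: np.ndarray, card: np.ndarray,
                     path: str | Path) -> Path:
    """Write the two navigators as CSV with columns t, resp, card."""
    df = pd.DataFrame({"t": t, "resp": resp, "card": card})
    df.to_csv(path, index=False, float_format="%.12g")
    return Path(path)


def read_navigators(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"t", "resp", "card"} - set(df.columns)
    if missing:
        raise FormatError(f"navigator CSV missing columns: {sorted(missing)}")
    return df
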
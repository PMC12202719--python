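"""Cardiac trigger detection, trigger scoring and retrospective binning.

Triggers are prominence-qualified maxima of the normalised first
derivative of the cardiac navigator: the derivative is scaled so its
10th percentile maps to 0 and its 98th to 1, peaks closer than the
refractory window (0.375 s, a 160 bpm ceiling) are resolved in favour
of the larger, and surviving peaks must have topographic prominence
above 0.5.

Detected triggers are scored against reference R-waves interval-wise:
within each half-open RR interval the first pilot-tone event is the
match, extras are false positives, an empty interval is a false
negative.  Jitter is the sample SD of the matched time differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .io_core import GatingConfig, TriggerSeries, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "MatchResult",
    "GatingReport",
    "BinAssignment",
    "detect_triggers",
    "match_triggers",
    "gating_metrics",
    "assign_bins",
]


@dataclass
class MatchResult:
    """Outcome of pairing pilot-tone triggers with reference R-waves."""

    pairs: list[tuple[float, float]]          # (ref_time, pt_time)
    false_positive_times: list[float]
    false_negative_ref_times: list[float]
    window_bounds: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n_fp(self) -> int:
        return len(self.false_positive_times)

    @property
    def n_fn(self) -> int:
        return len(self.false_negative_ref_times)


@dataclass
class GatingReport:
    """Trigger performance summary.

    ``failure_rate`` is 100 x (false positives + false negatives) /
    number of reference triggers heading a search window.
    """

    mean_delay_ms: float
    jitter_ms: float
    n_triggers: int
    n_fp: int
    n_fn: int
    failure_rate: float

    def __post_init__(self) -> None:
        if np.isfinite(self.jitter_ms) and self.jitter_ms < 0:
            raise ValidationError("jitter cannot be negative")
        if not (0 <= self.failure_rate <= 100):
            raise ValidationError("failure rate must lie in [0, 100]")

    def to_dict(self) -> dict:
        return {
            "mean_delay_ms": self.mean_delay_ms,
            "jitter_ms": self.jitter_ms,
            "n_triggers": self.n_triggers,
            "n_fp": self.n_fp,
            "n_fn": self.n_fn,
            "failure_rate": self.failure_rate,
        }


@dataclass
class BinAssignment:
    """Per-line cardiac and respiratory bin labels (-1 = unassigned)."""

    cardiac_bin: np.ndarray
    respiratory_bin: np.ndarray
    n_card_bins: int
    n_resp_bins: int


# ---------------------------------------------------------------------------
# Trigger detection
# ---------------------------------------------------------------------------


def detect_triggers(card_nav: np.ndarray, fs: float,
                    cfg: GatingConfig | None = None,
                    t0: float = 0.0) -> TriggerSeries:
    """Detect cardiac triggers on the navigator's normalised derivative.

    The first derivative (central differences) is affinely rescaled so
    the ``p_lo`` percentile is 0 and the ``p_hi`` percentile is 1; local
    maxima are kept if no larger maximum lies within ``window_s`` and
    their prominence exceeds ``cfg.prominence``.  A flat navigator
    (equal percentiles) yields zero triggers with a warning.
    """
    cfg = cfg or GatingConfig()
    card_nav = np.asarray(card_nav, dtype=float)
    if fs <= 40:
        raise ValidationError("sampling rate must exceed the cardiac band (40 Hz)")
    if card_nav.size / fs < 2.0:
        raise ValidationError("record must span at least 2 s")

    deriv = np.gradient(card_nav)
    p_lo, p_hi = np.percentile(deriv, [cfg.p_lo, cfg.p_hi])
    if p_hi == p_lo:
        logger.warning("flat navigator: percentile normalisation degenerate, "
                       "no triggers")
        return TriggerSeries(event_time=np.array([]), source="PT")
    norm = (deriv - p_lo) / (p_hi - p_lo)

    distance = cfg.window_s * fs
    peaks, _ = find_peaks(norm, distance=distance, prominence=cfg.prominence)
    return TriggerSeries(event_time=t0 + peaks / fs, source="PT")


# ---------------------------------------------------------------------------
# Matching and metrics
# ---------------------------------------------------------------------------


def match_triggers(pt: TriggerSeries, ref: TriggerSeries) -> MatchResult:
    """Pair pilot-tone events with reference R-waves interval-wise.

    For each half-open interval ``[R_k, R_{k+1})``: the first PT event
    is matched with ``R_k``, further events are false positives, none is
    a false negative at ``R_k``.  PT events before the first or at/after
    the last R-wave fall outside every search window and are ignored.
    """
    if len(ref) < 2:
        raise ValidationError("need at least 2 reference events")
    pt_times = pt.event_time
    pairs: list[tuple[float, float]] = []
    fps: list[float] = []
    fns: list[float] = []
    bounds: list[tuple[float, float]] = []
    for rk, rk1 in zip(ref.event_time[:-1], ref.event_time[1:]):
        bounds.append((rk, rk1))
        lo = np.searchsorted(pt_times, rk, side="left")
        hi = np.searchsorted(pt_times, rk1, side="left")
        inside = pt_times[lo:hi]
        if inside.size == 0:
            fns.append(float(rk))
        else:
            pairs.append((float(rk), float(inside[0])))
            fps.extend(float(t) for t in inside[1:])
    return MatchResult(pairs=pairs, false_positive_times=fps,
                       false_negative_ref_times=fns, window_bounds=bounds)


def gating_metrics(match: MatchResult) -> GatingReport:
    """Summarise a match: mean delay, jitter (sample SD, n-1), counts
    and the failure rate 100*(FP+FN)/n_triggers, where ``n_triggers``
    counts the reference R-waves heading a search window."""
    delays_ms = np.array([(pt - rk) * 1e3 for rk, pt in match.pairs])
    n_triggers = len(match.pairs) + match.n_fn
    if n_triggers == 0:
        raise ValidationError("no reference triggers in scope")
    mean_delay = float(delays_ms.mean()) if delays_ms.size else float("nan")
    jitter = float(delays_ms.std(ddof=1)) if delays_ms.size >= 2 else float("nan")
    if delays_ms.size < 2:
        logger.warning("fewer than 2 matched pairs: jitter undefined")
    failure = 100.0 * (match.n_fp + match.n_fn) / n_triggers
    return GatingReport(mean_delay_ms=mean_delay, jitter_ms=jitter,
                        n_triggers=n_triggers, n_fp=match.n_fp,
                        n_fn=match.n_fn, failure_rate=failure)


# ---------------------------------------------------------------------------
# Retrospective binning
# ---------------------------------------------------------------------------


def assign_bins(resp_nav: np.ndarray, triggers: TriggerSeries,
                line_time: np.ndarray, n_resp: int = 12, n_card: int = 20
                ) -> BinAssignment:
    """Assign each k-space line a cardiac phase bin and a respiratory
    amplitude bin.

    Cardiac: ``floor(n_card * (t - T_k) / (T_{k+1} - T_k))`` within each
    RR interval, clipped to the last bin; lines before the first or
    after the last trigger stay unassigned (-1).  Respiratory:
    equal-count amplitude quantiles of the navigator (rank-based), the
    retrospective-binning convention for amplitude gating.
    """
    line_time = np.asarray(line_time, dtype=float)
    resp_nav = np.asarray(resp_nav, dtype=float)
    if resp_nav.shape != line_time.shape:
        raise ValidationError("respiratory navigator must be sampled at line_time")
    n = line_time.size
    card_bin = -np.ones(n, dtype=int)
    trig = triggers.event_time
    if len(trig) >= 2:
        k = np.searchsorted(trig, line_time, side="right") - 1
        ok = (k >= 0) & (k < len(trig) - 1)
        kk = k[ok]
        rr = trig[kk + 1] - trig[kk]
        frac = (line_time[ok] - trig[kk]) / rr
        card_bin[ok] = np.minimum((n_card * frac).astype(int), n_card - 1)
    else:
        logger.warning("fewer than 2 triggers: cardiac bins unassigned")

    ranks = np.argsort(np.argsort(resp_nav, kind="stable"), kind="stable")
    resp_bin = (ranks * n_resp // n).astype(int)
    return BinAssignment(cardiac_bin=card_bin, respiratory_bin=resp_bin,
                         n_card_bins=n_card, n_resp_bins=n_resp)
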
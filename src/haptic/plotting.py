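"""Quick-look plots: navigators with trigger marks, and the
amplitude/jitter/noise-ratio trade-off."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io_core import TriggerSeries
from .pipeline import SweepResult
from .ptnav import PhysioNavigators

__all__ = ["plot_navigators", "plot_sweep"]


def plot_navigators(nav: PhysioNavigators, triggers: TriggerSeries | None = None,
                    ref: TriggerSeries | None = None,
                    path: str | Path | None = None):
    """Respiratory and cardiac navigators over time; pilot-tone triggers
    as ticks, reference events (if given) as dashed lines."""
    fig, (ax_r, ax_c) = plt.subplots(2, 1, sharex=True, figsize=(10, 5))
    ax_r.plot(nav.t, nav.resp, lw=0.8)
    ax_r.set_ylabel("respiratory (a.u.)")
    ax_c.plot(nav.t, nav.card, lw=0.8)
    ax_c.set_ylabel("cardiac (a.u.)")
    ax_c.set_xlabel("time (s)")
    if triggers is not None and len(triggers):
        ax_c.plot(triggers.event_time,
                  np.interp(triggers.event_time, nav.t, nav.card),
                  "|", color="tab:red", ms=14, label="PT triggers")
    if ref is not None and len(ref):
        for t in ref.event_time:
            ax_c.axvline(t, color="0.6", ls="--", lw=0.5)
        ax_c.plot([], [], color="0.6", ls="--", label="reference")
    if triggers is not None or ref is not None:
        ax_c.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_sweep(result: SweepResult, path: str | Path | None = None):
    """Transmit amplitude vs trigger jitter (left axis) and noise ratios
    (right axis, log-log)."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ok = np.isfinite(result.jitter_ms)
    ax.plot(result.amplitude[ok], result.jitter_ms[ok], "o-",
            color="tab:blue", label="jitter")
    ax.set_xscale("log")
    ax.set_xlabel("pilot-tone amplitude (a.u.)")
    ax.set_ylabel("jitter vs true beats (ms)", color="tab:blue")
    ax2 = ax.twinx()
    for series, label, style in ((result.ratio_none, "no cancellation", "^--"),
                                 (result.ratio_model, "model subtraction", "s--"),
                                 (result.ratio_editer, "EDITER", "o-")):
        ax2.plot(result.amplitude, series, style, label=label, alpha=0.8)
    ax2.set_yscale("log")
    ax2.set_ylabel("noise ratio")
    ax2.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
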
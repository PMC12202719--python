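"""End-to-end runs: simulate -> extract -> cancel -> gate -> recon.

One global seed is expanded into per-stage seeds through a spawned
``numpy.random.SeedSequence`` tree (stage order is fixed), so each
stage is individually reproducible and a full run is deterministic
given the configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cancel as cancel_mod
from . import gating as gating_mod
from . import ptnav, recon, simulate
from .io_core import (AcquisitionSet, RunConfig, TriggerSeries,
                      write_acquisitions, write_navigators, write_triggers)

logger = logging.getLogger(__name__)

__all__ = ["SweepResult", "run_pipeline", "run_amplitude_sweep",
           "pooled_noise_sd", "noise_ratio_for"]

# fixed stage order for seed spawning
_STAGES = ("physio", "coupling", "acquire", "noise_scan", "ref_scan")


def stage_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return dict(zip(_STAGES, children))


# ---------------------------------------------------------------------------
# Noise-ratio evaluation
# ---------------------------------------------------------------------------


def pooled_noise_sd(acq: AcquisitionSet, cfg: RunConfig,
                    max_frames: int = 60) -> float:
    """Noise SD pooled over the ROIs of non-overlapping view-share
    frames of a noise-only acquisition."""
    rcfg = dataclasses.replace(cfg.recon,
                               frame_stride_arms=cfg.recon.footprint_arms)
    frames = recon.view_share_frames(acq, rcfg)[:max_frames]
    mask = recon.roi_mask(rcfg.grid_size, rcfg.roi_diameter_fraction)
    pixels = np.concatenate([f.pixels[mask] for f in frames])
    return float(pixels.std(ddof=1))


def noise_ratio_for(acq_test: AcquisitionSet, acq_ref: AcquisitionSet,
                    cfg: RunConfig, max_frames: int = 60) -> float:
    return (pooled_noise_sd(acq_test, cfg, max_frames)
            / pooled_noise_sd(acq_ref, cfg, max_frames))


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def run_pipeline(cfg: RunConfig, outdir: str | Path,
                 cancel_method: str = "editer",
                 write_clean: bool = True) -> dict:
    """Run the full chain and write all artifacts into ``outdir``.

    Returns the report dict (also written as ``report.json``); the
    manifest lists every artifact with the stage that produced it.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)
    manifest: dict = {"config": cfg.to_dict(), "stages": {}, "artifacts": {}}

    # -- simulate ------------------------------------------------------
    truth = simulate.gen_physio(
        cfg.sim.duration_s, cfg.sim.tr_s, cfg.sim.heart_rate_bpm,
        cfg.sim.hr_jitter_frac, cfg.sim.resp_rate_hz, cfg.sim.resp_amplitude,
        cfg.sim.rhythm, cfg.sim.arrhythmia_rate, seed=seeds["physio"])
    coupling = simulate.CouplingModel.from_config(cfg.sim, seed=seeds["coupling"])
    acq = simulate.simulate_acquisitions(truth, coupling, cfg.sim,
                                         seed=seeds["acquire"])
    acq_path = write_acquisitions(acq, outdir / "acq.h5")
    write_triggers(truth.beat_triggers, outdir / "truth.csv")
    manifest["artifacts"]["acq"] = acq_path.name
    manifest["artifacts"]["truth_triggers"] = "truth.csv"
    manifest["stages"]["simulate"] = {"n_lines": acq.n_lines,
                                      "n_beats": int(truth.beat_time.size)}

    # -- extract -------------------------------------------------------
    nav, diag = ptnav.extract_navigators(acq, cfg.extract)
    write_navigators(nav.t, nav.resp, nav.card, outdir / "nav.csv")
    (outdir / "channels.json").write_text(json.dumps(diag, sort_keys=True, indent=1))
    manifest["artifacts"]["navigators"] = "nav.csv"
    manifest["artifacts"]["channels"] = "channels.json"
    manifest["stages"]["extract"] = diag

    # -- cancel --------------------------------------------------------
    if cancel_method == "editer":
        model = cancel_mod.editer_fit(acq, cfg.cancel)
        clean, cancel_report = cancel_mod.editer_apply(model, acq)
    elif cancel_method == "model":
        clean, cancel_report = cancel_mod.model_subtract(acq, cfg.cancel)
    elif cancel_method == "none":
        clean, cancel_report = acq, None
    else:
        raise ValueError(f"unknown cancellation method {cancel_method!r}")
    if write_clean and cancel_method != "none":
        write_acquisitions(clean, outdir / "clean.h5")
        manifest["artifacts"]["clean"] = "clean.h5"
    if cancel_report is not None:
        cr = {"mean_residual_db": float(np.mean(cancel_report.residual_db)),
              "n_groups": cancel_report.n_groups,
              "skipped_lines": cancel_report.skipped_lines}
        (outdir / "cancel.json").write_text(json.dumps(cr, sort_keys=True, indent=1))
        manifest["artifacts"]["cancel_report"] = "cancel.json"
        manifest["stages"]["cancel"] = cr

    # -- gate ----------------------------------------------------------
    fs = 1.0 / cfg.sim.tr_s
    pt_triggers = gating_mod.detect_triggers(nav.card, fs, cfg.gating,
                                             t0=float(nav.t[0]))
    write_triggers(pt_triggers, outdir / "pt_triggers.csv")
    match = gating_mod.match_triggers(pt_triggers, truth.beat_triggers)
    report_g = gating_mod.gating_metrics(match)
    bins = gating_mod.assign_bins(nav.resp, pt_triggers, nav.t,
                                  cfg.gating.n_resp_bins, cfg.gating.n_card_bins)
    pd.DataFrame({"t": nav.t, "cardiac_bin": bins.cardiac_bin,
                  "respiratory_bin": bins.respiratory_bin}).to_csv(
        outdir / "bins.csv", index=False, float_format="%.12g")
    manifest["artifacts"]["pt_triggers"] = "pt_triggers.csv"
    manifest["artifacts"]["bins"] = "bins.csv"

    # -- noise ratio ---------------------------------------------------
    noise_cfg = dataclasses.replace(cfg.sim, duration_s=cfg.sim.noise_duration_s)
    truth_n = simulate.gen_physio(
        noise_cfg.duration_s, noise_cfg.tr_s, noise_cfg.heart_rate_bpm,
        noise_cfg.hr_jitter_frac, noise_cfg.resp_rate_hz,
        noise_cfg.resp_amplitude, noise_cfg.rhythm, noise_cfg.arrhythmia_rate,
        seed=seeds["noise_scan"])
    acq_noise = simulate.simulate_acquisitions(
        truth_n, coupling, noise_cfg, noise_only=True, seed=seeds["noise_scan"])
    acq_ref = simulate.simulate_acquisitions(
        truth_n, coupling, noise_cfg, noise_only=True, pt_amplitude=0.0,
        seed=seeds["ref_scan"])
    if cancel_method == "editer":
        nmodel = cancel_mod.editer_fit(acq_noise, cfg.cancel)
        acq_noise_clean, _ = cancel_mod.editer_apply(nmodel, acq_noise)
    elif cancel_method == "model":
        acq_noise_clean, _ = cancel_mod.model_subtract(acq_noise, cfg.cancel)
    else:
        acq_noise_clean = acq_noise
    nratio = noise_ratio_for(acq_noise_clean, acq_ref, cfg)

    report = {
        "gating": report_g.to_dict(),
        "noise_ratio": nratio,
        "cancel_method": cancel_method,
        "seed": cfg.seed,
        "n_lines": acq.n_lines,
        "resp_channels": diag["resp_channels"],
        "card_channels": diag["card_channels"],
    }
    (outdir / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=1))
    manifest["artifacts"]["report"] = "report.json"
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1))
    return report


# ---------------------------------------------------------------------------
# Amplitude sweep
# ---------------------------------------------------------------------------

PAPER_AMPLITUDES = (0.01, 0.02, 0.04, 0.06, 0.08, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0)
"""Default transmit-amplitude grid (signal-generator voltage analogs)."""


@dataclass
class SweepResult:
    """Per-amplitude jitter and noise-ratio trade-off table."""

    amplitude: np.ndarray
    jitter_ms: np.ndarray          # vs true beats; NaN where undefined
    ratio_editer: np.ndarray
    ratio_model: np.ndarray
    ratio_none: np.ndarray
    valid: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "amplitude": self.amplitude,
            "jitter_ms": self.jitter_ms,
            "ratio_editer": self.ratio_editer,
            "ratio_model": self.ratio_model,
            "ratio_none": self.ratio_none,
            "valid": self.valid,
        })


def run_amplitude_sweep(cfg: RunConfig, amplitudes=PAPER_AMPLITUDES,
                        max_noise_frames: int = 60) -> SweepResult:
    """Jitter / noise-amplification trade-off over transmit amplitudes.

    One physiological truth and coupling are shared across the sweep;
    per amplitude a fresh acquisition (seed-controlled noise) is
    simulated, navigators extracted, triggers scored against the true
    beats, and noise-only scans evaluated without cancellation, with
    EDITER and with model subtraction against a common no-carrier
    reference.  A failing amplitude marks its row invalid; the sweep
    continues.
    """
    cfg.validate()
    amplitudes = np.asarray(list(amplitudes), dtype=float)
    if amplitudes.size < 1:
        raise ValueError("need at least one amplitude")
    seeds = stage_seeds(cfg.seed)
    truth = simulate.gen_physio(
        cfg.sim.duration_s, cfg.sim.tr_s, cfg.sim.heart_rate_bpm,
        cfg.sim.hr_jitter_frac, cfg.sim.resp_rate_hz, cfg.sim.resp_amplitude,
        cfg.sim.rhythm, cfg.sim.arrhythmia_rate, seed=seeds["physio"])
    coupling = simulate.CouplingModel.from_config(cfg.sim, seed=seeds["coupling"])

    noise_cfg = dataclasses.replace(cfg.sim, duration_s=cfg.sim.noise_duration_s)
    truth_n = simulate.gen_physio(
        noise_cfg.duration_s, noise_cfg.tr_s, noise_cfg.heart_rate_bpm,
        noise_cfg.hr_jitter_frac, noise_cfg.resp_rate_hz,
        noise_cfg.resp_amplitude, noise_cfg.rhythm, noise_cfg.arrhythmia_rate,
        seed=seeds["noise_scan"])
    acq_ref = simulate.simulate_acquisitions(
        truth_n, coupling, noise_cfg, noise_only=True, pt_amplitude=0.0,
        seed=seeds["ref_scan"])
    sd_ref = pooled_noise_sd(acq_ref, cfg, max_noise_frames)

    n = amplitudes.size
    jitter = np.full(n, np.nan)
    r_editer = np.full(n, np.nan)
    r_model = np.full(n, np.nan)
    r_none = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    amp_seeds = seeds["acquire"].spawn(n)

    for i, (amp, sub) in enumerate(zip(amplitudes, amp_seeds)):
        try:
            s_scan, s_noise = sub.spawn(2)
            acq = simulate.simulate_acquisitions(
                truth, coupling, cfg.sim, pt_amplitude=amp, seed=s_scan)
            try:
                nav, _ = ptnav.extract_navigators(acq, cfg.extract)
                pt = gating_mod.detect_triggers(nav.card, 1.0 / cfg.sim.tr_s,
                                                cfg.gating, t0=float(nav.t[0]))
                if len(pt) >= 2:
                    match = gating_mod.match_triggers(pt, truth.beat_triggers)
                    jitter[i] = gating_mod.gating_metrics(match).jitter_ms
            except (ptnav.ExtractionError,) as exc:
                logger.warning("amplitude %.3g: navigator extraction failed: %s",
                               amp, exc)

            acq_noise = simulate.simulate_acquisitions(
                truth_n, coupling, noise_cfg, noise_only=True,
                pt_amplitude=amp, seed=s_noise)
            r_none[i] = pooled_noise_sd(acq_noise, cfg, max_noise_frames) / sd_ref
            model = cancel_mod.editer_fit(acq_noise, cfg.cancel)
            clean_e, _ = cancel_mod.editer_apply(model, acq_noise)
            r_editer[i] = pooled_noise_sd(clean_e, cfg, max_noise_frames) / sd_ref
            clean_m, _ = cancel_mod.model_subtract(acq_noise, cfg.cancel)
            r_model[i] = pooled_noise_sd(clean_m, cfg, max_noise_frames) / sd_ref
            valid[i] = True
        except Exception as exc:  # noqa: BLE001 - row-level robustness
            logger.error("amplitude %.3g failed: %s", amp, exc)

    return SweepResult(amplitude=amplitudes, jitter_ms=jitter,
                       ratio_editer=r_editer, ratio_model=r_model,
                       ratio_none=r_none, valid=valid)
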
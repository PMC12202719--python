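"""Shared fixtures: small synthetic acquisitions with known truth.

Simulations are session-scoped — they are deterministic (fixed seeds)
and read-only for the tests that share them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from haptic.io_core import RunConfig, SimConfig
from haptic import simulate as sim


@pytest.fixture(scope="session")
def sim_cfg() -> SimConfig:
    """Default acquisition parameters at a short, test-friendly duration."""
    return dataclasses.replace(SimConfig(), duration_s=20.0)


@pytest.fixture(scope="session")
def truth(sim_cfg):
    return sim.gen_physio(sim_cfg.duration_s, sim_cfg.tr_s, seed=101)


@pytest.fixture(scope="session")
def coupling(sim_cfg):
    return sim.CouplingModel.from_config(sim_cfg, seed=102)


@pytest.fixture(scope="session")
def acq(sim_cfg, truth, coupling):
    """20 s default-condition acquisition (phantom + carrier + noise)."""
    return sim.simulate_acquisitions(truth, coupling, sim_cfg, seed=103)


@pytest.fixture(scope="session")
def acq_noiseless(sim_cfg, truth, coupling):
    """Carrier-only acquisition in the noiseless limit."""
    cfg = dataclasses.replace(sim_cfg, noise_sd=0.0, saturation_noise_frac=0.0,
                              phantom_scale=0.0)
    return sim.simulate_acquisitions(truth, coupling, cfg, seed=104)


@pytest.fixture(scope="session")
def tiny_acq(coupling):
    """100-line, 5-sample-coil acquisition for I/O tests."""
    cfg = dataclasses.replace(SimConfig(), duration_s=10.0, n_imaging=3,
                              n_sniffer=2)
    t = sim.gen_physio(10.0, cfg.tr_s, seed=7)
    coup = sim.CouplingModel.from_config(cfg, seed=8)
    full = sim.simulate_acquisitions(t, coup, cfg, seed=9)
    sub = full.copy()
    sub.samples = sub.samples[:100]
    sub.line_time = sub.line_time[:100]
    sub.arm_angle = sub.arm_angle[:100]
    sub.trajectory = sub.trajectory[:100]
    return sub


@pytest.fixture()
def run_cfg() -> RunConfig:
    cfg = RunConfig(seed=11)
    cfg.sim = dataclasses.replace(cfg.sim, duration_s=12.0, noise_duration_s=10.0)
    return cfg
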
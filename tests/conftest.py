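"""Shared fixtures: constructed traces with known content."""

from __future__ import annotations

import numpy as np
import pytest

from ampero import SimulationConfig, Trace
from ampero.simulate import spike_template

FS = 5000.0


def make_trace(current: np.ndarray, fs: float = FS, mode: str = "iviec", **kw) -> Trace:
    time = np.arange(current.size) / fs
    return Trace(time=time, current=np.asarray(current, float), sampling_rate=fs, mode=mode, **kw)


def plant_spikes(
    duration_s: float,
    onsets_s,
    charges_fc,
    rise_tau: float = 0.5,
    decay_tau: float = 3.0,
    noise_sd: float = 0.0,
    fs: float = FS,
    seed: int = 0,
) -> Trace:
    """A trace with template spikes at known onsets (plus optional noise)."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    cur = np.zeros(n)
    for onset, q in zip(onsets_s, charges_fc):
        mask = t >= onset
        cur[mask] += spike_template(t[mask] - onset, q, rise_tau, decay_tau)
    if noise_sd > 0:
        cur += np.random.default_rng(seed).normal(0, noise_sd, n)
    return make_trace(cur)


@pytest.fixture
def sca_config() -> SimulationConfig:
    return SimulationConfig(seed=7)
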
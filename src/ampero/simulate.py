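"""Synthetic SCA / IVIEC current traces and Fura-2 ratio traces.

The generator emulates the standard recording conditions for quantal
exocytosis measurements: 5 kHz digitisation, a 5-s high-K+ stimulation
window for single-cell amperometry (SCA), unstimulated vesicle-rupture
events spread over the whole recording for intracellular vesicle impact
electrochemical cytometry (IVIEC), Gaussian baseline noise and a slow
sinusoidal drift.

Event parameters are drawn from explicit, documented distributions —
Poisson event timing and log-normal quantal sizes.  These distributions
are modelling choices of this package (real recordings pin down only
summary statistics such as per-condition means), so recovery tests
against the simulator validate the analysis code, not any biological
claim; see docs/methods.md.

Spikes are rendered with a difference-of-exponentials template

    i(t) = c · (exp(-t/tau_decay) − exp(-t/tau_rise)),   t >= 0,

scaled so the time integral equals the event charge.  The template is
strictly positive for t > 0 when tau_decay > tau_rise, starts at zero,
and has analytic peak time t* = ln(tau_d/tau_r)·tau_r·tau_d/(tau_d−tau_r).

All randomness flows from ``SimulationConfig.seed`` through
``numpy.random.default_rng``; the same seed reproduces traces
sample-for-sample.  Per-cell seeds are derived as ``seed + cell_index``.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .datatypes import CalciumTrace, GroundTruth, SimulationConfig, Trace
from .errors import ConfigError, ParameterError
from .metrics import charge_from_molecules

__all__ = [
    "spike_template",
    "template_peak",
    "draw_event_ledger",
    "simulate_trace",
    "simulate_condition",
    "simulate_fura2",
]


def _check_taus(rise_tau: float, decay_tau: float) -> None:
    if rise_tau <= 0 or decay_tau <= 0:
        raise ParameterError("rise_tau and decay_tau must be > 0")
    if decay_tau <= rise_tau:
        raise ParameterError(
            "decay_tau must exceed rise_tau for a positive difference-of-exponentials pulse"
        )


def spike_template(t_rel, charge: float, rise_tau: float, decay_tau: float):
    """Current (pA) of one event at time ``t_rel`` seconds after onset.

    Parameters
    ----------
    t_rel : float or ndarray
        Time after event onset, s.  Values < 0 return 0 pA.
    charge : float
        Total charge of the event, fC.  The template integrates to this
        charge over [0, inf) by construction.
    rise_tau, decay_tau : float
        Rise and decay time constants in ms; decay_tau > rise_tau.
    """
    _check_taus(rise_tau, decay_tau)
    if charge <= 0:
        raise ParameterError("charge must be > 0")
    tau_r = rise_tau * 1e-3
    tau_d = decay_tau * 1e-3
    # integral of (e^(-t/tau_d) - e^(-t/tau_r)) over [0, inf) is tau_d - tau_r;
    # charge is in fC and current in pA, 1 fC = 1e-3 pA*s.
    c = (charge * 1e-3) / (tau_d - tau_r)
    t = np.asarray(t_rel, dtype=float)
    out = np.where(t >= 0, c * (np.exp(-t / tau_d) - np.exp(-t / tau_r)), 0.0)
    return float(out) if np.isscalar(t_rel) or out.ndim == 0 else out


def template_peak(charge: float, rise_tau: float, decay_tau: float) -> tuple[float, float]:
    """Analytic (peak_time_s, i_max_pA) of the spike template."""
    _check_taus(rise_tau, decay_tau)
    tau_r = rise_tau * 1e-3
    tau_d = decay_tau * 1e-3
    t_star = math.log(tau_d / tau_r) * tau_r * tau_d / (tau_d - tau_r)
    return t_star, spike_template(t_star, charge, rise_tau, decay_tau)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and CV."""
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


def draw_event_ledger(config: SimulationConfig, mode: str, rng: np.random.Generator) -> GroundTruth:
    """Draw event onsets, quantal sizes and amplitudes (no trace rendering).

    Onsets form a Poisson process at ``event_rate`` inside the
    stimulation window (SCA) or over the whole trace (IVIEC); molecule
    counts are log-normal with mean ``molecules_mean`` and CV
    ``molecules_cv``; charges follow from Faraday's law (n = 2).

    RNG draw order (part of the determinism contract): event count,
    onset times, molecule counts.
    """
    if mode not in ("sca", "iviec"):
        raise ConfigError(f"mode must be 'sca' or 'iviec', got {mode!r}")
    if mode == "sca":
        if config.stim_window is None:
            raise ConfigError("SCA simulation requires a stim_window")
        w0, w1 = config.stim_window
    else:
        w0, w1 = 0.0, config.duration

    n_events = int(rng.poisson(config.event_rate * (w1 - w0)))
    onsets = np.sort(rng.uniform(w0, w1, size=n_events))
    if config.molecules_cv > 0:
        mu, sigma = _lognormal_params(config.molecules_mean, config.molecules_cv)
        molecules = rng.lognormal(mu, sigma, size=n_events)
    else:
        molecules = np.full(n_events, config.molecules_mean)
    charges = np.asarray(charge_from_molecules(molecules), dtype=float).reshape(n_events)
    i_max = np.array(
        [template_peak(q, config.rise_tau, config.decay_tau)[1] for q in charges]
    )
    return GroundTruth(
        onset_time=onsets,
        charge=charges,
        molecules=molecules,
        i_max=i_max,
        noise_sd_true=config.noise_sd,
    )


def simulate_trace(
    config: SimulationConfig,
    mode: str = "sca",
    cell_id: str = "cell_00",
    condition: str = "",
    seed: Optional[int] = None,
) -> tuple[Trace, GroundTruth]:
    """Render one simulated recording and its ground-truth event ledger.

    The trace is the sum of the rendered spike templates, white Gaussian
    noise of SD ``noise_sd`` and a sinusoidal drift of amplitude
    ``drift_amplitude`` whose period is twice the trace duration (so the
    drift never completes a cycle within the record).  Deterministic
    given the seed.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    truth = draw_event_ledger(config, mode, rng)

    n = int(round(config.duration * config.sampling_rate))
    dt = 1.0 / config.sampling_rate
    time = np.arange(n) * dt
    current = np.zeros(n)

    # render each template over a finite support covering >99.99% of its charge
    support = (20.0 * config.decay_tau + 5.0 * config.rise_tau) * 1e-3
    n_sup = int(round(support / dt)) + 1
    for onset, q in zip(truth.onset_time, truth.charge):
        i0 = int(np.ceil(onset / dt))
        i1 = min(i0 + n_sup, n)
        if i1 <= i0:
            continue
        t_rel = time[i0:i1] - onset
        current[i0:i1] += spike_template(t_rel, q, config.rise_tau, config.decay_tau)

    phase = rng.uniform(0.0, 2.0 * math.pi)
    if config.drift_amplitude > 0:
        current += config.drift_amplitude * np.sin(
            2.0 * math.pi * time / (2.0 * config.duration) + phase
        )
    if config.noise_sd > 0:
        current += rng.normal(0.0, config.noise_sd, size=n)

    trace = Trace(
        time=time,
        current=current,
        sampling_rate=config.sampling_rate,
        mode=mode,
        condition=condition,
        cell_id=cell_id,
        stim_window=config.stim_window if mode == "sca" else None,
    )
    return trace, truth


def simulate_condition(
    config: SimulationConfig,
    mode: str = "sca",
    condition: str = "",
) -> list[tuple[Trace, GroundTruth]]:
    """Simulate ``config.n_cells`` independent cells for one condition.

    Cell ``i`` uses seed ``config.seed + i``, so each cell's trace is
    independently reproducible.
    """
    out = []
    for i in range(config.n_cells):
        out.append(
            simulate_trace(
                config,
                mode=mode,
                cell_id=f"cell_{i:03d}",
                condition=condition,
                seed=config.seed + i,
            )
        )
    return out


def simulate_fura2(
    baseline_s: float = 5.0,
    stim_s: float = 5.0,
    response_amplitude: float = 0.5,
    n_cells: int = 30,
    duration: float = 90.0,
    frame_rate: float = 5.0,
    baseline_ratio: float = 0.8,
    decay_tau: float = 15.0,
    background340: float = 50.0,
    background380: float = 80.0,
    f380_level: float = 1000.0,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> list[CalciumTrace]:
    """Simulate per-cell Fura-2 340/380 intensity pairs.

    Emulates the conventional imaging protocol: a 90-s ratiometric
    recording at 340/380 nm with a ``baseline_s`` quiescent period, a
    ``stim_s`` stimulation during which the ratio ramps up by
    ``response_amplitude``, then exponential relaxation (time constant
    ``decay_tau`` s) back toward baseline.  Constant backgrounds are
    added to both channels so downstream background subtraction is
    exercised; Gaussian noise of ``noise_sd`` a.u. is added per channel.
    """
    if baseline_s <= 0:
        raise ParameterError("baseline_s must be > 0")
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    n = int(round(duration * frame_rate))
    time = np.arange(n) / frame_rate

    ramp = np.clip((time - baseline_s) / stim_s, 0.0, 1.0)
    relax = np.where(
        time > baseline_s + stim_s,
        np.exp(-(time - baseline_s - stim_s) / decay_tau),
        1.0,
    )
    response = response_amplitude * ramp * relax

    traces = []
    for i in range(n_cells):
        ratio = baseline_ratio + response
        f380_clean = np.full(n, f380_level)
        f340 = ratio * f380_clean + background340 + rng.normal(0, noise_sd, n)
        f380 = f380_clean + background380 + rng.normal(0, noise_sd, n)
        traces.append(
            CalciumTrace(
                time=time,
                f340=f340,
                f380=f380,
                background340=background340,
                background380=background380,
                cell_id=f"cell_{i:03d}",
            )
        )
    return traces
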
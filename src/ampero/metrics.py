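"""Per-spike quantification: charge, molecule count, and kinetic shape.

The number of molecules N released in one event follows from Faraday's
law, Q = n·N·F, where Q is the oxidation charge carried by the spike, n
the number of electrons exchanged per molecule (2 for catecholamines),
and F = 96,485 C/mol.  Charge is the baseline-corrected time integral of
the spike current; kinetic parameters are read off the spike shape:

* ``i_max`` — baseline-corrected peak current (pA), a proxy for maximal
  transmitter flux through the fusion pore;
* ``t_half`` — full width at half of i_max (ms), the duration of the
  open pore;
* ``t_rise`` — time from 25% to 75% of i_max on the rising limb (ms),
  pore opening kinetics;
* ``t_fall`` — time from 75% to 25% of i_max on the falling limb (ms),
  pore closing kinetics.

All crossing times are interpolated linearly between samples, so they
are sub-sample accurate on smoothed traces.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .datatypes import (
    FaradayConstants,
    SpikeCandidate,
    SpikeEvent,
    Trace,
)
from .errors import ParameterError

__all__ = [
    "molecules_from_charge",
    "charge_from_molecules",
    "integrate_charge",
    "shape_parameters",
    "tail_charge_correction",
    "quantify_events",
]

#: 1 pA·s = 1e-12 C = 1000 fC.
FC_PER_PA_S = 1000.0


def molecules_from_charge(charge_fc, constants: FaradayConstants | None = None):
    """Convert spike charge (fC) to a molecule count via Faraday's law.

    N_molecules = (Q / (n·F)) · N_A, with Q in coulombs.  Linear in Q.
    Accepts scalars or arrays; negative charge raises.
    """
    constants = constants or FaradayConstants()
    q = np.asarray(charge_fc, dtype=float)
    if np.any(q < 0):
        raise ParameterError("charge must be non-negative")
    coulombs = q * 1e-15
    moles = coulombs / (constants.n_electrons * constants.faraday)
    out = moles * constants.avogadro
    return float(out) if np.isscalar(charge_fc) or out.ndim == 0 else out


def charge_from_molecules(molecules, constants: FaradayConstants | None = None):
    """Inverse of :func:`molecules_from_charge`: molecules → charge in fC."""
    constants = constants or FaradayConstants()
    n = np.asarray(molecules, dtype=float)
    if np.any(n < 0):
        raise ParameterError("molecule count must be non-negative")
    coulombs = n / constants.avogadro * constants.n_electrons * constants.faraday
    out = coulombs * 1e15
    return float(out) if np.isscalar(molecules) or out.ndim == 0 else out


def integrate_charge(
    trace: Trace,
    candidate: SpikeCandidate,
    baseline: np.ndarray,
) -> float:
    """Trapezoidal charge (fC) of one event over its half-open extent.

    Integrates max(current − baseline, 0) over [onset_index, end_index);
    negative-going excursions are clipped at baseline before integration
    because only the oxidation (positive) current carries released
    molecules.
    """
    i0, i1 = candidate.onset_index, candidate.end_index
    if i1 <= i0:
        raise ParameterError("candidate has inverted boundaries")
    if i0 < 0 or i1 > trace.n_samples:
        raise ParameterError("candidate extent lies outside the trace")
    y = np.clip(trace.current[i0:i1] - np.asarray(baseline)[i0:i1], 0.0, None)
    q_pa_s = np.trapezoid(y, dx=trace.dt)
    return float(q_pa_s * FC_PER_PA_S)


def _cross_up(t: np.ndarray, y: np.ndarray, level: float) -> float:
    """Time of the first upward crossing of `level`, linearly interpolated."""
    below = y < level
    idx = np.flatnonzero(below[:-1] & ~below[1:])
    if idx.size == 0:
        return math.nan
    i = idx[0]
    frac = (level - y[i]) / (y[i + 1] - y[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def _cross_down(t: np.ndarray, y: np.ndarray, level: float) -> float:
    """Time of the last downward crossing of `level`, linearly interpolated."""
    above = y >= level
    idx = np.flatnonzero(above[:-1] & ~above[1:])
    if idx.size == 0:
        return math.nan
    i = idx[-1]
    frac = (y[i] - level) / (y[i] - y[i + 1])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def shape_parameters(
    trace: Trace,
    candidate: SpikeCandidate,
    baseline: np.ndarray,
) -> tuple[float, float, float, float]:
    """Kinetic shape of one event: (i_max pA, t_half ms, t_rise ms, t_fall ms).

    t_half spans the first upward and last downward crossing of 50% of
    i_max; t_rise the 25%→75% upward crossings on the rising limb;
    t_fall the 75%→25% downward crossings on the falling limb.  Any
    parameter whose crossings cannot be located (event truncated above
    the crossing level, or fewer than 3 samples) comes back NaN; the
    caller keeps the charge and excludes the event from shape
    statistics.
    """
    i0, i1 = candidate.onset_index, candidate.end_index
    if i1 - i0 < 3:
        raise ParameterError("candidate must span at least 3 samples")
    t = trace.time[i0:i1]
    y = trace.current[i0:i1] - np.asarray(baseline)[i0:i1]
    ipk = int(np.argmax(y))
    i_max = float(y[ipk])
    if i_max <= 0:
        raise ParameterError("event has non-positive peak after baseline correction")

    rise_t, rise_y = t[: ipk + 1], y[: ipk + 1]
    fall_t, fall_y = t[ipk:], y[ipk:]

    up50 = _cross_up(rise_t, rise_y, 0.5 * i_max)
    down50 = _cross_down(fall_t, fall_y, 0.5 * i_max)
    up25 = _cross_up(rise_t, rise_y, 0.25 * i_max)
    up75 = _cross_up(rise_t, rise_y, 0.75 * i_max)
    down75 = _cross_down(fall_t, fall_y, 0.75 * i_max)
    down25 = _cross_down(fall_t, fall_y, 0.25 * i_max)

    t_half = (down50 - up50) * 1e3 if not (math.isnan(up50) or math.isnan(down50)) else math.nan
    t_rise = (up75 - up25) * 1e3 if not (math.isnan(up25) or math.isnan(up75)) else math.nan
    t_fall = (down25 - down75) * 1e3 if not (math.isnan(down75) or math.isnan(down25)) else math.nan
    return i_max, t_half, t_rise, t_fall


#: ln(75%/25%): an exponential decay spends t_fall = tau * ln 3 between the
#: 75% and 25% crossings, so tau is recoverable from the measured fall time
_LN3 = math.log(3.0)


def tail_charge_correction(t_fall_ms: float, tail_level_pa: float) -> float:
    """Charge (fC) lost below the event-boundary level on the decay tail.

    Event extents end where the current drops below the boundary level
    L (baseline + boundary_multiplier x noise SD), so the integral
    misses the residual exponential tail, about L*tau with
    tau = t_fall / ln 3.  1 pA*ms = 1 fC.  Returns 0 when t_fall is
    unavailable.
    """
    if tail_level_pa <= 0 or not math.isfinite(t_fall_ms):
        return 0.0
    return tail_level_pa * (t_fall_ms / _LN3)


def quantify_events(
    trace: Trace,
    candidates: Sequence[SpikeCandidate],
    baseline: np.ndarray,
    constants: FaradayConstants | None = None,
    tail_level: float = 0.0,
) -> list[SpikeEvent]:
    """Quantify every candidate on a trace into SpikeEvents.

    Events too short for shape estimation keep their charge and carry
    NaN shape parameters.  ``tail_level`` (pA) is the boundary level
    used to delimit event extents; when given, the exponential
    tail charge truncated below it is added back per event (see
    :func:`tail_charge_correction`).
    """
    constants = constants or FaradayConstants()
    events: list[SpikeEvent] = []
    for cand in candidates:
        q = integrate_charge(trace, cand, baseline)
        try:
            i_max, t_half, t_rise, t_fall = shape_parameters(trace, cand, baseline)
        except ParameterError:
            y = trace.current[cand.onset_index : cand.end_index] - np.asarray(baseline)[
                cand.onset_index : cand.end_index
            ]
            i_max = float(max(y.max(), 0.0))
            t_half = t_rise = t_fall = math.nan
        q += tail_charge_correction(t_fall, tail_level)
        events.append(
            SpikeEvent(
                cell_id=trace.cell_id,
                condition=trace.condition,
                mode=trace.mode,
                peak_time=float(trace.time[cand.peak_index]),
                i_max=i_max,
                charge=q,
                molecules=molecules_from_charge(q, constants),
                t_half=t_half,
                t_rise=t_rise,
                t_fall=t_fall,
            )
        )
    return events
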
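"""Core data containers for amperometric and Ca2+ trace analysis.

A :class:`Trace` is a uniformly sampled current-vs-time recording in pA,
acquired either in single-cell amperometry mode (``"sca"``: a disk
electrode apposed to a cell records exocytotic release spikes during a
stimulation window) or in intracellular vesicle impact electrochemical
cytometry mode (``"iviec"``: a nanotip electrode inside the cell records
vesicle rupture spikes not locked to any stimulus).

Detected events travel through the pipeline as :class:`SpikeCandidate`
(sample-index extents on a trace) and, once quantified, as
:class:`SpikeEvent` (charge, molecule count via Faraday's law, and the
kinetic shape parameters i_max, t_half, t_rise, t_fall).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ParameterError

__all__ = [
    "Trace",
    "SimulationConfig",
    "GroundTruth",
    "DetectionConfig",
    "SpikeCandidate",
    "SpikeEvent",
    "FaradayConstants",
    "StatResult",
    "CalciumTrace",
    "ResponseCurve",
    "events_to_frame",
    "EVENT_COLUMNS",
]

#: Faraday constant in C/mol.
FARADAY_C_PER_MOL = 96485.0
#: Avogadro's number, molecules/mol.
AVOGADRO = 6.02214076e23

MODES = ("sca", "iviec")


@dataclass(frozen=True)
class FaradayConstants:
    """Constants for charge → molecule conversion (Q = nNF).

    ``n_electrons`` defaults to 2, the two-electron oxidation of
    catecholamines at a carbon surface; it is configurable for other
    analytes.
    """

    n_electrons: int = 2
    faraday: float = FARADAY_C_PER_MOL
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        if self.n_electrons <= 0:
            raise ParameterError("n_electrons must be a positive integer")
        if self.faraday <= 0 or self.avogadro <= 0:
            raise ParameterError("physical constants must be positive")


@dataclass
class Trace:
    """A uniformly sampled current time series with recording metadata.

    Parameters
    ----------
    time : ndarray
        Sample times in seconds, strictly increasing, uniform to 1 ppm.
    current : ndarray
        Current in pA, finite at every sample.
    sampling_rate : float
        Acquisition rate in Hz (5000 Hz is the conventional digitisation
        rate for amperometry after a 2-kHz hardware filter).
    mode : str
        ``"sca"`` or ``"iviec"``.
    condition : str
        Experimental condition label (e.g. ``"control"``, ``"ogdr"``).
    cell_id : str
        Identifier of the recorded cell.
    stim_window : (float, float) or None
        Stimulation window (start_s, end_s); required for SCA, None for
        IVIEC.
    """

    time: np.ndarray
    current: np.ndarray
    sampling_rate: float
    mode: str = "sca"
    condition: str = ""
    cell_id: str = ""
    stim_window: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.ndim != 1 or self.current.ndim != 1:
            raise ParameterError("time and current must be 1-D arrays")
        if self.time.size != self.current.size:
            raise ParameterError("time and current must have equal length")
        if self.time.size < 2:
            raise ParameterError("a trace needs at least two samples")
        if self.mode not in MODES:
            raise ParameterError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not np.all(np.isfinite(self.current)):
            raise ParameterError("current contains non-finite samples")
        dt = np.diff(self.time)
        expected = 1.0 / self.sampling_rate
        if np.any(dt <= 0) or np.any(np.abs(dt / expected - 1.0) > 1e-6):
            raise ParameterError(
                "time must be strictly increasing and uniform at 1/sampling_rate (1 ppm)"
            )
        if self.stim_window is not None:
            s, e = self.stim_window
            if not (self.time[0] - expected <= s < e <= self.time[-1] + expected):
                raise ParameterError("stim_window must lie within the trace")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def copy_with(self, **changes) -> "Trace":
        return replace(self, **changes)


@dataclass
class SimulationConfig:
    """Design constants for a simulated recording.

    Defaults mirror the conventional experiment: 5 kHz digitisation, a
    5-s high-K+ stimulation starting after a 2-s baseline, Poisson event
    timing at 3 events/s inside the window, right-skewed (log-normal)
    quantal sizes with CV 0.8, ~0.3 pA Gaussian noise and a 2-pA slow
    sinusoidal drift.

    Attributes
    ----------
    sampling_rate : Hz
    duration : s
    stim_window : (start_s, end_s) or None (None for IVIEC)
    event_rate : events/s inside the window (SCA) or over the trace (IVIEC)
    n_cells : number of cells simulated by :func:`simulate_condition`
    molecules_mean : target mean quantal size, molecules/event
    molecules_cv : coefficient of variation of the log-normal quantal size
    rise_tau, decay_tau : spike template time constants, ms
    noise_sd : white Gaussian noise SD, pA
    drift_amplitude : amplitude of the slow sinusoidal baseline drift, pA
    seed : RNG seed; all simulator randomness flows from it
    """

    sampling_rate: float = 5000.0
    duration: float = 10.0
    stim_window: Optional[tuple[float, float]] = (2.0, 7.0)
    event_rate: float = 3.0
    n_cells: int = 20
    molecules_mean: float = 105_000.0
    molecules_cv: float = 0.8
    rise_tau: float = 0.5
    decay_tau: float = 3.0
    noise_sd: float = 0.3
    drift_amplitude: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be > 0")
        if self.duration <= 0:
            raise ConfigError("duration must be > 0")
        if self.event_rate < 0:
            raise ConfigError("event_rate must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.molecules_mean <= 0:
            raise ConfigError("molecules_mean must be > 0")
        if self.molecules_cv < 0:
            raise ConfigError("molecules_cv must be >= 0")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ConfigError("rise_tau and decay_tau must be > 0")
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        if self.stim_window is not None:
            s, e = self.stim_window
            if not (0.0 <= s < e <= self.duration):
                raise ConfigError("stim_window must be contained in [0, duration]")


@dataclass
class GroundTruth:
    """The simulator's event ledger, for recovery testing.

    Per-event arrays are sorted by onset time.  ``molecules`` and
    ``charge`` are consistent under Faraday's law with n = 2 electrons.
    """

    onset_time: np.ndarray  # s
    charge: np.ndarray  # fC
    molecules: np.ndarray  # count
    i_max: np.ndarray  # pA, template peak amplitude
    noise_sd_true: float  # pA

    def __post_init__(self) -> None:
        self.onset_time = np.asarray(self.onset_time, dtype=float)
        self.charge = np.asarray(self.charge, dtype=float)
        self.molecules = np.asarray(self.molecules, dtype=float)
        self.i_max = np.asarray(self.i_max, dtype=float)
        if not (
            self.onset_time.size == self.charge.size == self.molecules.size == self.i_max.size
        ):
            raise ParameterError("ground-truth arrays must have equal length")
        if np.any(np.diff(self.onset_time) < 0):
            raise ParameterError("ground-truth events must be sorted by onset_time")

    @property
    def n_events(self) -> int:
        return self.onset_time.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_time_s": self.onset_time,
                "charge_fC": self.charge,
                "molecules": self.molecules,
                "i_max_pA": self.i_max,
            }
        )


@dataclass
class DetectionConfig:
    """Spike detection parameters.

    The detection threshold is ``threshold_multiplier`` (default 5) times
    the noise SD; event extents run to the crossings of baseline +
    ``boundary_multiplier`` (default 1) times the noise SD.
    """

    filter_cutoff: float = 1000.0  # Hz
    threshold_multiplier: float = 5.0
    boundary_multiplier: float = 1.0
    noise_window: Optional[tuple[float, float]] = None  # None = automatic
    min_separation: float = 3.0  # ms
    min_charge: float = 1.0  # fC; false-positive filter
    min_width: float = 1.0  # ms; false-positive filter
    min_rise_samples: int = 3  # false-positive filter
    stim_only: bool = False
    post_window: float = 1.0  # s kept after stim end when stim_only

    def __post_init__(self) -> None:
        if not (self.threshold_multiplier > self.boundary_multiplier > 0):
            raise ConfigError("need threshold_multiplier > boundary_multiplier > 0")
        if self.filter_cutoff <= 0:
            raise ConfigError("filter_cutoff must be > 0")
        if self.min_separation < 0 or self.min_width < 0 or self.min_charge < 0:
            raise ConfigError("min_separation, min_width, min_charge must be >= 0")


@dataclass
class SpikeCandidate:
    """A detected spike as half-open sample extent [onset_index, end_index) on a trace."""

    onset_index: int
    peak_index: int
    end_index: int
    baseline: float  # pA, local baseline level at the peak

    def __post_init__(self) -> None:
        if not (self.onset_index <= self.peak_index < self.end_index):
            raise ParameterError(
                "candidate indices must satisfy onset <= peak < end "
                f"(got {self.onset_index}, {self.peak_index}, {self.end_index})"
            )


@dataclass
class SpikeEvent:
    """One quantified exocytotic (SCA) or vesicle-rupture (IVIEC) event.

    Shape parameters are NaN when the event was too short or too shallow
    for sub-sample crossing estimation; charge is always reported.
    """

    cell_id: str
    condition: str
    mode: str
    peak_time: float  # s
    i_max: float  # pA, baseline-corrected
    charge: float  # fC
    molecules: float  # count
    t_half: float = math.nan  # ms
    t_rise: float = math.nan  # ms
    t_fall: float = math.nan  # ms


EVENT_COLUMNS = [
    "cell_id",
    "condition",
    "mode",
    "peak_time_s",
    "i_max_pA",
    "charge_fC",
    "molecules",
    "t_half_ms",
    "t_rise_ms",
    "t_fall_ms",
]


def events_to_frame(events: Sequence[SpikeEvent]) -> pd.DataFrame:
    """Tabulate SpikeEvents into the canonical event table."""
    return pd.DataFrame(
        [
            (
                e.cell_id,
                e.condition,
                e.mode,
                e.peak_time,
                e.i_max,
                e.charge,
                e.molecules,
                e.t_half,
                e.t_rise,
                e.t_fall,
            )
            for e in events
        ],
        columns=EVENT_COLUMNS,
    )


@dataclass
class StatResult:
    """Outcome of a two-sample Mann–Whitney rank-sum comparison."""

    u_statistic: float
    p_value: float
    n1: int
    n2: int
    mean1: float
    sem1: float
    mean2: float
    sem2: float
    method: str  # "exact" | "normal-approximation"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ParameterError("p_value must be in [0, 1]")
        if self.u_statistic < 0 or self.u_statistic > self.n1 * self.n2:
            raise ParameterError("U must lie in [0, n1*n2]")


@dataclass
class CalciumTrace:
    """Fura-2 ROI intensity time series at 340 and 380 nm excitation."""

    time: np.ndarray  # s
    f340: np.ndarray  # a.u.
    f380: np.ndarray  # a.u.
    background340: float | np.ndarray = 0.0
    background380: float | np.ndarray = 0.0
    cell_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.f340 = np.asarray(self.f340, dtype=float)
        self.f380 = np.asarray(self.f380, dtype=float)
        if not (self.time.size == self.f340.size == self.f380.size):
            raise ParameterError("time, f340 and f380 must have equal length")


@dataclass
class ResponseCurve:
    """Across-cell mean ± SEM of the 340/380 ratio over time."""

    time: np.ndarray
    mean_ratio: np.ndarray
    sem_ratio: np.ndarray
    n_cells: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "mean": self.mean_ratio,
                "sem": self.sem_ratio,
                "n": self.n_cells,
            }
        )
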
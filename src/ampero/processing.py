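"""Trace filtering, noise estimation, baseline tracking and spike detection.

Detection follows the standard amperometry workflow: the raw trace is
binomially smoothed to a 1-kHz bandwidth, the noise floor is estimated
robustly on a quiescent segment, and local maxima of the
baseline-corrected current exceeding five noise standard deviations are
taken as spikes.  Each spike is extended to the crossings of
baseline + 1×SD to define its extent.  Deterministic false-positive
filters (minimum charge, minimum width, minimum rising span) stand in
for the manual trace curation used with interactive analysis software.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .datatypes import DetectionConfig, SpikeCandidate, Trace
from .errors import ParameterError
from .metrics import FC_PER_PA_S

__all__ = [
    "smoothing_passes",
    "binomial_smooth",
    "estimate_noise_sd",
    "rolling_baseline",
    "detect_spikes",
    "estimate_baseline",
    "process_trace",
]

_KERNEL = np.array([0.25, 0.5, 0.25])

#: block length (s) for the block-median baseline tracker
_BASELINE_BLOCK_S = 0.05
#: threshold floor (pA) so zero-noise traces keep a finite detection threshold
_NOISE_FLOOR_PA = 1e-9


def smoothing_passes(cutoff: float, sampling_rate: float) -> int:
    """Number of (1/4, 1/2, 1/4) passes placing the −3 dB point at or below `cutoff`.

    One pass has amplitude response H(f) = cos²(πf/fs); p passes give
    cos^(2p)(πf/fs).  Solving cos^(2p)(πfc/fs) = 2^(−1/2) yields

        p >= ln 2 / (4 · ln(1/cos(π·fc/fs)))

    and the smallest such integer (at least 1) is returned.
    """
    if cutoff <= 0:
        raise ParameterError("cutoff must be > 0")
    if cutoff > sampling_rate / 2:
        raise ParameterError("cutoff must not exceed the Nyquist frequency")
    theta = math.pi * cutoff / sampling_rate
    c = math.cos(theta)
    if c <= 0:  # cutoff at Nyquist: a single pass already nulls it
        return 1
    p = math.log(2.0) / (4.0 * math.log(1.0 / c))
    return max(1, math.ceil(p - 1e-12))


def binomial_smooth(trace: Trace, cutoff: float = 1000.0) -> Trace:
    """Binomial smoothing to the requested −3 dB bandwidth.

    Convolves iteratively with the normalised kernel (1/4, 1/2, 1/4),
    repeated :func:`smoothing_passes` times; edges are handled by
    reflection so the output has the input's length and a DC gain of
    exactly 1.
    """
    p = smoothing_passes(cutoff, trace.sampling_rate)
    y = trace.current
    for _ in range(p):
        padded = np.pad(y, 1, mode="reflect")
        y = np.convolve(padded, _KERNEL, mode="valid")
    return trace.copy_with(current=y)


def _auto_noise_window(trace: Trace) -> tuple[float, float]:
    """Pre-stimulation segment for SCA; first 10% of the trace for IVIEC."""
    if trace.mode == "sca" and trace.stim_window is not None:
        return (float(trace.time[0]), float(trace.stim_window[0]))
    span = trace.time[-1] - trace.time[0]
    return (float(trace.time[0]), float(trace.time[0] + 0.1 * span))


def estimate_noise_sd(trace: Trace, window: Optional[tuple[float, float]] = None) -> float:
    """Robust noise SD (pA) on a quiescent window.

    Detrends the windowed current with the block-median baseline and
    returns 1.4826 × the median absolute deviation of the residual — a
    consistent estimator of the Gaussian SD that tolerates a small
    fraction of contaminating spikes.
    """
    if window is None:
        window = _auto_noise_window(trace)
    w0, w1 = window
    if w0 < trace.time[0] - trace.dt or w1 > trace.time[-1] + trace.dt or w1 <= w0:
        raise ParameterError("noise window lies outside the trace")
    mask = (trace.time >= w0) & (trace.time < w1)
    x = trace.current[mask]
    if x.size < 100:
        raise ParameterError(
            f"noise window holds {x.size} samples; at least 100 are required"
        )
    base = _block_median_baseline(x, trace.sampling_rate)
    resid = x - base
    return float(1.4826 * np.median(np.abs(resid - np.median(resid))))


def _block_median_baseline(current: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Slow baseline as block medians interpolated to the full grid.

    Medians over non-overlapping 50-ms blocks are insensitive to sparse
    spikes (a few ms wide each) while tracking drift far slower than the
    block; linear interpolation between block centres returns a smooth
    per-sample baseline.
    """
    n = current.size
    block = max(3, int(round(_BASELINE_BLOCK_S * sampling_rate)))
    if n < 2 * block:
        return np.full(n, float(np.median(current)))
    n_blocks = n // block
    trimmed = current[: n_blocks * block].reshape(n_blocks, block)
    med = np.median(trimmed, axis=1)
    centers = (np.arange(n_blocks) + 0.5) * block
    return np.interp(np.arange(n), centers, med)


def rolling_baseline(trace: Trace) -> np.ndarray:
    """Per-sample slow baseline of a trace (block-median tracker)."""
    return _block_median_baseline(trace.current, trace.sampling_rate)


def _boundaries(x: np.ndarray, peaks: np.ndarray, level: float) -> tuple[np.ndarray, np.ndarray]:
    """Half-open [onset, end) extents around each peak.

    An extent edge is the nearest run of 3 consecutive samples below
    `level`; requiring a run (rather than a single sample) stops a lone
    noise dip on the decay tail from truncating the event.
    """
    below = x < level
    run = below[:-2] & below[1:-1] & below[2:]
    run_idx = np.flatnonzero(run)
    onsets = np.empty(peaks.size, dtype=int)
    ends = np.empty(peaks.size, dtype=int)
    for k, p in enumerate(peaks):
        j = np.searchsorted(run_idx, p)
        onsets[k] = run_idx[j - 1] + 1 if j > 0 else 0
        ends[k] = min(run_idx[j] + 2, x.size) if j < run_idx.size else x.size
    return onsets, ends


def detect_spikes(
    trace: Trace,
    config: DetectionConfig | None = None,
    noise_sd: Optional[float] = None,
) -> list[SpikeCandidate]:
    """Detect spike candidates on an (already filtered) trace.

    Local maxima of the baseline-corrected current above
    ``threshold_multiplier × noise_sd`` become candidates.  Maxima
    closer than ``min_separation`` whose connecting valley stays above
    half the lower peak are treated as ripple on one event and merged
    (the higher peak is kept); genuinely separate peaks keep both
    candidates, with the shared boundary split at the inter-peak
    minimum.  Deterministic false-positive filters then drop candidates
    below ``min_charge``, narrower than ``min_width``, or rising over
    fewer than ``min_rise_samples`` samples.  With ``stim_only`` set,
    SCA candidates must peak inside [stim_start, stim_end + post_window].
    """
    config = config or DetectionConfig()
    if noise_sd is None:
        noise_sd = estimate_noise_sd(trace, config.noise_window)
    sd = max(float(noise_sd), _NOISE_FLOOR_PA)

    base = rolling_baseline(trace)
    x = trace.current - base
    height = config.threshold_multiplier * sd
    peaks, _ = find_peaks(x, height=height)
    if peaks.size == 0:
        return []

    # merge ripple maxima into their parent spike: two maxima belong to one
    # event when the valley between them stays above half the lower maximum
    # (noise ripple on a flank), or when they sit closer than min_separation
    # without the valley returning to the boundary level
    boundary = config.boundary_multiplier * sd
    min_sep = int(round(config.min_separation * 1e-3 * trace.sampling_rate))
    merged = [int(peaks[0])]
    for p in peaks[1:]:
        p = int(p)
        last = merged[-1]
        valley = float(x[last : p + 1].min())
        shallow = valley > 0.5 * min(x[last], x[p])
        if shallow or (p - last < min_sep and valley > boundary):
            if x[p] > x[last]:
                merged[-1] = p
            continue
        merged.append(p)
    peaks = np.array(merged)

    # second pass: the naive rolling baseline rides up inside events, so
    # re-estimate an event-aware baseline from the preliminary extents and
    # re-derive peaks and extents against it
    onsets0, ends0 = _boundaries(x, peaks, boundary)
    prelim = [
        SpikeCandidate(int(o), int(p), int(e), float(base[p]))
        for o, p, e in zip(onsets0, peaks, ends0)
        if o <= p < e
    ]
    base = estimate_baseline(trace, prelim)
    x = trace.current - base
    keep = x[peaks] >= height
    peaks = peaks[keep]
    if peaks.size == 0:
        return []
    onsets, ends = _boundaries(x, peaks, boundary)

    # split extents shared by neighbouring peaks at the inter-peak minimum
    for k in range(peaks.size - 1):
        if ends[k] > onsets[k + 1]:
            split = peaks[k] + int(np.argmin(x[peaks[k] : peaks[k + 1] + 1]))
            ends[k] = split
            onsets[k + 1] = split

    min_width = int(round(config.min_width * 1e-3 * trace.sampling_rate))
    dt = trace.dt
    out: list[SpikeCandidate] = []
    for onset, peak, end in zip(onsets, peaks, ends):
        if end - onset < max(min_width, 2):
            continue
        if peak - onset < config.min_rise_samples:
            continue
        charge = np.trapezoid(np.clip(x[onset:end], 0.0, None), dx=dt) * FC_PER_PA_S
        if charge < config.min_charge:
            continue
        if config.stim_only and trace.stim_window is not None:
            t_peak = trace.time[peak]
            if not (trace.stim_window[0] <= t_peak <= trace.stim_window[1] + config.post_window):
                continue
        out.append(
            SpikeCandidate(
                onset_index=int(onset),
                peak_index=int(peak),
                end_index=int(end),
                baseline=float(base[peak]),
            )
        )
    return out


def estimate_baseline(trace: Trace, candidates: Sequence[SpikeCandidate]) -> np.ndarray:
    """Per-sample baseline excluding detected events.

    Block medians are computed only from samples outside every candidate
    extent and interpolated across events; blocks dominated by events
    are dropped.  If no block survives (a degenerate all-event trace)
    the baseline falls back to the straight line between the trace
    endpoints.
    """
    n = trace.n_samples
    in_event = np.zeros(n, dtype=bool)
    for c in candidates:
        in_event[c.onset_index : c.end_index] = True

    block = max(3, int(round(_BASELINE_BLOCK_S * trace.sampling_rate)))
    n_blocks = n // block
    if n_blocks < 2:
        clean = trace.current[~in_event]
        level = float(np.median(clean)) if clean.size else float(np.median(trace.current))
        return np.full(n, level)

    centers, meds = [], []
    for b in range(n_blocks):
        sl = slice(b * block, (b + 1) * block)
        keep = ~in_event[sl]
        if keep.sum() >= block // 2:
            centers.append((b + 0.5) * block)
            meds.append(float(np.median(trace.current[sl][keep])))
    if not centers:
        return np.linspace(trace.current[0], trace.current[-1], n)
    return np.interp(np.arange(n), centers, meds)


def process_trace(
    trace: Trace,
    config: DetectionConfig | None = None,
) -> tuple[Trace, float, list[SpikeCandidate], np.ndarray]:
    """Filter → noise floor → detect → event-aware baseline, in one call.

    Returns (filtered trace, noise_sd, candidates, baseline array); the
    candidates and baseline refer to the filtered trace.
    """
    config = config or DetectionConfig()
    filtered = binomial_smooth(trace, config.filter_cutoff)
    sd = estimate_noise_sd(filtered, config.noise_window)
    candidates = detect_spikes(filtered, config, noise_sd=sd)
    baseline = estimate_baseline(filtered, candidates)
    return filtered, sd, candidates, baseline
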
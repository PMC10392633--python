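"""Fura-2 ratiometric Ca2+ trace analysis.

Fura-2's excitation spectrum shifts with Ca2+ binding, so the ratio of
background-corrected emission at 340-nm over 380-nm excitation tracks
cytosolic free Ca2+ independently of dye loading.  This module turns
per-ROI 340/380 intensity series into per-cell ratio traces and
across-cell mean ± SEM response curves, optionally baseline-normalised
(Δr = r − mean ratio over the pre-stimulus window).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .datatypes import CalciumTrace, ResponseCurve
from .errors import ParameterError

__all__ = ["ratio_trace", "align_and_average"]


def ratio_trace(trace: CalciumTrace) -> tuple[np.ndarray, np.ndarray]:
    """Background-corrected 340/380 ratio of one cell.

    r(t) = (F340 − bg340) / (F380 − bg380).  Frames where the corrected
    F380 is non-positive carry no usable denominator and come back NaN;
    if every frame is invalid the trace is unusable and an error is
    raised.  Returns (time, ratio).
    """
    f340 = trace.f340 - np.asarray(trace.background340, dtype=float)
    f380 = trace.f380 - np.asarray(trace.background380, dtype=float)
    valid = f380 > 0
    if not valid.any():
        raise ParameterError("all frames invalid: corrected F380 <= 0 everywhere")
    ratio = np.full(trace.time.size, np.nan)
    ratio[valid] = f340[valid] / f380[valid]
    return trace.time.copy(), ratio


def align_and_average(
    traces: Sequence[tuple[np.ndarray, np.ndarray]],
    baseline_window: Optional[tuple[float, float]] = (0.0, 5.0),
    normalize: bool = False,
) -> ResponseCurve:
    """Across-cell mean ± SEM ratio curve on a common time grid.

    Traces are (time, ratio) pairs; any trace not on the first trace's
    grid is linearly resampled onto it.  With ``normalize`` the mean of
    each trace over ``baseline_window`` is subtracted first (Δr
    curves); by default absolute ratios are averaged.  Needs at least
    two traces.
    """
    if len(traces) < 2:
        raise ParameterError("align_and_average needs at least 2 traces")
    t_ref = np.asarray(traces[0][0], dtype=float)
    rows = []
    for t, r in traces:
        t = np.asarray(t, dtype=float)
        r = np.asarray(r, dtype=float)
        if t.size != t_ref.size or not np.allclose(t, t_ref):
            r = np.interp(t_ref, t, r)
        if normalize:
            if baseline_window is None:
                raise ParameterError("normalize requires a baseline_window")
            w0, w1 = baseline_window
            sel = (t_ref >= w0) & (t_ref < w1)
            if not sel.any():
                raise ParameterError("baseline_window contains no frames")
            r = r - np.nanmean(r[sel])
        rows.append(r)
    mat = np.vstack(rows)
    n = mat.shape[0]
    mean = np.nanmean(mat, axis=0)
    sem = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(n)
    return ResponseCurve(time=t_ref, mean_ratio=mean, sem_ratio=sem, n_cells=n)
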
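"""File round-trips: traces (HDF5/CSV), event tables, ledgers, Ca2+ CSVs.

HDF5 traces hold ``time`` and ``current`` datasets with acquisition
metadata as root attributes and round-trip bit-exactly; the CSV dialect
is a two-column ``time_s,current_pA`` table with a sidecar
``<stem>.meta.json`` metadata file and round-trips to <= 1e-9 relative
error.  Malformed inputs raise :class:`~ampero.errors.ParseError`
naming the offending field or column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .datatypes import EVENT_COLUMNS, CalciumTrace, GroundTruth, Trace
from .errors import ParseError

__all__ = [
    "write_trace_h5",
    "read_trace_h5",
    "write_trace_csv",
    "read_trace_csv",
    "write_events",
    "read_events",
    "write_ground_truth",
    "read_ground_truth",
    "read_calcium_csv",
]

_CSV_FLOAT_FMT = "%.12g"


def _meta_dict(trace: Trace) -> dict:
    return {
        "sampling_rate": trace.sampling_rate,
        "mode": trace.mode,
        "condition": trace.condition,
        "cell_id": trace.cell_id,
        "stim_start": None if trace.stim_window is None else trace.stim_window[0],
        "stim_end": None if trace.stim_window is None else trace.stim_window[1],
    }


def _trace_from_meta(time: np.ndarray, current: np.ndarray, meta: dict, source: str) -> Trace:
    for key in ("sampling_rate", "mode"):
        if key not in meta or meta[key] is None:
            raise ParseError(f"{source}: missing metadata field {key!r}")
    stim = None
    if meta.get("stim_start") is not None and meta.get("stim_end") is not None:
        stim = (float(meta["stim_start"]), float(meta["stim_end"]))
    return Trace(
        time=time,
        current=current,
        sampling_rate=float(meta["sampling_rate"]),
        mode=str(meta["mode"]),
        condition=str(meta.get("condition", "") or ""),
        cell_id=str(meta.get("cell_id", "") or ""),
        stim_window=stim,
    )


def write_trace_h5(trace: Trace, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("time", data=trace.time)
        f.create_dataset("current", data=trace.current)
        for key, val in _meta_dict(trace).items():
            f.attrs[key] = "" if val is None else val


def read_trace_h5(path: str | Path) -> Trace:
    with h5py.File(path, "r") as f:
        for name in ("time", "current"):
            if name not in f:
                raise ParseError(f"{path}: missing dataset {name!r}")
        time = f["time"][:]
        current = f["current"][:]
        meta = {k: (None if isinstance(v, str) and v == "" else v) for k, v in f.attrs.items()}
    return _trace_from_meta(time, current, meta, str(path))


def write_trace_csv(trace: Trace, path: str | Path) -> None:
    """Two-column CSV plus a ``<stem>.meta.json`` sidecar."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.time, "current_pA": trace.current}).to_csv(
        path, index=False, float_format=_CSV_FLOAT_FMT
    )
    path.with_suffix(".meta.json").write_text(json.dumps(_meta_dict(trace), indent=1))


def read_trace_csv(path: str | Path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "current_pA"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    sidecar = path.with_suffix(".meta.json")
    if not sidecar.exists():
        raise ParseError(f"{path}: sidecar metadata file {sidecar.name} not found")
    meta = json.loads(sidecar.read_text())
    return _trace_from_meta(
        df["time_s"].to_numpy(), df["current_pA"].to_numpy(), meta, str(path)
    )


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ParseError(f"event table lacks column {missing[0]!r}")
    events.to_csv(path, index=False, float_format=_CSV_FLOAT_FMT)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return df


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    truth.to_frame().to_csv(path, index=False, float_format=_CSV_FLOAT_FMT)


def read_ground_truth(path: str | Path, noise_sd_true: float = float("nan")) -> GroundTruth:
    df = pd.read_csv(path)
    for col in ("onset_time_s", "charge_fC", "molecules", "i_max_pA"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return GroundTruth(
        onset_time=df["onset_time_s"].to_numpy(),
        charge=df["charge_fC"].to_numpy(),
        molecules=df["molecules"].to_numpy(),
        i_max=df["i_max_pA"].to_numpy(),
        noise_sd_true=noise_sd_true,
    )


def read_calcium_csv(path: str | Path, cell_id: str = "", condition: str = "") -> CalciumTrace:
    """Read a Fura-2 ROI series: time_s, F340, F380 (+ optional bg340/bg380)."""
    df = pd.read_csv(path)
    for col in ("time_s", "F340", "F380"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    bg340 = df["bg340"].to_numpy() if "bg340" in df.columns else 0.0
    bg380 = df["bg380"].to_numpy() if "bg380" in df.columns else 0.0
    return CalciumTrace(
        time=df["time_s"].to_numpy(),
        f340=df["F340"].to_numpy(),
        f380=df["F380"].to_numpy(),
        background340=bg340,
        background380=bg380,
        cell_id=cell_id,
        condition=condition,
    )
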
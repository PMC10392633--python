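"""Cell-level aggregation, fraction of release, and group comparisons.

The statistical unit is the cell: per-event measurements are first
summarised per cell (mean and median of molecules, i_max, t_half,
t_rise, t_fall), and condition groups are compared on per-cell means
with the unpaired two-sided Mann–Whitney rank-sum test.  A pooled-event
mode is available for comparisons made directly on events.

The fraction of vesicular release is the mean number of molecules
released per exocytotic event (SCA) divided by the mean number stored
per vesicle (IVIEC), expressed in percent.  It is a ratio of group
means — SCA and IVIEC cells are distinct populations, so no pairing
exists — and is reported both at full precision and rounded to the
nearest integer percent.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import StatResult
from .errors import ParameterError

__all__ = [
    "aggregate_cells",
    "group_summary",
    "fraction_of_release",
    "mann_whitney",
    "fraction_bootstrap_ci",
    "compare_groups",
]

_PARAMS = ["molecules", "i_max_pA", "t_half_ms", "t_rise_ms", "t_fall_ms"]


def aggregate_cells(events: pd.DataFrame) -> pd.DataFrame:
    """One row per cell: event count plus mean/median of each spike parameter.

    Shape parameters flagged NaN (events too short for crossing
    estimation) are excluded from their summaries.  Rows are ordered by
    cell_id; an empty event table yields an empty frame with the same
    columns.
    """
    cols = ["cell_id", "condition", "mode", "n_events"]
    for p in _PARAMS:
        cols += [f"{p}_mean", f"{p}_median"]
    if events.empty:
        return pd.DataFrame(columns=cols)
    missing = {"cell_id", *_PARAMS} - set(events.columns)
    if missing:
        raise ParameterError(f"event table lacks columns: {sorted(missing)}")

    rows = []
    for cell_id, grp in events.groupby("cell_id", sort=True):
        row = {
            "cell_id": cell_id,
            "condition": grp["condition"].iloc[0] if "condition" in grp else "",
            "mode": grp["mode"].iloc[0] if "mode" in grp else "",
            "n_events": int(len(grp)),
        }
        for p in _PARAMS:
            vals = grp[p].dropna()
            row[f"{p}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{p}_median"] = float(vals.median()) if len(vals) else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def group_summary(values: Iterable[float]) -> tuple[float, float]:
    """Mean and SEM (sample SD / sqrt(n)) of per-cell values; needs n >= 2."""
    x = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if x.size < 2:
        raise ParameterError("group_summary needs at least 2 finite values")
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size))


def fraction_of_release(released_mean: float, stored_mean: float) -> tuple[float, int]:
    """Percent of vesicular content released per event.

    Returns (unrounded percent, nearest-integer percent).
    """
    if stored_mean <= 0:
        raise ParameterError("stored_mean must be > 0")
    if released_mean < 0:
        raise ParameterError("released_mean must be >= 0")
    pct = 100.0 * released_mean / stored_mean
    return pct, int(round(pct))


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Unpaired two-sided Mann–Whitney rank-sum test.

    Uses the exact null distribution when there are no ties and
    n1·n2 <= 400, otherwise the normal approximation with tie and
    continuity corrections; the method used is recorded in the result.
    The reported U is the statistic of the first sample.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (not has_ties) and (x.size * y.size <= 400)
    res = sps.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    mean1 = float(x.mean())
    mean2 = float(y.mean())
    sem1 = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    sem2 = float(y.std(ddof=1) / np.sqrt(y.size)) if y.size > 1 else 0.0
    return StatResult(
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=int(x.size),
        n2=int(y.size),
        mean1=mean1,
        sem1=sem1,
        mean2=mean2,
        sem2=sem2,
        method="exact" if exact else "normal-approximation",
    )


def fraction_bootstrap_ci(
    released_cells: Sequence[float],
    stored_cells: Sequence[float],
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile 95% CI (percent) of the ratio of group means.

    Cells are resampled with replacement independently in the released
    (SCA) and stored (IVIEC) groups; deterministic given the seed.
    """
    rel = np.asarray(released_cells, dtype=float)
    sto = np.asarray(stored_cells, dtype=float)
    if rel.size == 0 or sto.size == 0:
        raise ParameterError("both groups must be non-empty")
    if n_boot < 100:
        raise ParameterError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    ri = rng.integers(0, rel.size, size=(n_boot, rel.size))
    si = rng.integers(0, sto.size, size=(n_boot, sto.size))
    ratios = 100.0 * rel[ri].mean(axis=1) / sto[si].mean(axis=1)
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return float(lo), float(hi)


def compare_groups(
    cells: pd.DataFrame,
    events: pd.DataFrame,
    parameter: str,
    condition_a: str,
    condition_b: str,
    pooled: bool = False,
) -> StatResult:
    """Mann–Whitney comparison of one spike parameter between two conditions.

    By default per-cell means are compared (the cell is the statistical
    unit); with ``pooled=True`` all events are pooled per condition.
    """
    if pooled:
        src, col = events, parameter
    else:
        src, col = cells, f"{parameter}_mean"
    if col not in src.columns:
        raise ParameterError(f"column {col!r} not present")
    a = src.loc[src["condition"] == condition_a, col].dropna().to_numpy()
    b = src.loc[src["condition"] == condition_b, col].dropna().to_numpy()
    return mann_whitney(a, b)
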
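"""Time-dependent glycemic metrics.

Metrics that need evenly spaced measurements (CONGA, MODD, the Rodbard
SD decomposition, CV-by-day, MAG, hourly AUC, rate of change) are
computed on the day-by-day grid from :mod:`cgmkit.gridding`; ADRR and
GVP operate directly on the raw timestamped readings.  Missing grid
cells are handled by pairwise deletion throughout, and a metric with no
valid pairs or blocks returns NaN.

Every operation accepts a :class:`~cgmkit.io.CGMTable` (returning a
per-subject DataFrame), a single-subject frame, or — for the grid-based
metrics — a prebuilt :class:`~cgmkit.gridding.DayGrid`.
"""

from __future__ import annotations

import logging
from typing import Callable

import numpy as np
import pandas as pd

from .distribution import (
    bgi, cogi, ea1c, gmi, grade_family, hyper_index, hypo_index, igc,
    j_index, m_value, mage, percent_above, percent_below, percent_in_range,
    risk_transform, summary_glu,
)
from .gridding import DayGrid, active_percent, day_by_day
from .io import CGMTable
from .params import MetricParams, as_params

logger = logging.getLogger(__name__)


def _nan_sd(x: np.ndarray) -> float:
    """Sample SD ignoring NaN; NaN when fewer than 2 values remain."""
    x = x[~np.isnan(x)]
    return float(np.std(x, ddof=1)) if x.size > 1 else float("nan")


def _as_grid(data, params: MetricParams | None) -> DayGrid:
    if isinstance(data, DayGrid):
        return data
    return day_by_day(data, params)


def _dispatch_grid(data, fn: Callable[[DayGrid], dict], params: MetricParams | None):
    if isinstance(data, CGMTable) and data.n_subjects > 1:
        rows = []
        for sid, sub in data.iter_subjects():
            rows.append({"id": sid, **fn(day_by_day(sub, params))})
        return pd.DataFrame(rows)
    return fn(_as_grid(data, params))


def _dispatch_series(data, fn: Callable[[pd.DataFrame], dict]):
    if isinstance(data, CGMTable):
        if data.n_subjects > 1:
            return pd.DataFrame([{"id": sid, **fn(sub)} for sid, sub in data.iter_subjects()])
        return fn(data.subject(data.subject_ids[0]))
    return fn(data.sort_values("time").reset_index(drop=True))


# ---------------------------------------------------------------- CONGA

def conga(data, n_hours: float | None = None, params: MetricParams | None = None):
    """Continuous overall net glycemic action.

    Sample SD of the differences between grid values ``n_hours`` apart
    on the day-concatenated grid, over pairs where both cells are
    observed.  NaN when no valid pair exists.
    """
    p = as_params(params)
    n = n_hours if n_hours is not None else p.conga_hours

    def one(grid: DayGrid) -> dict:
        lag = int(round(n * 60.0 / grid.dt0))
        flat = grid.flatten()
        if lag < 1 or lag >= flat.size:
            return {"conga": float("nan")}
        d = flat[lag:] - flat[:-lag]
        return {"conga": _nan_sd(d)}

    return _dispatch_grid(data, one, p)


# ---------------------------------------------------------------- MODD

def modd(data, params: MetricParams | None = None):
    """Mean of daily differences: |g(t) − g(t − 24 h)| averaged.

    Computed column-wise between consecutive day rows of the grid over
    cells observed on both days.
    """

    def one(grid: DayGrid) -> dict:
        if grid.n_days < 2:
            raise ValueError("MODD needs at least 2 days of data")
        d = np.abs(grid.gd2d[1:] - grid.gd2d[:-1])
        valid = d[~np.isnan(d)]
        return {"modd": float(np.mean(valid)) if valid.size else float("nan")}

    return _dispatch_grid(data, one, params)


# ------------------------------------------------- SD decomposition

def sd_measures(data, params: MetricParams | None = None):
    """Rodbard's six SD subtypes on the day-by-day grid.

    - ``SdW``    mean of within-day SDs
    - ``SdHHMM`` SD across time-of-day of the column means
    - ``SdWSH``  mean of SDs within non-overlapping 1-hour blocks
    - ``SdDM``   SD of the daily means
    - ``SdB``    mean across time-of-day of the between-day SDs
    - ``SdBDM``  SdB after removing each day's mean (day-centered)

    All SDs are sample-based; rows, columns or blocks with fewer than
    two observed cells are skipped.
    """

    def one(grid: DayGrid) -> dict:
        x = grid.gd2d
        if grid.n_days < 2 or grid.n_cols < 2:
            raise ValueError("SD decomposition needs >= 2 days and >= 2 grid columns")
        within = np.array([_nan_sd(row) for row in x])
        col_means = np.array([
            float(np.nanmean(c)) if np.any(~np.isnan(c)) else np.nan
            for c in x.T
        ])
        hour_cells = max(int(round(60.0 / grid.dt0)), 1)
        blocks = []
        for row in x:
            for start in range(0, row.size, hour_cells):
                blocks.append(_nan_sd(row[start:start + hour_cells]))
        day_means = np.array([
            float(np.nanmean(r)) if np.any(~np.isnan(r)) else np.nan for r in x
        ])
        between = np.array([_nan_sd(c) for c in x.T])
        centered = x - day_means[:, None]
        between_dm = np.array([_nan_sd(c) for c in centered.T])
        return {
            "SdW": float(np.nanmean(within)) if np.any(~np.isnan(within)) else float("nan"),
            "SdHHMM": _nan_sd(col_means),
            "SdWSH": float(np.nanmean(blocks)) if np.any(~np.isnan(blocks)) else float("nan"),
            "SdDM": _nan_sd(day_means),
            "SdB": float(np.nanmean(between)) if np.any(~np.isnan(between)) else float("nan"),
            "SdBDM": float(np.nanmean(between_dm)) if np.any(~np.isnan(between_dm)) else float("nan"),
        }

    return _dispatch_grid(data, one, params)


def cv_measures(data, params: MetricParams | None = None):
    """Mean and SD across days of the per-day CV (100·sd/mean, %).

    Days with fewer than two observed cells are skipped; ``CVsd`` is
    NaN when fewer than two usable days remain.
    """

    def one(grid: DayGrid) -> dict:
        cvs = []
        for row in grid.gd2d:
            vals = row[~np.isnan(row)]
            if vals.size > 1:
                cvs.append(100.0 * float(np.std(vals, ddof=1)) / float(np.mean(vals)))
        cvs = np.array(cvs)
        return {
            "CVmean": float(np.mean(cvs)) if cvs.size else float("nan"),
            "CVsd": float(np.std(cvs, ddof=1)) if cvs.size > 1 else float("nan"),
        }

    return _dispatch_grid(data, one, params)


# ---------------------------------------------------------------- ADRR

def adrr(data, params: MetricParams | None = None):
    """Average daily risk range.

    Per local calendar day, the maximum low risk plus the maximum high
    risk from the Kovatchev transform (each 0 when no reading of that
    sign); ADRR is the mean of the daily sums.
    """

    def one(sub: pd.DataFrame) -> dict:
        if sub.empty:
            raise ValueError("ADRR needs at least one day of readings")
        days = pd.to_datetime(sub["time"]).dt.normalize()
        totals = []
        for _, day in sub.groupby(days, sort=True):
            _, rl, rh = risk_transform(day["gl"].to_numpy(dtype=float))
            totals.append(float(np.max(rl)) + float(np.max(rh)))
        return {"adrr": float(np.mean(totals))}

    return _dispatch_series(data, one)


# ---------------------------------------------------------------- GVP

def gvp(data, params: MetricParams | None = None):
    """Glucose variability percentage: excess arc length of the trace.

    Over consecutive reading pairs no more than ``inter_gap`` minutes
    apart, L = Σ √(Δt² + Δg²) (Δt in minutes, Δg in mg/dL) against the
    flat-line length L0 = Σ Δt; GVP = 100·(L/L0 − 1) ≥ 0.
    """
    p = as_params(params)

    def one(sub: pd.DataFrame) -> dict:
        t = pd.to_datetime(sub["time"]).astype("int64").to_numpy() / 60e9  # minutes
        g = sub["gl"].to_numpy(dtype=float)
        dt = np.diff(t)
        dg = np.diff(g)
        ok = dt <= p.inter_gap
        if not np.any(ok):
            raise ValueError("no reading pair within inter_gap; cannot compute GVP")
        L = float(np.sum(np.sqrt(dt[ok] ** 2 + dg[ok] ** 2)))
        L0 = float(np.sum(dt[ok]))
        return {"gvp": 100.0 * (L / L0 - 1.0)}

    return _dispatch_series(data, one)


# ---------------------------------------------------------------- MAG

def mag(data, n_minutes: float | None = None, params: MetricParams | None = None):
    """Mean absolute glucose change per hour.

    The concatenated grid is subsampled every ``n_minutes`` (default
    60); MAG is the summed |Δg| between successive observed samples
    divided by the hours elapsed between the first and last used
    sample.
    """
    p = as_params(params)
    n = n_minutes if n_minutes is not None else p.mag_minutes

    def one(grid: DayGrid) -> dict:
        step = max(int(round(n / grid.dt0)), 1)
        flat = grid.flatten()[::step]
        obs = np.flatnonzero(~np.isnan(flat))
        if obs.size < 2:
            return {"mag": float("nan")}
        vals = flat[obs]
        hours = (obs[-1] - obs[0]) * step * grid.dt0 / 60.0
        return {"mag": float(np.sum(np.abs(np.diff(vals)))) / hours}

    return _dispatch_grid(data, one, p)


# ---------------------------------------------------------------- AUC

def auc(data, params: MetricParams | None = None):
    """Hourly average area under the glucose curve, averaged over days.

    Per day, trapezoids over adjacent observed cell pairs (width
    dt0/60 h), normalized by the covered width so the result is an
    hourly average in mg/dL; days without an adjacent pair are skipped.
    """

    def one(grid: DayGrid) -> dict:
        w = grid.dt0 / 60.0
        daily = []
        for row in grid.gd2d:
            pair_ok = ~np.isnan(row[:-1]) & ~np.isnan(row[1:])
            if not np.any(pair_ok):
                continue
            area = float(np.sum(w * (row[:-1][pair_ok] + row[1:][pair_ok]) / 2.0))
            daily.append(area / (w * int(np.sum(pair_ok))))
        return {"auc": float(np.mean(daily)) if daily else float("nan")}

    return _dispatch_grid(data, one, params)


# ---------------------------------------------------------------- ROC

def roc(data, timelag: float | None = None, params: MetricParams | None = None) -> np.ndarray:
    """Rate of change (mg/dL/min) over the concatenated grid.

    roc_t = (g_t − g_{t−timelag}) / timelag wherever both cells are
    observed; returns the list of rates for a single subject or grid.
    """
    p = as_params(params)
    lag_min = timelag if timelag is not None else p.roc_timelag

    def one(grid: DayGrid) -> np.ndarray:
        lag = max(int(round(lag_min / grid.dt0)), 1)
        flat = grid.flatten()
        return (flat[lag:] - flat[:-lag]) / (lag * grid.dt0)

    if isinstance(data, CGMTable) and data.n_subjects > 1:
        raise ValueError("roc returns a per-reading series; slice one subject first")
    return one(_as_grid(data, p))


def sd_roc(data, timelag: float | None = None, params: MetricParams | None = None):
    """Sample SD of the rate of change — a local-variability summary."""
    p = as_params(params)

    def one(grid: DayGrid) -> dict:
        return {"sd_roc": _nan_sd(roc(grid, timelag, p))}

    return _dispatch_grid(data, one, p)


# ---------------------------------------------------------------- all

#: column order of the combined per-subject metric matrix
ALL_METRIC_BLOCKS = (
    "summary", "percent_above", "percent_below", "percent_in_range",
    "ea1c", "gmi", "j_index", "m_value", "grade", "bgi",
    "hyper_index", "hypo_index", "igc", "cogi", "mage",
    "conga", "modd", "sd_measures", "cv_measures",
    "adrr", "gvp", "mag", "auc", "sd_roc", "active_percent",
)


def all_metrics(table: CGMTable, params: MetricParams | None = None) -> pd.DataFrame:
    """Every implemented metric for every subject, one row per subject.

    Metrics that fail on a subject (too little data) become NaN with a
    logged warning rather than aborting the whole matrix.  The column
    order is fixed: distribution block first, then the grid/time block.
    """
    p = as_params(params)
    rows = []
    for sid, sub in table.iter_subjects():
        row: dict = {"id": sid}
        g = sub["gl"].to_numpy(dtype=float)

        def safe(fn, *args, **kwargs) -> dict:
            try:
                return fn(*args, **kwargs)
            except (ValueError, KeyError) as exc:
                logger.warning("%s failed for subject %s: %s", fn.__name__, sid, exc)
                return {}

        row.update(safe(summary_glu, g, p))
        row.update(safe(percent_above, g, params=p))
        row.update(safe(percent_below, g, params=p))
        row.update(safe(percent_in_range, g, params=p))
        row.update(safe(ea1c, g))
        row.update(safe(gmi, g))
        row.update(safe(j_index, g))
        row.update(safe(m_value, g, params=p))
        row.update(safe(grade_family, g, params=p))
        row.update(safe(bgi, g))
        row.update(safe(hyper_index, g, params=p))
        row.update(safe(hypo_index, g, params=p))
        row.update(safe(igc, g, params=p))
        row.update(safe(cogi, g))
        row.update(safe(mage, g))

        try:
            grid = day_by_day(sub, p)
        except ValueError as exc:
            logger.warning("gridding failed for subject %s: %s", sid, exc)
            grid = None
        if grid is not None:
            row.update(safe(conga, grid, params=p))
            row.update(safe(modd, grid, params=p))
            row.update(safe(sd_measures, grid, params=p))
            row.update(safe(cv_measures, grid, params=p))
            row.update(safe(mag, grid, params=p))
            row.update(safe(auc, grid, params=p))
            row.update(safe(sd_roc, grid, params=p))
        row.update(safe(adrr, sub))
        row.update(safe(gvp, sub, params=p))
        ap = safe(active_percent, sub, p)
        if ap:
            row["active_percent"] = ap["active_percent"]
            row["ndays"] = ap["ndays"]
        rows.append(row)
    return pd.DataFrame(rows)
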
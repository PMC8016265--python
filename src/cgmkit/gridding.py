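"""Equidistant day-by-day gridding of a CGM trace.

Several variability metrics (CONGA, MODD, the Rodbard SD decomposition,
rate of change, ...) need glucose on an evenly spaced grid aligned
across days.  :func:`day_by_day` linearly interpolates a single
subject's readings onto a grid of period ``dt0`` minutes, one row per
calendar day, refusing to bridge gaps longer than ``inter_gap`` minutes
and never extrapolating beyond the observed span.

Grid convention: column ``j`` (1-based) is the time of day ``j * dt0``
minutes after local midnight, so a 5-minute grid has 288 columns at
00:05, 00:10, ..., 24:00.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .params import MetricParams, as_params

MINUTES_PER_DAY = 1440


@dataclass
class DayGrid:
    """Interpolated glucose grid for one subject.

    Attributes
    ----------
    gd2d
        Array of shape ``(n_days, 1440 // dt0)``, mg/dL, NaN where no
        interpolation was possible.
    actual_dates
        Calendar date of each row, consecutive and strictly increasing.
    dt0
        Grid period, minutes; divides 1440.
    """

    gd2d: np.ndarray
    actual_dates: list[date]
    dt0: int

    @property
    def n_days(self) -> int:
        return self.gd2d.shape[0]

    @property
    def n_cols(self) -> int:
        return self.gd2d.shape[1]

    def flatten(self) -> np.ndarray:
        """Day-concatenated series (row-major)."""
        return self.gd2d.reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Debug export: ISO-date row labels, HH:MM column labels."""
        cols = [f"{(j * self.dt0) // 60 % 24:02d}:{(j * self.dt0) % 60:02d}"
                for j in range(1, self.n_cols + 1)]
        return pd.DataFrame(self.gd2d, index=[d.isoformat() for d in self.actual_dates], columns=cols)


def _divisors_of_day() -> np.ndarray:
    return np.array([d for d in range(1, MINUTES_PER_DAY + 1) if MINUTES_PER_DAY % d == 0])


def infer_dt0(times: pd.Series | np.ndarray) -> int:
    """Infer the sensor period: rounded median inter-reading interval.

    The median is robust to occasional long gaps.  The result is clamped
    to the nearest divisor of 1440 so that whole days tile exactly.
    """
    t = pd.to_datetime(pd.Series(times)).sort_values()
    if len(t) < 2:
        raise ValueError("need at least 2 timestamps to infer the sensor period")
    diffs = t.diff().dropna().dt.total_seconds() / 60.0
    dt0 = int(round(float(np.median(diffs))))
    dt0 = max(dt0, 1)
    divisors = _divisors_of_day()
    if MINUTES_PER_DAY % dt0 != 0:
        dt0 = int(divisors[np.argmin(np.abs(divisors - dt0))])
    return dt0


def _resolve_series(series) -> pd.DataFrame:
    """Accept a CGMTable holding one subject or a single-subject frame."""
    from .io import CGMTable

    if isinstance(series, CGMTable):
        ids = series.subject_ids
        if len(ids) != 1:
            raise ValueError(
                f"expected a single-subject series, got {len(ids)} subjects; "
                "slice with table.subject(id) first"
            )
        return series.subject(ids[0])
    return series.sort_values("time").reset_index(drop=True)


def day_by_day(series, params: MetricParams | None = None) -> DayGrid:
    """Project a single subject's readings onto the day-by-day grid.

    Each grid point takes the linear interpolation of its two bracketing
    observations iff those observations are at most ``inter_gap``
    minutes apart; otherwise the cell is NaN.  Grid points before the
    first or after the last observation are NaN (no extrapolation).
    """
    params = as_params(params)
    sub = _resolve_series(series)
    if len(sub) < 2:
        raise ValueError("need at least 2 readings to build a day-by-day grid")

    times = pd.to_datetime(sub["time"])
    gl = sub["gl"].to_numpy(dtype=float)

    dt0 = int(params.dt0) if params.dt0 is not None else infer_dt0(times)
    if MINUTES_PER_DAY % dt0 != 0:
        raise ValueError(
            f"dt0 = {dt0} min does not divide 1440; pass an explicit dt0 "
            "(e.g. 5, 10, 15) that tiles a 24-hour day"
        )

    first_day = times.iloc[0].normalize()
    last_day = times.iloc[-1].normalize()
    n_days = (last_day - first_day).days + 1
    n_cols = MINUTES_PER_DAY // dt0

    # minutes since midnight of the first day
    obs_min = (times - first_day).dt.total_seconds().to_numpy() / 60.0
    grid_min = np.arange(1, n_days * n_cols + 1, dtype=float) * dt0

    values = np.full(grid_min.shape, np.nan)
    inside = (grid_min >= obs_min[0]) & (grid_min <= obs_min[-1])
    idx = np.searchsorted(obs_min, grid_min[inside], side="left")
    exact = (idx < len(obs_min)) & np.isclose(
        obs_min[np.minimum(idx, len(obs_min) - 1)], grid_min[inside], rtol=0.0, atol=1e-6
    )

    left = np.clip(idx - 1, 0, len(obs_min) - 1)
    right = np.clip(idx, 0, len(obs_min) - 1)
    gap = obs_min[right] - obs_min[left]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(gap > 0, (grid_min[inside] - obs_min[left]) / np.where(gap > 0, gap, 1.0), 0.0)
    interp = gl[left] + frac * (gl[right] - gl[left])
    ok = exact | (gap <= params.inter_gap)
    out = np.where(exact, gl[np.minimum(idx, len(obs_min) - 1)], interp)
    values[inside] = np.where(ok, out, np.nan)

    dates = [(first_day + pd.Timedelta(days=i)).date() for i in range(n_days)]
    return DayGrid(values.reshape(n_days, n_cols), dates, dt0)


def active_percent(series, params: MetricParams | None = None) -> dict:
    """Fraction of expected grid slots the sensor actually covered.

    Returns ``active_percent`` (%, capped at 100), ``ndays`` (fractional
    days between first and last reading), ``start`` and ``end``
    timestamps, and the ``dt0`` used.  The expected count is
    ``floor((end - start) / dt0) + 1`` over the observed span, so a
    gapless trace scores 100%.
    """
    params = as_params(params)
    sub = _resolve_series(series)
    if len(sub) < 2:
        raise ValueError("need at least 2 readings for active_percent")
    times = pd.to_datetime(sub["time"])
    dt0 = int(params.dt0) if params.dt0 is not None else infer_dt0(times)

    start, end = times.iloc[0], times.iloc[-1]
    span_min = (end - start).total_seconds() / 60.0
    expected = int(np.floor(span_min / dt0)) + 1
    slots = np.round((times - start).dt.total_seconds().to_numpy() / 60.0 / dt0).astype(int)
    observed = len(np.unique(slots))
    pct = min(100.0, 100.0 * observed / expected)
    return {
        "active_percent": pct,
        "ndays": span_min / MINUTES_PER_DAY,
        "start": start,
        "end": end,
        "dt0": dt0,
    }


def active_percent_table(table, params: MetricParams | None = None) -> pd.DataFrame:
    """Per-subject active-percent summary, one row per subject."""
    rows = []
    for sid, sub in table.iter_subjects():
        rec = active_percent(sub, params)
        rows.append({"id": sid, **rec})
    return pd.DataFrame(rows)
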
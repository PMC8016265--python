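"""CGM visualizations: time-series panels, lasagna plots, rate-of-change
views, and the ambulatory glucose profile (AGP) report.

All functions are pure with respect to the data: they never mutate the
input table, contain no randomness, and return matplotlib figures (plus
a summary dataclass for the AGP).  Matplotlib's non-interactive Agg
backend is forced so the module works headless.
"""

from __future__ import annotations

import base64
import io as _io
from dataclasses import dataclass, field
from datetime import date

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import BoundaryNorm, LinearSegmentedColormap, ListedColormap, TwoSlopeNorm

from .distribution import summary_glu
from .gridding import DayGrid, active_percent, day_by_day
from .io import CGMTable
from .params import MetricParams, as_params
from .temporal import roc

# ROC category edges in mg/dL/min, blue (falling) -> white (stable) -> red (rising)
ROC_EDGES = (-np.inf, -3.0, -2.0, -1.0, 1.0, 2.0, 3.0, np.inf)
ROC_COLORS = ("#08306b", "#4292c6", "#c6dbef", "#ffffff", "#fcbba1", "#ef3b2c", "#99000d")

#: anchors of the 'red-orange' scheme: red (low) -> green (in range) ->
#: yellow -> orange (high)
RED_ORANGE_ANCHORS = ("#b2182b", "#1a9850", "#ffffbf", "#e08214")


#: 3-anchor blue -> white -> red gradient; blueness decreases monotonically
#: with glucose so a higher value is never bluer
BLUE_RED_ANCHORS = ("#2166ac", "#f7f7f7", "#b2182b")


def _lasagna_cmap(scheme: str):
    if scheme == "blue-red":
        return LinearSegmentedColormap.from_list("blue-red", BLUE_RED_ANCHORS)
    if scheme == "red-orange":
        return LinearSegmentedColormap.from_list("red-orange", RED_ORANGE_ANCHORS)
    raise ValueError(f"unknown color scheme: {scheme!r}")


@dataclass(frozen=True)
class LasagnaSpec:
    """Rendering options for lasagna plots."""

    datatype: str = "all"            # all | average | single
    sorting: str = "unsorted"        # unsorted | timesorted | subjectsorted
    color_scheme: str = "blue-red"   # blue-red | red-orange
    midpoint: float = 105.0
    limits: tuple[float, float] = (50.0, 500.0)

    def __post_init__(self) -> None:
        lo, hi = self.limits
        if not lo < self.midpoint < hi:
            raise ValueError("limits must bracket the midpoint")
        if self.datatype not in {"all", "average", "single"}:
            raise ValueError(f"unknown datatype: {self.datatype!r}")
        if self.sorting not in {"unsorted", "timesorted", "subjectsorted"}:
            raise ValueError(f"unknown sorting: {self.sorting!r}")


# ------------------------------------------------------------- time series

def plot_glu(table: CGMTable, target_range: tuple[float, float] = (70.0, 180.0),
             log: bool = False) -> plt.Figure:
    """One time-series panel per subject with target-range guide lines."""
    ids = table.subject_ids
    if not ids:
        raise ValueError("empty table")
    fig, axes = plt.subplots(len(ids), 1, figsize=(9, 2.2 * len(ids)),
                             sharex=False, squeeze=False)
    for ax, sid in zip(axes.ravel(), ids):
        sub = table.subject(sid)
        ax.plot(sub["time"], sub["gl"], lw=0.6, color="#333333")
        for bound in target_range:
            ax.axhline(bound, color="red", lw=0.8)
        if log:
            ax.set_yscale("log")
        ax.set_ylabel("mg/dL")
        ax.set_title(str(sid), fontsize=9, loc="left")
    fig.tight_layout()
    return fig


# ---------------------------------------------------------------- lasagna

def _lasagna_matrix(table: CGMTable, spec: LasagnaSpec,
                    params: MetricParams | None) -> tuple[np.ndarray, list[str]]:
    """Rows × time matrix to render, plus row labels."""
    p = as_params(params)
    if spec.datatype == "single":
        ids = table.subject_ids
        if len(ids) != 1:
            raise ValueError("datatype 'single' needs a single-subject table")
        grid = day_by_day(table.subject(ids[0]), p)
        return grid.gd2d, [d.isoformat() for d in grid.actual_dates]

    grids = {sid: day_by_day(sub, p) for sid, sub in table.iter_subjects()}
    if spec.datatype == "average":
        n_cols = max(g.n_cols for g in grids.values())
        rows = []
        for sid, g in grids.items():
            if g.n_cols != n_cols:
                raise ValueError("subjects were gridded at different dt0; pass an explicit dt0")
            with np.errstate(invalid="ignore"):
                rows.append(np.nanmean(g.gd2d, axis=0))
        return np.vstack(rows), list(grids)
    # datatype == "all": subjects across the full (unioned) day span
    n_cols = max(g.n_cols for g in grids.values())
    first = min(g.actual_dates[0] for g in grids.values())
    last = max(g.actual_dates[-1] for g in grids.values())
    span = (last - first).days + 1
    rows = []
    for sid, g in grids.items():
        if g.n_cols != n_cols:
            raise ValueError("subjects were gridded at different dt0; pass an explicit dt0")
        row = np.full(span * n_cols, np.nan)
        start = (g.actual_dates[0] - first).days * n_cols
        row[start:start + g.gd2d.size] = g.flatten()
        rows.append(row)
    return np.vstack(rows), list(grids)


def _apply_sorting(mat: np.ndarray, sorting: str) -> np.ndarray:
    """NaNs stay trailing; observed values are sorted descending."""
    def sort_desc(v: np.ndarray) -> np.ndarray:
        out = np.full_like(v, np.nan)
        vals = np.sort(v[~np.isnan(v)])[::-1]
        out[: vals.size] = vals
        return out

    if sorting == "unsorted":
        return mat
    if sorting == "timesorted":
        return np.apply_along_axis(sort_desc, 0, mat)
    if sorting == "subjectsorted":
        return np.apply_along_axis(sort_desc, 1, mat)
    raise ValueError(f"unknown sorting: {sorting!r}")


def plot_lasagna(table: CGMTable, spec: LasagnaSpec | None = None,
                 params: MetricParams | None = None) -> plt.Figure:
    """Heatmap of glucose over time: rows = days (single subject) or
    subjects (multi-subject), columns = time; color encodes glucose with
    a gradient centered on ``spec.midpoint``.
    """
    spec = spec or LasagnaSpec()
    mat, labels = _lasagna_matrix(table, spec, params)
    mat = _apply_sorting(mat, spec.sorting)

    lo, hi = spec.limits
    data_lo, data_hi = np.nanmin(mat), np.nanmax(mat)
    if data_lo < lo or data_hi > hi:
        import warnings

        warnings.warn(
            f"glucose range [{data_lo:.0f}, {data_hi:.0f}] exceeds lasagna limits "
            f"[{lo:.0f}, {hi:.0f}]; colors are clamped",
            RuntimeWarning,
            stacklevel=2,
        )
    norm = TwoSlopeNorm(vmin=lo, vcenter=spec.midpoint, vmax=hi)
    fig, ax = plt.subplots(figsize=(9, 0.4 * mat.shape[0] + 1.5))
    im = ax.imshow(np.clip(mat, lo, hi), aspect="auto", interpolation="nearest",
                   cmap=_lasagna_cmap(spec.color_scheme), norm=norm)
    ax.set_yticks(range(len(labels)), labels, fontsize=7)
    ax.set_xlabel("time")
    fig.colorbar(im, ax=ax, label="mg/dL")
    fig.tight_layout()
    return fig


# ------------------------------------------------------------------- ROC

def roc_category(rates: np.ndarray) -> np.ndarray:
    """Bin index 0..6 of each rate in the standard ROC categories."""
    return np.digitize(rates, ROC_EDGES[1:-1])


def plot_roc(table: CGMTable, subjects: list[str] | None = None,
             timelag: float | None = None,
             params: MetricParams | None = None) -> plt.Figure:
    """Per-subject glucose series with points colored by rate of change."""
    p = as_params(params)
    ids = subjects if subjects is not None else table.subject_ids
    cmap = ListedColormap(ROC_COLORS)
    norm = BoundaryNorm((-10.0,) + ROC_EDGES[1:-1] + (10.0,), cmap.N)
    fig, axes = plt.subplots(len(ids), 1, figsize=(9, 2.4 * len(ids)), squeeze=False)
    for ax, sid in zip(axes.ravel(), ids):
        sub = table.subject(sid)
        grid = day_by_day(sub, p)
        rates = roc(grid, timelag, p)
        lag = max(int(round((timelag or p.roc_timelag) / grid.dt0)), 1)
        flat = grid.flatten()[lag:]
        x = np.arange(flat.size)
        ok = ~np.isnan(flat) & ~np.isnan(rates)
        ax.scatter(x[ok], flat[ok], c=np.clip(rates[ok], -9.9, 9.9),
                   cmap=cmap, norm=norm, s=3, edgecolors="none")
        ax.set_facecolor("#888888")
        ax.set_ylabel("mg/dL")
        ax.set_title(str(sid), fontsize=9, loc="left")
    fig.tight_layout()
    return fig


def hist_roc(table: CGMTable, subjects: list[str] | None = None,
             timelag: float | None = None,
             params: MetricParams | None = None) -> plt.Figure:
    """Histogram of rate-of-change values per subject, bin-colored."""
    p = as_params(params)
    ids = subjects if subjects is not None else table.subject_ids
    fig, axes = plt.subplots(len(ids), 1, figsize=(7, 2.4 * len(ids)), squeeze=False)
    inner = np.arange(-4.0, 4.01, 0.25)
    for ax, sid in zip(axes.ravel(), ids):
        rates = roc(day_by_day(table.subject(sid), p), timelag, p)
        rates = rates[~np.isnan(rates)]
        counts, edges = np.histogram(np.clip(rates, -4.0, 4.0), bins=inner)
        centers = (edges[:-1] + edges[1:]) / 2
        colors = [ROC_COLORS[i] for i in roc_category(centers)]
        ax.bar(centers, counts, width=0.24, color=colors, edgecolor="#555555", lw=0.3)
        ax.set_xlabel("mg/dL/min")
        ax.set_title(str(sid), fontsize=9, loc="left")
    fig.tight_layout()
    return fig


# ------------------------------------------------------------------- AGP

#: AGP band boundary convention: exact values 54, 70, 180, 250 fall in
#: the bands 54-69, 70-180, 70-180 and 181-250 respectively.
AGP_BAND_NAMES = ("very_low", "low", "target", "high", "very_high")


@dataclass
class AGPSummary:
    """Numeric content of an ambulatory glucose profile report."""

    subject_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    ndays: float
    active_percent: float
    mean: float
    gmi: float
    cv: float
    band_percent: dict[str, float] = field(default_factory=dict)
    #: per-time-of-day quantile curves, keys '5','25','50','75','95'
    quantile_curves: dict[str, np.ndarray] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "start": str(self.start),
            "end": str(self.end),
            "ndays": self.ndays,
            "active_percent": self.active_percent,
            "mean": self.mean,
            "gmi": self.gmi,
            "cv": self.cv,
            "band_percent": self.band_percent,
        }


def agp_bands(values: np.ndarray, cutoffs=(54.0, 70.0, 180.0, 250.0)) -> dict[str, float]:
    """Percent of readings per AGP band; the five percents sum to 100."""
    c1, c2, c3, c4 = cutoffs
    n = values.size
    return {
        "very_low": 100.0 * float(np.sum(values < c1)) / n,
        "low": 100.0 * float(np.sum((values >= c1) & (values < c2))) / n,
        "target": 100.0 * float(np.sum((values >= c2) & (values <= c3))) / n,
        "high": 100.0 * float(np.sum((values > c3) & (values <= c4))) / n,
        "very_high": 100.0 * float(np.sum(values > c4)) / n,
    }


def _most_recent_days(sub: pd.DataFrame, maxd: int) -> pd.DataFrame:
    last_day = pd.to_datetime(sub["time"]).dt.normalize().max()
    cutoff = last_day - pd.Timedelta(days=maxd - 1)
    return sub[pd.to_datetime(sub["time"]).dt.normalize() >= cutoff].reset_index(drop=True)


def agp_report(table: CGMTable, subject_id: str | None = None, maxd: int = 14,
               daily: bool = False,
               params: MetricParams | None = None) -> tuple[AGPSummary, plt.Figure]:
    """Ambulatory glucose profile for one subject.

    Uses the most recent ``maxd`` calendar days, computes the band
    percentages and per-time-of-day 5/25/50/75/95% quantile curves from
    the day-by-day grid, and renders the standard report: stacked band
    bar, quantile ribbon (5-95 and 25-75 shading around the median),
    and optional per-day mini panels.
    """
    p = as_params(params)
    sid = subject_id if subject_id is not None else table.subject_ids[0]
    sub = _most_recent_days(table.subject(sid), maxd)
    if pd.to_datetime(sub["time"]).dt.normalize().nunique() < 1 or len(sub) < 2:
        raise ValueError(f"not enough data for an AGP report for {sid!r}")

    grid = day_by_day(sub, p)
    ap = active_percent(sub, p)
    g = sub["gl"].to_numpy(dtype=float)
    stats = summary_glu(g, p)
    bands = agp_bands(g, p.agp_cutoffs)

    probs = (5, 25, 50, 75, 95)
    with np.errstate(invalid="ignore"):
        curves = {
            str(q): np.nanpercentile(grid.gd2d, q, axis=0)
            for q in probs
        }
    summary = AGPSummary(
        subject_id=sid, start=ap["start"], end=ap["end"], ndays=ap["ndays"],
        active_percent=ap["active_percent"], mean=stats["mean"],
        gmi=3.31 + 0.02392 * stats["mean"], cv=stats["cv"],
        band_percent=bands, quantile_curves=curves,
    )

    fig = plt.figure(figsize=(9, 7.0 if daily else 4.5))
    gs = fig.add_gridspec(3 if daily else 2, 1,
                          height_ratios=[1, 2, 2] if daily else [1, 2])

    # stacked band bar
    ax0 = fig.add_subplot(gs[0])
    left = 0.0
    band_colors = {"very_low": "#8b0000", "low": "#e34a33", "target": "#31a354",
                   "high": "#fec44f", "very_high": "#d95f0e"}
    for name in AGP_BAND_NAMES:
        ax0.barh(0, bands[name], left=left, color=band_colors[name], height=0.5)
        left += bands[name]
    ax0.set_xlim(0, 100)
    ax0.set_yticks([])
    ax0.set_xlabel("% of readings (bands <54 / 54-69 / 70-180 / 181-250 / >250 mg/dL)")
    ax0.set_title(
        f"{sid}: {ap['ndays']:.1f} days, {ap['active_percent']:.1f}% active, "
        f"mean {stats['mean']:.1f} mg/dL, GMI {summary.gmi:.1f}%, CV {stats['cv']:.1f}%",
        fontsize=9,
    )

    # quantile ribbons over time of day
    ax1 = fig.add_subplot(gs[1])
    hours = np.arange(1, grid.n_cols + 1) * grid.dt0 / 60.0
    ax1.fill_between(hours, curves["5"], curves["95"], color="#c6dbef", label="5-95%")
    ax1.fill_between(hours, curves["25"], curves["75"], color="#6baed6", label="25-75%")
    ax1.plot(hours, curves["50"], color="#08306b", lw=1.5, label="median")
    for bound in (70.0, 180.0):
        ax1.axhline(bound, color="green", lw=0.8, ls="--")
    ax1.set_xlim(0, 24)
    ax1.set_xlabel("time of day (h)")
    ax1.set_ylabel("mg/dL")
    ax1.legend(fontsize=7, loc="upper right")

    if daily:
        ax2 = fig.add_subplot(gs[2])
        ax2.imshow(grid.gd2d, aspect="auto", interpolation="nearest",
                   cmap=plt.get_cmap("RdBu_r"),
                   norm=TwoSlopeNorm(vmin=40, vcenter=105, vmax=max(400, float(np.nanmax(grid.gd2d)))))
        ax2.set_yticks(range(grid.n_days),
                       [d.isoformat() for d in grid.actual_dates], fontsize=6)
        ax2.set_xlabel("time of day")
    fig.tight_layout()
    return summary, fig


_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>AGP report — {sid}</title>
<style>body{{font-family:sans-serif;max-width:60em;margin:2em auto}}
table{{border-collapse:collapse}}td,th{{border:1px solid #999;padding:0.3em 0.8em}}</style>
</head><body>
<h1>Ambulatory glucose profile — {sid}</h1>
<p>{start} to {end} ({ndays:.1f} days, sensor active {active:.1f}%)</p>
<table><tr><th>mean (mg/dL)</th><th>GMI (%)</th><th>CV (%)</th></tr>
<tr><td>{mean:.1f}</td><td>{gmi:.1f}</td><td>{cv:.1f}</td></tr></table>
<h2>Time in ranges</h2>
<table><tr><th>&lt;54</th><th>54&ndash;69</th><th>70&ndash;180</th><th>181&ndash;250</th><th>&gt;250</th></tr>
<tr><td>{very_low:.1f}%</td><td>{low:.1f}%</td><td>{target:.1f}%</td><td>{high:.1f}%</td><td>{very_high:.1f}%</td></tr></table>
<h2>Profile</h2>
<img alt="AGP figure" src="data:image/png;base64,{png}" style="max-width:100%">
</body></html>
"""


def write_agp_html(summary: AGPSummary, fig: plt.Figure, path) -> None:
    """Render the AGP as a self-contained HTML file (embedded PNG)."""
    buf = _io.BytesIO()
    fig.savefig(buf, format="png", dpi=110)
    html = _HTML_TEMPLATE.format(
        sid=summary.subject_id, start=summary.start, end=summary.end,
        ndays=summary.ndays, active=summary.active_percent,
        mean=summary.mean, gmi=summary.gmi, cv=summary.cv,
        png=base64.b64encode(buf.getvalue()).decode("ascii"),
        **summary.band_percent,
    )
    with open(path, "w") as fh:
        fh.write(html)
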
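"""CGM data contract: reading, validation and unit conversion.

The canonical on-disk format is a long CSV with three columns — ``id``
(subject label), ``time`` (date-time, second resolution) and ``gl``
(glucose in mg/dL).  In memory the same contract is carried by
:class:`CGMTable`, a thin wrapper around a pandas DataFrame that
guarantees per-subject time ordering, strictly increasing timestamps
(duplicates collapsed) and positive finite glucose.  mg/dL is the
canonical unit everywhere inside the package; mmol/L conversion happens
only at the I/O edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: conversion factor mg/dL per mmol/L (the GRADE transform's g/18)
MGDL_PER_MMOL = 18.0

REQUIRED_COLUMNS = ("id", "time", "gl")


@dataclass
class ValidationReport:
    """Counts collected while cleaning raw rows into a :class:`CGMTable`."""

    raw_rows: int = 0
    dropped_bad_time: int = 0
    dropped_bad_glucose: int = 0
    duplicates_collapsed: int = 0
    per_subject_counts: dict[str, int] = field(default_factory=dict)

    @property
    def dropped_total(self) -> int:
        return self.dropped_bad_time + self.dropped_bad_glucose

    @property
    def retained_rows(self) -> int:
        return sum(self.per_subject_counts.values())


@dataclass
class CGMTable:
    """Validated multi-subject CGM readings in long format.

    ``data`` has columns ``id`` (str), ``time`` (datetime64, naive) and
    ``gl`` (float, mg/dL), sorted by subject first-appearance order then
    by time, with strictly increasing timestamps within each subject.
    """

    data: pd.DataFrame
    report: ValidationReport | None = None

    @property
    def subject_ids(self) -> list[str]:
        """Subjects in order of first appearance."""
        return list(dict.fromkeys(self.data["id"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def __len__(self) -> int:
        return len(self.data)

    def subject(self, subject_id: str) -> pd.DataFrame:
        """One subject's readings, time-sorted."""
        sub = self.data.loc[self.data["id"] == subject_id]
        if sub.empty:
            raise KeyError(f"unknown subject id: {subject_id!r}")
        return sub.reset_index(drop=True)

    def iter_subjects(self) -> Iterable[tuple[str, pd.DataFrame]]:
        for sid in self.subject_ids:
            yield sid, self.subject(sid)

    def select(self, subject_ids: Iterable[str]) -> "CGMTable":
        wanted = list(subject_ids)
        missing = set(wanted) - set(self.subject_ids)
        if missing:
            raise KeyError(f"unknown subject ids: {sorted(missing)}")
        sub = self.data[self.data["id"].isin(wanted)].reset_index(drop=True)
        return CGMTable(sub)


def _frame_from_raw(frame: pd.DataFrame, tz: str | None = None) -> tuple[pd.DataFrame, ValidationReport]:
    """Clean a raw id/time/gl frame and collect a validation report."""
    report = ValidationReport(raw_rows=len(frame))

    out = frame.loc[:, ["id", "time", "gl"]].copy()
    out["id"] = out["id"].astype(str)

    times = pd.to_datetime(out["time"], errors="coerce", format="mixed")
    if isinstance(times.dtype, pd.DatetimeTZDtype):
        times = times.dt.tz_convert(tz) if tz else times
        times = times.dt.tz_localize(None)
    bad_time = times.isna()
    report.dropped_bad_time = int(bad_time.sum())

    gl = pd.to_numeric(out["gl"], errors="coerce")
    bad_gl = ~np.isfinite(gl) | (gl <= 0)
    report.dropped_bad_glucose = int((bad_gl & ~bad_time).sum())

    keep = ~(bad_time | bad_gl)
    out = pd.DataFrame({"id": out.loc[keep, "id"], "time": times[keep], "gl": gl[keep].astype(float)})
    if report.dropped_total:
        logger.warning(
            "dropped %d rows (%d unparseable time, %d non-positive/missing glucose)",
            report.dropped_total, report.dropped_bad_time, report.dropped_bad_glucose,
        )

    # stable sort keeps first occurrence on duplicate timestamps; subjects
    # stay in first-appearance order
    order = pd.Categorical(out["id"], categories=list(dict.fromkeys(out["id"])), ordered=True)
    out = out.assign(_order=order).sort_values(["_order", "time"], kind="mergesort").drop(columns="_order")
    dup = out.duplicated(subset=["id", "time"], keep="first")
    report.duplicates_collapsed = int(dup.sum())
    out = out.loc[~dup].reset_index(drop=True)
    report.per_subject_counts = out["id"].value_counts(sort=False).to_dict()
    return out, report


def read_cgm_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    tz: str | None = None,
) -> CGMTable:
    """Read and validate a long-format CGM CSV.

    Parameters
    ----------
    path
        CSV file with a header row and columns ``id``, ``time``, ``gl``
        (or the names given in ``column_map``).
    column_map
        Mapping from the canonical names ``{"id", "time", "gl"}`` to the
        names used in the file, e.g. ``{"gl": "glucose_mgdl"}``.
    tz
        Optional timezone used to interpret timezone-aware timestamps;
        naive timestamps are kept as local wall-clock times either way.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If a required column cannot be resolved or no valid rows remain.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"CGM CSV not found: {path}")
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"no valid readings in {path}: file is empty") from None

    rename = {}
    for canonical in REQUIRED_COLUMNS:
        source = (column_map or {}).get(canonical, canonical)
        if source not in raw.columns:
            raise ValueError(
                f"cannot resolve column {canonical!r} (looked for {source!r}) "
                f"in {path}; available: {list(raw.columns)}"
            )
        rename[source] = canonical
    raw = raw.rename(columns=rename)

    data, report = _frame_from_raw(raw, tz=tz)
    if data.empty:
        raise ValueError(
            f"no valid readings in {path} "
            f"({report.dropped_total} rows dropped during validation)"
        )
    return CGMTable(data, report)


def table_from_frame(frame: pd.DataFrame, tz: str | None = None) -> CGMTable:
    """Build a validated :class:`CGMTable` from an in-memory id/time/gl frame."""
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"frame is missing required columns: {missing}")
    data, report = _frame_from_raw(frame, tz=tz)
    if data.empty:
        raise ValueError("no valid readings in frame")
    return CGMTable(data, report)


def validate_table(table: CGMTable) -> CGMTable:
    """Re-run validation (sort, dedup, drop bad rows) on an existing table."""
    data, report = _frame_from_raw(table.data)
    if data.empty:
        raise ValueError("no valid readings after validation")
    return CGMTable(data, report)


def convert_units(values, direction: str):
    """Convert glucose between mg/dL and mmol/L (factor 18.0).

    ``direction`` is ``"mgdl_to_mmol"`` or ``"mmol_to_mgdl"``.  Values
    must be positive and finite; the round trip is an identity to float
    precision.
    """
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("glucose values must be positive and finite")
    if direction == "mgdl_to_mmol":
        out = arr / MGDL_PER_MMOL
    elif direction == "mmol_to_mgdl":
        out = arr * MGDL_PER_MMOL
    else:
        raise ValueError(f"unknown direction: {direction!r}")
    return float(out) if np.isscalar(values) else out


def write_cgm_csv(table: CGMTable, path: str | Path) -> None:
    """Write a table back to the canonical CSV dialect (id, time, gl)."""
    out = table.data.copy()
    out["time"] = out["time"].dt.strftime("%Y-%m-%d %H:%M:%S")
    out.to_csv(path, index=False)


def write_metrics_csv(result: pd.DataFrame, path: str | Path) -> None:
    """Write a per-subject metric table to CSV at full float precision."""
    if result is None or result.empty:
        raise ValueError("refusing to write an empty metric result")
    result.to_csv(path, index=False)
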
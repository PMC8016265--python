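"""Time-independent glycemic metrics.

Everything here is a function of a subject's pooled glucose values
(mg/dL) alone — the timestamps play no role.  Each operation accepts
either a plain sequence of values or a :class:`~cgmkit.io.CGMTable`;
given a table it returns a tidy per-subject DataFrame with the subject
label in the ``id`` column, mirroring the one-row-per-subject output
shape used throughout the CGM literature.

Statistical conventions: sample standard deviations (``ddof=1``),
quantiles by linear interpolation of order statistics (R type 7), MAD
scaled by 1.4826 for normal consistency.  A metric that has no
qualifying observations (e.g. MAGE on a constant series) returns NaN,
never 0 — zero is a valid metric value and must stay distinguishable.
"""

from __future__ import annotations

import logging
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import CGMTable
from .params import MetricParams, as_params

logger = logging.getLogger(__name__)

# glucose at/below 18 mg/dL makes the GRADE double log undefined
_GRADE_FLOOR = 18.0 + 1e-6


def _values(data) -> np.ndarray:
    if isinstance(data, CGMTable):
        arr = data.data["gl"].to_numpy(dtype=float)
    elif isinstance(data, pd.DataFrame):
        arr = data["gl"].to_numpy(dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
    if arr.size == 0:
        raise ValueError("no glucose values supplied")
    return arr


def per_subject(data, fn: Callable[[np.ndarray], dict], params: MetricParams | None = None) -> pd.DataFrame:
    """Apply a values→dict metric per subject of a table."""
    rows = []
    for sid, sub in data.iter_subjects():
        rows.append({"id": sid, **fn(sub["gl"].to_numpy(dtype=float))})
    return pd.DataFrame(rows)


def _dispatch(data, fn: Callable[[np.ndarray], dict]):
    if isinstance(data, CGMTable):
        return per_subject(data, fn)
    return fn(_values(data))


# ---------------------------------------------------------------- summary

def summary_glu(data, params: MetricParams | None = None):
    """Distribution summary: mean, median, SD, CV, IQR, range, MAD, quantiles.

    All values are in mg/dL except ``cv`` which is 100·sd/mean in %.
    With fewer than two values, ``sd`` and ``cv`` are NaN.
    """
    p = as_params(params)

    def one(g: np.ndarray) -> dict:
        sd = float(np.std(g, ddof=1)) if g.size > 1 else float("nan")
        out = {
            "mean": float(np.mean(g)),
            "median": float(np.median(g)),
            "sd": sd,
            "cv": 100.0 * sd / float(np.mean(g)),
            "iqr": float(np.quantile(g, 0.75) - np.quantile(g, 0.25)),
            "range": float(np.max(g) - np.min(g)),
            "mad": p.mad_constant * float(np.median(np.abs(g - np.median(g)))),
        }
        for prob in p.quantile_probs:
            out[f"q{prob:g}"] = float(np.quantile(g, prob / 100.0))
        return out

    return _dispatch(data, one)


def percent_above(data, thresholds: Sequence[float] | None = None, params: MetricParams | None = None):
    """Percent of readings strictly above each threshold (defaults 140/180/250)."""
    p = as_params(params)
    ts = tuple(thresholds) if thresholds is not None else p.targets_above

    def one(g: np.ndarray) -> dict:
        return {f"above_{t:g}": 100.0 * float(np.mean(g > t)) for t in ts}

    return _dispatch(data, one)


def percent_below(data, thresholds: Sequence[float] | None = None, params: MetricParams | None = None):
    """Percent of readings strictly below each threshold (defaults 54/70)."""
    p = as_params(params)
    ts = tuple(thresholds) if thresholds is not None else p.targets_below

    def one(g: np.ndarray) -> dict:
        return {f"below_{t:g}": 100.0 * float(np.mean(g < t)) for t in ts}

    return _dispatch(data, one)


def percent_in_range(data, ranges: Sequence[tuple[float, float]] | None = None,
                     params: MetricParams | None = None):
    """Percent of readings inside each [lo, hi] band, endpoints inclusive."""
    p = as_params(params)
    rs = tuple(ranges) if ranges is not None else p.ranges_in

    def one(g: np.ndarray) -> dict:
        return {
            f"in_range_{lo:g}_{hi:g}": 100.0 * float(np.mean((g >= lo) & (g <= hi)))
            for lo, hi in rs
        }

    return _dispatch(data, one)


# ------------------------------------------------- A1c-scale re-expressions

def ea1c(data):
    """Estimated A1c (%): (mean glucose + 46.7) / 28.7."""
    return _dispatch(data, lambda g: {"ea1c": (float(np.mean(g)) + 46.7) / 28.7})


def gmi(data):
    """Glucose management indicator (%): 3.31 + 0.02392 · mean glucose."""
    return _dispatch(data, lambda g: {"gmi": 3.31 + 0.02392 * float(np.mean(g))})


def j_index(data):
    """J-index: 0.001 · (mean + SD)², combining level and spread."""

    def one(g: np.ndarray) -> dict:
        sd = float(np.std(g, ddof=1)) if g.size > 1 else 0.0
        return {"j_index": 0.001 * (float(np.mean(g)) + sd) ** 2}

    return _dispatch(data, one)


def m_value(data, r: float | None = None, params: MetricParams | None = None):
    """M-value: mean of |10·log10(g/r)|³ with reference r (default 90 mg/dL).

    Penalizes deviations from the reference symmetrically on the log
    scale, cubically in the deviation.
    """
    ref = r if r is not None else as_params(params).mvalue_ref

    def one(g: np.ndarray) -> dict:
        return {"m_value": float(np.mean(np.abs(10.0 * np.log10(g / ref)) ** 3))}

    return _dispatch(data, one)


# ---------------------------------------------------------------- GRADE

def _grade_contributions(g: np.ndarray) -> np.ndarray:
    """Per-reading GRADE score: 425·(log10(log10(g/18)) + 0.16)², capped at 50.

    g must exceed 18 mg/dL for the double log; smaller values are clamped
    just above with a warning (they would cap at 50 anyway).
    """
    if np.any(g <= 18.0):
        warnings.warn(
            "glucose values <= 18 mg/dL clamped for the GRADE double-log transform",
            RuntimeWarning,
            stacklevel=3,
        )
        g = np.maximum(g, _GRADE_FLOOR)
    h = 425.0 * (np.log10(np.log10(g / 18.0)) + 0.16) ** 2
    return np.minimum(h, 50.0)


def grade_family(data, eugly_range: tuple[float, float] | None = None,
                 params: MetricParams | None = None):
    """GRADE score and its eu-/hypo-/hyperglycemia attribution percentages.

    ``grade`` is the mean per-reading contribution; the three percents
    attribute the total contribution to readings inside the euglycemic
    window (default [70, 140] mg/dL), below it, and above it, and sum
    to 100.
    """
    lo, hi = eugly_range if eugly_range is not None else as_params(params).grade_eugly_range

    def one(g: np.ndarray) -> dict:
        h = _grade_contributions(g)
        total = float(np.sum(h))
        if total == 0.0:
            # constant trace at the transform's zero: attribute by count
            eu = 100.0 * float(np.mean((g >= lo) & (g <= hi)))
            return {"grade": 0.0, "grade_eugly": eu,
                    "grade_hypo": 100.0 * float(np.mean(g < lo)),
                    "grade_hyper": 100.0 * float(np.mean(g > hi))}
        return {
            "grade": float(np.mean(h)),
            "grade_eugly": 100.0 * float(np.sum(h[(g >= lo) & (g <= hi)])) / total,
            "grade_hypo": 100.0 * float(np.sum(h[g < lo])) / total,
            "grade_hyper": 100.0 * float(np.sum(h[g > hi])) / total,
        }

    return _dispatch(data, one)


# ------------------------------------------------------- Kovatchev risk

def risk_transform(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Kovatchev symmetrized risk: f(g) = 1.509·((ln g)^1.084 − 5.381).

    Returns ``(f, rl, rh)`` where rl = 10·f² for f < 0 (low risk),
    rh = 10·f² for f > 0 (high risk); rl·rh = 0 per reading and both
    live in [0, 100].
    """
    f = 1.509 * (np.log(g) ** 1.084 - 5.381)
    r = np.minimum(10.0 * f * f, 100.0)  # risk scale saturates at 100
    rl = np.where(f < 0, r, 0.0)
    rh = np.where(f > 0, r, 0.0)
    return f, rl, rh


def bgi(data):
    """Low and high blood glucose indices: means of rl and rh."""

    def one(g: np.ndarray) -> dict:
        _, rl, rh = risk_transform(g)
        return {"lbgi": float(np.mean(rl)), "hbgi": float(np.mean(rh))}

    return _dispatch(data, one)


# -------------------------------------------------- Rodbard index family

def hyper_index(data, ultr: float | None = None, a: float | None = None,
                c: float | None = None, params: MetricParams | None = None):
    """Hyperglycemia index: Σ_{g>ULTR} (g − ULTR)^a / (n·c)."""
    p = as_params(params)
    u = ultr if ultr is not None else p.ultr
    ea = a if a is not None else p.hyper_exponent
    sc = c if c is not None else p.hyper_scale

    def one(g: np.ndarray) -> dict:
        excess = g[g > u] - u
        return {"hyper_index": float(np.sum(excess ** ea)) / (g.size * sc)}

    return _dispatch(data, one)


def hypo_index(data, lltr: float | None = None, b: float | None = None,
               d: float | None = None, params: MetricParams | None = None):
    """Hypoglycemia index: Σ_{g<LLTR} (LLTR − g)^b / (n·d)."""
    p = as_params(params)
    l = lltr if lltr is not None else p.lltr
    eb = b if b is not None else p.hypo_exponent
    sc = d if d is not None else p.hypo_scale

    def one(g: np.ndarray) -> dict:
        deficit = l - g[g < l]
        return {"hypo_index": float(np.sum(deficit ** eb)) / (g.size * sc)}

    return _dispatch(data, one)


def igc(data, params: MetricParams | None = None):
    """Index of glycemic control: hyper_index + hypo_index."""
    p = as_params(params)

    def one(g: np.ndarray) -> dict:
        hi = hyper_index(g, params=p)["hyper_index"]
        ho = hypo_index(g, params=p)["hypo_index"]
        return {"igc": hi + ho}

    return _dispatch(data, one)


# ---------------------------------------------------------------- COGI

def cogi(data):
    """Continuous glucose monitoring index, a 0–100 composite.

    Weighted sum 0.5·w1 + 0.35·w2 + 0.15·w3 of rescaled time in range
    [70, 180] (w1), time below 70 capped at 15% (w2), and SD rescaled
    over [18, 108] mg/dL (w3); 100 is best.
    """

    def one(g: np.ndarray) -> dict:
        tir = 100.0 * float(np.mean((g >= 70.0) & (g <= 180.0)))
        tbr = 100.0 * float(np.mean(g < 70.0))
        sd = float(np.std(g, ddof=1)) if g.size > 1 else 0.0
        w1 = tir
        w2 = 100.0 * (1.0 - min(tbr, 15.0) / 15.0)
        w3 = 100.0 * min(max((108.0 - sd) / 90.0, 0.0), 1.0)
        return {"cogi": 0.5 * w1 + 0.35 * w2 + 0.15 * w3}

    return _dispatch(data, one)


# ---------------------------------------------------------------- MAGE

def mage(data, variant: str = "naive", short_ma: int = 5, long_ma: int = 32):
    """Mean amplitude of glycemic excursions.

    The default ``naive`` rule averages |g − mean| over readings whose
    deviation exceeds one (sample) SD; if no reading qualifies the
    result is NaN.  The ``ma_crossing`` variant instead detects
    excursion turning points from the crossings of a short and a long
    moving average and averages the qualifying peak-to-nadir amplitudes.
    """

    def one(g: np.ndarray) -> dict:
        if variant == "naive":
            if g.size < 3:
                raise ValueError("MAGE needs at least 3 readings")
            mu = float(np.mean(g))
            sd = float(np.std(g, ddof=1))
            dev = np.abs(g - mu)
            qual = dev[dev > sd]
            return {"mage": float(np.mean(qual)) if qual.size else float("nan")}
        if variant == "ma_crossing":
            return {"mage": _mage_ma(g, short_ma, long_ma)}
        raise ValueError(f"unknown MAGE variant: {variant!r}")

    return _dispatch(data, one)


def _mage_ma(g: np.ndarray, short_ma: int, long_ma: int) -> float:
    if g.size < long_ma:
        return float("nan")
    s = pd.Series(g)
    ma_s = s.rolling(short_ma, min_periods=1).mean().to_numpy()
    ma_l = s.rolling(long_ma, min_periods=1).mean().to_numpy()
    diff = ma_s - ma_l
    sign = np.sign(diff)
    crossings = np.flatnonzero(np.diff(sign) != 0)
    if crossings.size < 2:
        return float("nan")
    sd = float(np.std(g, ddof=1))
    # extremum of the raw trace between consecutive crossings
    bounds = np.concatenate(([0], crossings + 1, [g.size]))
    extrema = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = g[a:b]
        if seg.size:
            extrema.append(float(seg.max()) if np.mean(diff[a:b]) > 0 else float(seg.min()))
    amps = np.abs(np.diff(extrema))
    amps = amps[amps > sd]
    return float(np.mean(amps)) if amps.size else float("nan")
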
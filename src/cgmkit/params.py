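"""Tunable constants shared by every metric and plot.

All glucose thresholds are in mg/dL, all durations in minutes unless a
field name says otherwise.  The defaults follow the conventions of the
CGM metrics literature (consensus time-in-range cutoffs 70/180, AGP band
edges 54/70/180/250, Kovatchev risk transform, Rodbard hyper-/hypo-
glycemia indices) and are exposed so that every one of them can be
overridden per call or from the command line.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence


@dataclass(frozen=True)
class MetricParams:
    """Bundle of every tunable constant used by the metric layer.

    Parameters
    ----------
    targets_above
        Thresholds for percent-above (strict ``>``), mg/dL.
    targets_below
        Thresholds for percent-below (strict ``<``), mg/dL.
    ranges_in
        ``(lo, hi)`` pairs for percent-in-range (inclusive both ends).
    ultr, lltr
        Upper / lower limits of the target range used by the
        hyperglycemia and hypoglycemia indices.
    hyper_exponent, hypo_exponent
        Exponents ``a`` and ``b`` of the Rodbard index power transforms.
    hyper_scale, hypo_scale
        Scaling divisors ``c`` and ``d`` of the Rodbard indices.
    mvalue_ref
        Reference glucose ``r`` of the M-value, mg/dL.
    conga_hours
        Lag of the CONGA difference, hours.
    mag_minutes
        Sampling interval of the mean absolute glucose change, minutes.
    roc_timelag
        Lag of the rate-of-change difference, minutes.
    inter_gap
        Largest gap (minutes) across which linear interpolation is
        allowed when building the day-by-day grid; gaps of exactly
        ``inter_gap`` are still interpolated.
    dt0
        Grid period in minutes; ``None`` means infer from the data as
        the rounded median inter-reading interval.
    quantile_probs
        Percentile probabilities reported by the summary operation.
    agp_cutoffs
        Band edges of the ambulatory glucose profile, mg/dL.
    lasagna_midpoint, lasagna_limits
        Color-scale anchors of the lasagna plots, mg/dL.
    grade_eugly_range
        Euglycemia window of the GRADE attribution percentages, mg/dL.
    mad_constant
        Normal-consistency factor of the median absolute deviation.
    """

    targets_above: tuple[float, ...] = (140.0, 180.0, 250.0)
    targets_below: tuple[float, ...] = (54.0, 70.0)
    ranges_in: tuple[tuple[float, float], ...] = ((70.0, 180.0), (63.0, 140.0))
    ultr: float = 140.0
    lltr: float = 80.0
    hyper_exponent: float = 1.1
    hypo_exponent: float = 2.0
    hyper_scale: float = 30.0
    hypo_scale: float = 30.0
    mvalue_ref: float = 90.0
    conga_hours: float = 1.0
    mag_minutes: float = 60.0
    roc_timelag: float = 15.0
    inter_gap: float = 45.0
    dt0: float | None = None
    quantile_probs: tuple[float, ...] = (0.0, 25.0, 50.0, 75.0, 100.0)
    agp_cutoffs: tuple[float, float, float, float] = (54.0, 70.0, 180.0, 250.0)
    lasagna_midpoint: float = 105.0
    lasagna_limits: tuple[float, float] = (50.0, 500.0)
    grade_eugly_range: tuple[float, float] = (70.0, 140.0)
    mad_constant: float = 1.4826

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.targets_above + self.targets_below):
            raise ValueError("thresholds must be positive")
        for lo, hi in self.ranges_in:
            if not lo < hi:
                raise ValueError(f"range ({lo}, {hi}) must satisfy lo < hi")
        if self.inter_gap <= 0:
            raise ValueError("inter_gap must be > 0")
        if self.dt0 is not None and self.dt0 <= 0:
            raise ValueError("dt0 must be > 0 when set")
        lo, hi = self.lasagna_limits
        if not lo < self.lasagna_midpoint < hi:
            raise ValueError("lasagna limits must bracket the midpoint")

    def with_(self, **kwargs) -> "MetricParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


DEFAULT_PARAMS = MetricParams()


def as_params(params: MetricParams | None) -> MetricParams:
    return DEFAULT_PARAMS if params is None else params
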
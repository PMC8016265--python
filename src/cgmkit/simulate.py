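"""Synthetic CGM trace generator.

Emulates the structure of real multi-day sensor data: a per-subject
baseline, a diurnal sinusoid, meal-shaped pulses, AR(1) sensor noise,
per-reading dropout, contiguous gap blocks (sensor off / signal loss),
and small per-subject timestamp jitter so that measurement times are
misaligned across subjects, as they are in practice.  Glucose is
floored at 40 mg/dL to keep the log-based risk transforms in-domain.

The generator is fully deterministic given ``seed``.  It emulates the
marginal and short-range temporal structure of CGM traces but not
physiology: no insulin dynamics, no sensor drift or calibration error,
and meals at random rather than habitual times.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .io import CGMTable, table_from_frame

GLUCOSE_FLOOR = 40.0


def _broadcast(value, n: int, name: str) -> list:
    if np.isscalar(value):
        return [value] * n
    value = list(value)
    if len(value) != n:
        raise ValueError(f"{name} must be scalar or length {n}, got {len(value)}")
    return value


@dataclass
class SimConfig:
    """Parameters of the synthetic CGM generator.

    Per-subject fields (``baseline`` ... ``meal_amplitude``) accept a
    scalar (shared) or a list of length ``n_subjects``.

    Parameters
    ----------
    n_subjects, days, dt0
        Panel shape: subjects, days per subject, sensor period (min;
        must divide 1440).
    baseline
        Mean glucose level, mg/dL.
    diurnal_amplitude, diurnal_peak_hour
        Amplitude (mg/dL) and peak time (hours, 0–24) of the daily
        sinusoid.
    noise_sd, ar_coef
        Stationary SD (mg/dL) and lag-1 coefficient of the AR(1)
        sensor-noise process.
    meals_per_day, meal_amplitude, meal_decay_minutes
        Expected meal count per day (Poisson), peak excursion height
        (mg/dL) and decay time constant of the gamma-shaped pulse.
    dropout_prob
        Independent per-reading dropout probability.
    gap_rate_per_day, gap_length_minutes
        Expected number (Poisson) and length of contiguous missing
        blocks per day.
    jitter_sd_seconds
        SD of the per-subject timestamp offset jitter.
    start, seed
        First timestamp (ISO date or datetime) and RNG seed.
    """

    n_subjects: int = 5
    days: int = 14
    dt0: int = 5
    baseline: float | list = 140.0
    diurnal_amplitude: float | list = 25.0
    diurnal_peak_hour: float | list = 17.0
    noise_sd: float | list = 15.0
    ar_coef: float | list = 0.7
    meals_per_day: float | list = 3.0
    meal_amplitude: float | list = 60.0
    meal_decay_minutes: float = 45.0
    dropout_prob: float = 0.02
    gap_rate_per_day: float = 0.3
    gap_length_minutes: float = 90.0
    jitter_sd_seconds: float = 40.0
    start: str = "2020-03-01 00:00:00"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.days < 1:
            raise ValueError("n_subjects and days must be >= 1")
        if 1440 % self.dt0 != 0:
            raise ValueError(f"dt0 = {self.dt0} must divide 1440")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")
        for coef in _broadcast(self.ar_coef, self.n_subjects, "ar_coef"):
            if not 0.0 <= coef < 1.0:
                raise ValueError("ar_coef must be in [0, 1)")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            payload = json.load(fh)
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**payload)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _ar1(rng: np.random.Generator, n: int, sd: float, coef: float) -> np.ndarray:
    """Stationary AR(1) series with marginal SD ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - coef**2), size=n)
    eps[0] = rng.normal(0.0, sd)  # start at the stationary distribution
    return lfilter([1.0], [1.0, -coef], eps)


def _meal_pulses(rng: np.random.Generator, minutes: np.ndarray, days: int,
                 per_day: float, amplitude: float, decay: float) -> np.ndarray:
    out = np.zeros_like(minutes)
    if per_day <= 0 or amplitude == 0:
        return out
    for day in range(days):
        for _ in range(rng.poisson(per_day)):
            # meals concentrated in waking hours
            t0 = day * 1440.0 + rng.uniform(6.0, 22.0) * 60.0
            amp = amplitude * rng.uniform(0.6, 1.4)
            dt = minutes - t0
            mask = dt >= 0
            # gamma-shaped excursion peaking at `decay` minutes after onset
            out[mask] += amp * (dt[mask] / decay) * np.exp(1.0 - dt[mask] / decay)
    return out


def simulate_cgm(config: SimConfig) -> CGMTable:
    """Generate a multi-subject CGM table from ``config``.

    glucose = baseline + diurnal sinusoid + meal pulses + AR(1) noise,
    floored at 40 mg/dL; timestamps are a regular ``dt0`` grid plus a
    per-subject jitter offset; dropout and gap blocks are applied last.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    baselines = _broadcast(config.baseline, n, "baseline")
    amps = _broadcast(config.diurnal_amplitude, n, "diurnal_amplitude")
    peaks = _broadcast(config.diurnal_peak_hour, n, "diurnal_peak_hour")
    sds = _broadcast(config.noise_sd, n, "noise_sd")
    coefs = _broadcast(config.ar_coef, n, "ar_coef")
    meals = _broadcast(config.meals_per_day, n, "meals_per_day")
    meal_amps = _broadcast(config.meal_amplitude, n, "meal_amplitude")

    n_per_day = 1440 // config.dt0
    n_read = config.days * n_per_day
    start = pd.Timestamp(config.start)
    frames = []
    for i in range(n):
        minutes = np.arange(n_read, dtype=float) * config.dt0
        # constant per-subject offset misaligns clocks across subjects
        offset = rng.normal(0.0, config.jitter_sd_seconds)
        hours = (minutes / 60.0) % 24.0
        diurnal = amps[i] * np.cos(2.0 * np.pi * (hours - peaks[i]) / 24.0)
        g = (
            baselines[i]
            + diurnal
            + _meal_pulses(rng, minutes, config.days, meals[i], meal_amps[i], config.meal_decay_minutes)
            + _ar1(rng, n_read, sds[i], coefs[i])
        )
        g = np.maximum(np.round(g, 1), GLUCOSE_FLOOR)

        keep = rng.random(n_read) >= config.dropout_prob
        for _ in range(rng.poisson(config.gap_rate_per_day * config.days)):
            gap_start = rng.uniform(0.0, minutes[-1])
            keep &= ~((minutes >= gap_start) & (minutes < gap_start + config.gap_length_minutes))
        if not np.any(keep):
            raise ValueError("configuration removed every reading; lower dropout/gap rates")

        times = start + pd.to_timedelta(np.round(minutes * 60.0 + offset), unit="s")
        frames.append(pd.DataFrame({
            "id": f"Subject {i + 1}",
            "time": times[keep],
            "gl": g[keep],
        }))
    return table_from_frame(pd.concat(frames, ignore_index=True))


#: fixed phenotype panel: one hyperglycemic/low-variability subject
#: (Subject 2), one high-variability subject (Subject 5), and three
#: intermediates — mirroring the qualitative contrast between chronic
#: hyperglycemia and glycemic lability.
PHENOTYPE_PANEL = SimConfig(
    n_subjects=5,
    days=14,
    dt0=5,
    baseline=[118.0, 220.0, 135.0, 175.0, 140.0],
    diurnal_amplitude=[18.0, 12.0, 20.0, 22.0, 35.0],
    diurnal_peak_hour=17.0,
    noise_sd=[10.0, 6.0, 12.0, 14.0, 35.0],
    ar_coef=[0.7, 0.7, 0.7, 0.7, 0.6],
    meals_per_day=3.0,
    meal_amplitude=[45.0, 30.0, 50.0, 55.0, 90.0],
    dropout_prob=0.02,
    gap_rate_per_day=0.3,
    jitter_sd_seconds=40.0,
)


def make_phenotype_panel(seed: int = 20210401) -> CGMTable:
    """Five engineered phenotypes for end-to-end testing.

    Subject 2 has a high mean with little variability (worst
    hyperglycemia index), Subject 5 a normal-ish mean with large, fast
    swings (largest SD of rate of change and within-day SD); Subjects
    1, 3, 4 are intermediate.
    """
    cfg = SimConfig(**{**asdict(PHENOTYPE_PANEL), "seed": seed})
    return simulate_cgm(cfg)
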
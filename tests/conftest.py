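import numpy as np
import pandas as pd
import pytest

from cgmkit import CGMTable, DayGrid, table_from_frame
from cgmkit.simulate import SimConfig, make_phenotype_panel, simulate_cgm


def make_table(times, glucose, subject="S1") -> CGMTable:
    """Build a validated single-subject table from times and values."""
    return table_from_frame(pd.DataFrame({
        "id": subject, "time": pd.to_datetime(times), "gl": glucose,
    }))


def regular_table(values, dt0=5, start="2020-01-01 00:00:00", subject="S1") -> CGMTable:
    """Single subject on an exact dt0-minute clock starting at `start`."""
    t0 = pd.Timestamp(start)
    times = [t0 + pd.Timedelta(minutes=dt0 * i) for i in range(len(values))]
    return make_table(times, values, subject)


def grid_of(values_2d, dt0=60) -> DayGrid:
    """DayGrid directly from a days x columns array (NaN = missing)."""
    from datetime import date, timedelta

    arr = np.asarray(values_2d, dtype=float)
    dates = [date(2020, 1, 1) + timedelta(days=i) for i in range(arr.shape[0])]
    assert 1440 % dt0 == 0 and arr.shape[1] == 1440 // dt0
    return DayGrid(arr, dates, dt0)


@pytest.fixture(scope="session")
def phenotype_panel() -> CGMTable:
    return make_phenotype_panel()


@pytest.fixture(scope="session")
def small_panel() -> CGMTable:
    """3 subjects, 4 days at 5 min — fast end-to-end input."""
    return simulate_cgm(SimConfig(n_subjects=3, days=4, seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(autouse=True)
def _close_figures():
    yield
    import matplotlib.pyplot as plt

    plt.close("all")
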
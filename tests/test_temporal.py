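"""Time-dependent metrics: closed forms and brute-force oracle equivalence.

The oracles re-derive each grid metric with explicit Python double loops
over (day, column) indices, independently of the vectorized paths they
check.
"""

import numpy as np
import pandas as pd
import pytest

from cgmkit import (
    MetricParams, adrr, all_metrics, auc, conga, cv_measures, gvp, mag,
    modd, risk_transform, roc, sd_measures, sd_roc, table_from_frame,
)

from conftest import grid_of, make_table, regular_table


def random_grid(rng, missing=0.2):
    """Small random DayGrid: 2-4 days, hourly or half-hourly columns."""
    dt0 = int(rng.choice([30, 60]))
    days = int(rng.integers(2, 5))
    cols = 1440 // dt0
    vals = rng.uniform(60, 300, size=(days, cols))
    vals[rng.random((days, cols)) < missing] = np.nan
    return grid_of(vals, dt0)


def sample_sd(values):
    values = [v for v in values if not np.isnan(v)]
    if len(values) < 2:
        return np.nan
    m = sum(values) / len(values)
    return (sum((v - m) ** 2 for v in values) / (len(values) - 1)) ** 0.5


# ------------------------------------------------------------- CONGA

class TestConga:
    def test_constant_grid_is_zero(self):
        assert conga(grid_of(np.full((2, 24), 120.0)))["conga"] == 0.0

    def test_linear_ramp_has_constant_differences(self):
        vals = np.arange(2 * 24, dtype=float).reshape(2, 24) + 100
        assert conga(grid_of(vals))["conga"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(1000):
            grid = random_grid(rng)
            lag = int(round(1 * 60 / grid.dt0))
            flat = list(grid.gd2d.reshape(-1))
            diffs = [flat[t] - flat[t - lag] for t in range(lag, len(flat))]
            expected = sample_sd(diffs)
            got = conga(grid)["conga"]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-9)


class TestModd:
    def test_identical_days_give_zero(self):
        profile = np.linspace(80, 200, 24)
        assert modd(grid_of(np.tile(profile, (3, 1))))["modd"] == pytest.approx(0.0)

    def test_shifted_day_gives_the_shift(self):
        day = np.linspace(90, 180, 24)
        assert modd(grid_of(np.vstack([day, day + 7.0])))["modd"] == pytest.approx(7.0)

    def test_single_day_rejected(self):
        with pytest.raises(ValueError):
            modd(grid_of(np.full((1, 24), 100.0)))

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(1000):
            grid = random_grid(rng)
            x = grid.gd2d
            diffs = [abs(x[i + 1, j] - x[i, j])
                     for i in range(x.shape[0] - 1) for j in range(x.shape[1])
                     if not (np.isnan(x[i + 1, j]) or np.isnan(x[i, j]))]
            expected = sum(diffs) / len(diffs) if diffs else np.nan
            got = modd(grid)["modd"]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-9)


class TestSdMeasures:
    def test_constant_grid_all_zero(self):
        res = sd_measures(grid_of(np.full((3, 48), 130.0), dt0=30))
        assert all(v == 0.0 for v in res.values())

    def test_hourly_grid_has_undefined_within_hour_sd(self):
        # one cell per 1-hour block -> SdWSH has no usable block
        res = sd_measures(grid_of(np.full((3, 24), 130.0), dt0=60))
        assert np.isnan(res["SdWSH"])

    def test_constant_days_at_different_levels(self):
        levels = np.array([100.0, 140.0, 190.0])
        res = sd_measures(grid_of(np.tile(levels[:, None], (1, 24))))
        assert res["SdW"] == 0.0 and res["SdHHMM"] == pytest.approx(0.0, abs=1e-12)
        assert res["SdDM"] == pytest.approx(np.std(levels, ddof=1))
        assert res["SdB"] == pytest.approx(np.std(levels, ddof=1))
        assert res["SdBDM"] == pytest.approx(0.0, abs=1e-12)

    def test_identical_nonconstant_profile_each_day(self):
        v = np.linspace(90, 210, 24)
        res = sd_measures(grid_of(np.tile(v, (4, 1))))
        assert res["SdW"] == pytest.approx(np.std(v, ddof=1))
        assert res["SdHHMM"] == pytest.approx(np.std(v, ddof=1))
        for key in ("SdDM", "SdB", "SdBDM"):
            assert res[key] == pytest.approx(0.0, abs=1e-9)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(300):
            grid = random_grid(rng)
            x = grid.gd2d
            days, cols = x.shape
            sdw = [sample_sd(x[i]) for i in range(days)]
            col_means = [np.nanmean(x[:, j]) if np.any(~np.isnan(x[:, j])) else np.nan
                         for j in range(cols)]
            hour_cells = max(int(round(60 / grid.dt0)), 1)
            blocks = [sample_sd(x[i, s:s + hour_cells])
                      for i in range(days) for s in range(0, cols, hour_cells)]
            day_means = [np.nanmean(x[i]) if np.any(~np.isnan(x[i])) else np.nan
                         for i in range(days)]
            sdb = [sample_sd(x[:, j]) for j in range(cols)]
            centered = x - np.array(day_means)[:, None]
            sdbdm = [sample_sd(centered[:, j]) for j in range(cols)]
            exp_wsh = np.nan if np.all(np.isnan(blocks)) else np.nanmean(blocks)
            expected = {
                "SdW": np.nanmean(sdw), "SdHHMM": sample_sd(col_means),
                "SdWSH": exp_wsh, "SdDM": sample_sd(day_means),
                "SdB": np.nanmean(sdb), "SdBDM": np.nanmean(sdbdm),
            }
            got = sd_measures(grid)
            for key, exp in expected.items():
                if np.isnan(exp):
                    assert np.isnan(got[key]), key
                else:
                    assert got[key] == pytest.approx(exp, abs=1e-9), key


class TestCvMeasures:
    def test_constant_days(self):
        res = cv_measures(grid_of(np.full((3, 24), 150.0)))
        assert res["CVmean"] == 0.0 and res["CVsd"] == 0.0

    def test_two_days_with_known_cvs(self):
        # day CVs of exactly 10% and 20% via scaled copies of one profile
        base = np.array([90.0, 100.0, 110.0] * 8)
        cv_base = 100 * np.std(base, ddof=1) / np.mean(base)
        d1 = 100 + (base - 100) * (10 / cv_base)
        d2 = 100 + (base - 100) * (20 / cv_base)
        res = cv_measures(grid_of(np.vstack([d1, d2])))
        assert res["CVmean"] == pytest.approx(15.0, abs=1e-9)
        assert res["CVsd"] == pytest.approx(np.std([10, 20], ddof=1), abs=1e-9)

    def test_matches_oracle(self, rng):
        for _ in range(1000):
            grid = random_grid(rng)
            cvs = []
            for row in grid.gd2d:
                vals = [v for v in row if not np.isnan(v)]
                if len(vals) > 1:
                    cvs.append(100 * sample_sd(vals) / (sum(vals) / len(vals)))
            exp_mean = np.mean(cvs) if cvs else np.nan
            exp_sd = sample_sd(cvs)
            got = cv_measures(grid)
            assert (np.isnan(exp_mean) and np.isnan(got["CVmean"])) or \
                got["CVmean"] == pytest.approx(exp_mean, abs=1e-9)
            assert (np.isnan(exp_sd) and np.isnan(got["CVsd"])) or \
                got["CVsd"] == pytest.approx(exp_sd, abs=1e-9)


class TestAdrr:
    def test_risk_free_trace_is_zero(self):
        table = regular_table(np.full(288, 112.5), dt0=5)
        assert adrr(table)["adrr"] == pytest.approx(0.0, abs=1e-3)

    def test_single_hypoglycemic_day(self):
        table = regular_table(np.full(100, 50.0), dt0=5)
        assert adrr(table)["adrr"] == pytest.approx(22.500, abs=1e-2)

    def test_matches_per_day_brute_force(self, rng):
        for _ in range(1000):
            n = int(rng.integers(10, 80))
            start = pd.Timestamp("2021-05-01") + pd.Timedelta(minutes=int(rng.integers(0, 1440)))
            times = start + pd.to_timedelta(np.cumsum(rng.integers(5, 120, n)), unit="m")
            g = rng.uniform(45, 350, n)
            table = make_table(times, g)
            sub = table.data
            totals = []
            for _, day in sub.groupby(sub["time"].dt.date):
                _, rl, rh = risk_transform(day["gl"].to_numpy())
                totals.append(max(rl) + max(rh))
            assert adrr(table)["adrr"] == pytest.approx(np.mean(totals), abs=1e-9)

    def test_nonnegative(self, small_panel):
        assert (adrr(small_panel)["adrr"] >= 0).all()


class TestGvp:
    def test_constant_glucose_is_zero(self):
        assert gvp(regular_table(np.full(50, 140.0), dt0=5))["gvp"] == pytest.approx(0.0)

    def test_single_segment_closed_form(self):
        table = make_table(["2020-01-01 00:00:00", "2020-01-01 00:05:00"], [100.0, 105.0])
        assert gvp(table)["gvp"] == pytest.approx(100 * (np.sqrt(50) / 5 - 1), rel=1e-9)

    def test_segments_across_large_gaps_excluded(self):
        times = ["2020-01-01 00:00:00", "2020-01-01 00:05:00",
                 "2020-01-01 02:00:00", "2020-01-01 02:05:00"]
        table = make_table(times, [100.0, 105.0, 300.0, 305.0])
        # both retained segments have the same (dt, dg)
        assert gvp(table)["gvp"] == pytest.approx(100 * (np.sqrt(50) / 5 - 1), rel=1e-9)

    def test_nonnegative(self, small_panel):
        assert (gvp(small_panel)["gvp"] >= 0).all()


class TestMag:
    def test_constant_is_zero(self):
        assert mag(grid_of(np.full((2, 24), 100.0)))["mag"] == 0.0

    def test_ramp_of_one_mgdl_per_minute(self):
        vals = (np.arange(2 * 288, dtype=float) * 5).reshape(2, 288) + 100
        assert mag(grid_of(vals, dt0=5))["mag"] == pytest.approx(60.0, rel=1e-9)

    def test_sampling_interval_irrelevant_on_monotone_data(self):
        vals = (np.arange(2 * 288, dtype=float) * 2).reshape(2, 288) + 100
        g = grid_of(vals, dt0=5)
        assert mag(g, n_minutes=60)["mag"] == pytest.approx(mag(g, n_minutes=30)["mag"], rel=1e-9)


class TestAuc:
    def test_constant_day_averages_to_itself(self):
        assert auc(grid_of(np.full((2, 24), 100.0)))["auc"] == pytest.approx(100.0)

    def test_linear_day_averages_to_midpoint(self):
        day = np.linspace(100, 200, 288)
        assert auc(grid_of(day[None, :], dt0=5))["auc"] == pytest.approx(150.0, rel=1e-3)

    def test_between_min_and_max(self, rng):
        for _ in range(50):
            grid = random_grid(rng)
            val = auc(grid)["auc"]
            if not np.isnan(val):
                assert np.nanmin(grid.gd2d) - 1e-9 <= val <= np.nanmax(grid.gd2d) + 1e-9


class TestRoc:
    def test_constant_grid(self):
        grid = grid_of(np.full((2, 288), 100.0), dt0=5)
        rates = roc(grid)
        assert np.nanmax(np.abs(rates)) == 0.0
        assert sd_roc(grid)["sd_roc"] == 0.0

    def test_ramp_has_constant_rate(self):
        vals = (np.arange(2 * 288, dtype=float) * 5).reshape(2, 288)
        grid = grid_of(vals + 100, dt0=5)
        rates = roc(grid, timelag=15)
        np.testing.assert_allclose(rates, 1.0, rtol=1e-9)
        assert sd_roc(grid)["sd_roc"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_cells_deleted_pairwise(self):
        vals = np.full((2, 288), 120.0)
        vals[0, 100:110] = np.nan
        grid = grid_of(vals, dt0=5)
        rates = roc(grid)
        assert np.isnan(rates).any()
        assert sd_roc(grid)["sd_roc"] == 0.0


class TestTimeInvariance:
    def test_shift_by_24h_changes_nothing(self, small_panel):
        shifted = small_panel.data.copy()
        shifted["time"] = shifted["time"] + pd.Timedelta(hours=24)
        m1 = all_metrics(small_panel)
        m2 = all_metrics(table_from_frame(shifted))
        pd.testing.assert_frame_equal(m1, m2)


class TestAllMetrics:
    def test_shape_and_column_census(self, phenotype_panel):
        res = all_metrics(phenotype_panel)
        assert len(res) == 5
        assert res.columns[0] == "id"
        assert res.shape[1] - 1 >= 30

    def test_deterministic(self, small_panel):
        a = all_metrics(small_panel)
        b = all_metrics(small_panel)
        pd.testing.assert_frame_equal(a, b)

    def test_dropping_a_subject_drops_one_row(self, small_panel):
        full = all_metrics(small_panel)
        keep = small_panel.subject_ids[:-1]
        reduced = all_metrics(small_panel.select(keep))
        pd.testing.assert_frame_equal(reduced, full.iloc[:-1].reset_index(drop=True))

    def test_gridfree_and_grid_gvp_agree_on_gapless_data(self):
        vals = 130 + 40 * np.sin(np.arange(2 * 288) / 25.0)
        table = regular_table(vals, dt0=5, start="2020-01-01 00:05:00")
        from cgmkit import day_by_day
        grid = day_by_day(table)
        flat = grid.flatten()
        ok = ~np.isnan(flat)
        idx = np.flatnonzero(ok)
        dt = np.diff(idx) * 5.0
        dg = np.diff(flat[idx])
        expected = 100 * (np.sum(np.sqrt(dt**2 + dg**2)) / np.sum(dt) - 1)
        assert gvp(table)["gvp"] == pytest.approx(expected, rel=1e-6)
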
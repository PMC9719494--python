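import numpy as np
import pandas as pd
import pytest

from poleward.extremes import (
    ExtremeEvent,
    build_climatology,
    detect_mcs_runs,
    detect_mhw_months,
    mcs_cumulative_intensity,
    median_edge_displacement,
    thermal_displacement,
)
from poleward.grid_io import KM_PER_DEG
from tests.conftest import daily_series, monthly_series


def flat_daily(value, n_years=4, shape=(2, 2), start="2000-01-01"):
    times = pd.date_range(start, periods=365 * n_years + 50, freq="D")
    vals = np.full((times.size,) + shape, float(value))
    return daily_series(vals, np.arange(shape[0], dtype=float), np.arange(shape[1], dtype=float), start=start)


class TestClimatology:
    def test_constant_input(self):
        series = flat_daily(15.0)
        clim = build_climatology(series, (2000, 2003))
        np.testing.assert_allclose(clim.daily_mean, 15.0, atol=1e-12)
        np.testing.assert_allclose(clim.daily_q10, 15.0, atol=1e-12)
        np.testing.assert_allclose(clim.monthly_mean, 15.0, atol=1e-12)

    def test_pure_sinusoid(self):
        times = pd.date_range("2000-01-01", periods=365 * 4 + 1, freq="D")
        doy = np.asarray(times.dayofyear)
        cyc = 15.0 + 2.0 * np.cos(2 * np.pi * (doy - 15) / 365.25)
        vals = np.tile(cyc[:, None, None], (1, 2, 2))
        series = daily_series(vals, np.arange(2.0), np.arange(2.0))
        clim = build_climatology(series, (2000, 2003))
        d = np.arange(365)
        expect = 15.0 + 2.0 * np.cos(2 * np.pi * (d + 1 - 15) / 365.25)
        # 11-day pooling + 31-day smoothing flattens the curve slightly
        assert np.max(np.abs(clim.daily_mean[:, 0, 0] - expect)) < 0.05
        assert np.max(np.abs(clim.daily_q10[:, 0, 0] - clim.daily_mean[:, 0, 0])) < 0.25

    def test_gaussian_q10_matches_normal_quantile(self):
        rng = np.random.default_rng(42)
        times = pd.date_range("1982-01-01", "2011-12-31", freq="D")
        vals = 15.0 + rng.normal(0, 1.0, (times.size, 1, 1))
        series = daily_series(vals, [0.0], [0.0], start="1982-01-01")
        clim = build_climatology(series, (1982, 2011))
        # Phi^-1(0.1) = -1.2816
        assert np.mean(clim.daily_q10[:, 0, 0]) == pytest.approx(15.0 - 1.2816, abs=0.1)
        assert np.mean(clim.daily_mean[:, 0, 0]) == pytest.approx(15.0, abs=0.05)

    def test_baseline_not_covered(self):
        series = flat_daily(10.0, n_years=2)
        with pytest.raises(ValueError, match="baseline"):
            build_climatology(series, (1999, 2005))


class TestDetectMhw:
    def build_monthly(self, anomaly_fn, n_years=10):
        times = pd.date_range("2000-01-01", periods=12 * n_years, freq="MS") + pd.Timedelta(days=14)
        months = np.asarray(times.month)
        base = 14.0 + 2.0 * np.cos(2 * np.pi * (months - 1) / 12.0)
        vals = np.tile(base[:, None, None], (1, 2, 2))
        vals = vals + anomaly_fn(np.arange(times.size))[:, None, None]
        series = monthly_series(vals, np.arange(2.0), np.arange(2.0), start="2000-01")
        clim_monthly = np.stack(
            [np.full((2, 2), 14.0 + 2.0 * np.cos(2 * np.pi * (m) / 12.0)) for m in range(12)]
        )
        from poleward.extremes import Climatology

        clim = Climatology(
            baseline=(2000, 2009),
            daily_mean=np.zeros((365, 2, 2)),
            daily_q10=np.zeros((365, 2, 2)),
            monthly_mean=clim_monthly,
        )
        return series, clim

    def test_series_equal_to_climatology_no_events(self):
        series, clim = self.build_monthly(lambda t: np.zeros(t.size))
        events = detect_mhw_months(series, clim, (2000, 2009))
        assert events == []

    def test_single_spike_flagged(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 0.1, 120)
        noise[37] += 3.0  # one hot month
        series, clim = self.build_monthly(lambda t: noise)
        events = detect_mhw_months(series, clim, (2000, 2009))
        # brute-force threshold scan at the spiked cell-month
        assert any(ev.start == (2003, 2) for ev in events)
        spike_events = [ev for ev in events if ev.start == (2003, 2)]
        assert len(spike_events) == 4  # all four cells share the series
        for ev in spike_events:
            assert ev.mean_intensity > 2.0

    def test_pure_trend_no_events(self):
        series, clim = self.build_monthly(lambda t: 0.01 * t)
        events = detect_mhw_months(series, clim, (2000, 2009))
        assert events == []

    def test_short_period_rejected(self):
        series, clim = self.build_monthly(lambda t: np.zeros(t.size))
        with pytest.raises(ValueError, match="2 years"):
            detect_mhw_months(series, clim, (2000, 2000))

    def test_exceedance_is_strict_and_seasonal(self):
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 0.5, 120)
        series, clim = self.build_monthly(lambda t: noise)
        events = detect_mhw_months(series, clim, (2000, 2009))
        q90 = clim.monthly_q90
        for ev in events:
            m = ev.start[1] - 1
            assert ev.mean_intensity > q90[m][ev.cell]


class TestThermalDisplacement:
    def make_gradient_month(self, anomaly, n=41):
        """1-D meridional gradient 0.01 degC/km; focal cell in the middle."""
        lat = np.linspace(-40.0, -40.0 + (n - 1) * 0.25, n)
        lon = np.array([150.0])
        north_km = (lat - lat[0]) * KM_PER_DEG
        base = 12.0 + 0.01 * north_km
        vals = np.tile(base[None, :, None], (2, 1, 1)).copy()
        focal = n // 2
        vals[1] += anomaly  # whole field warmed during the event month
        series = monthly_series(vals, lat, lon, start="2005-01")
        event = ExtremeEvent(
            kind="MHW_month", cell=(focal, 0), start=(2005, 2), end=(2005, 2),
            duration=1, mean_intensity=anomaly,
        )
        return event, series

    def test_zero_anomaly_zero_displacement(self):
        event, series = self.make_gradient_month(0.0)
        assert thermal_displacement(event, series, None) == 0.0

    def test_analytic_100km_poleward(self):
        event, series = self.make_gradient_month(1.0)
        d = thermal_displacement(event, series, None)
        cell_km = 0.25 * KM_PER_DEG  # ~27.8 km
        assert abs(d - 100.0) <= cell_km + 1e-6

    def test_no_cooler_cell_undefined(self):
        lat = np.array([-40.0, -39.75])
        lon = np.array([150.0])
        vals = np.full((1, 2, 1), 15.0)
        series = monthly_series(vals, lat, lon, start="2005-01")
        event = ExtremeEvent(
            kind="MHW_month", cell=(0, 0), start=(2005, 1), end=(2005, 1),
            duration=1, mean_intensity=2.0,
        )
        assert np.isnan(thermal_displacement(event, series, None))


class TestMedianEdgeDisplacement:
    def ev(self, cell, year, disp):
        return ExtremeEvent(
            kind="MHW_month", cell=cell, start=(year, 6), end=(year, 6),
            duration=1, mean_intensity=1.0, displacement_km=disp,
        )

    def test_no_events_is_zero(self):
        assert median_edge_displacement([], [(0, 0)], (2000, 2009)) == 0.0

    def test_median_of_three(self):
        events = [self.ev((0, 0), 2001, 10.0), self.ev((0, 0), 2002, 20.0), self.ev((0, 0), 2003, 400.0)]
        assert median_edge_displacement(events, [(0, 0)], (2000, 2009)) == 20.0

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        cells = [(0, 0), (0, 1), (2, 2)]
        events = []
        expected_pool = []
        for k in range(40):
            cell = cells[k % 3] if k % 4 else (9, 9)  # some events off-edge
            year = 1995 + (k % 20)
            disp = float(rng.gamma(2.0, 50.0))
            events.append(self.ev(cell, year, disp))
            if cell in cells[:2] and 2000 <= year <= 2009:
                expected_pool.append(disp)
        got = median_edge_displacement(events, cells[:2], (2000, 2009))
        assert got == pytest.approx(np.median(expected_pool))


def mcs_oracle(series, clim, period):
    """Exhaustive day-by-day scan, independent of the run-length implementation."""
    sub = series.slice_years(*period)
    times = pd.DatetimeIndex(sub.time_index)
    from poleward.extremes import _day_index_365

    idx = _day_index_365(times)
    out = []
    nt = sub.values.shape[0]
    for i in range(sub.values.shape[1]):
        for j in range(sub.values.shape[2]):
            run = []
            for t in range(nt + 1):
                cold = (
                    t < nt
                    and not np.isnan(sub.values[t, i, j])
                    and sub.values[t, i, j] < clim.daily_q10[idx[t], i, j]
                )
                if cold:
                    run.append(t)
                else:
                    if len(run) >= 5:
                        anoms = [sub.values[k, i, j] - clim.daily_mean[idx[k], i, j] for k in run]
                        out.append(
                            {
                                "cell": (i, j),
                                "start": times[run[0]],
                                "end": times[run[-1]],
                                "duration": len(run),
                                "mean_intensity": float(np.mean(anoms)),
                            }
                        )
                    run = []
    return out


class TestDetectMcs:
    def test_at_climatology_no_events(self):
        series = flat_daily(15.0)
        clim = build_climatology(series, (2000, 2003))
        assert detect_mcs_runs(series, clim, (2000, 2003)) == []

    def test_six_cold_days_single_event(self):
        series = flat_daily(15.0, n_years=4, shape=(1, 1))
        vals = series.values.copy()
        vals[100:106] -= 2.0
        cold = daily_series(vals, series.lat, series.lon)
        clim = build_climatology(flat_daily(15.0, n_years=4, shape=(1, 1)), (2000, 2003))
        events = detect_mcs_runs(cold, clim, (2000, 2003))
        assert len(events) == 1
        assert events[0].duration == 6
        assert events[0].mean_intensity == pytest.approx(-2.0)
        assert events[0].cumulative_intensity == pytest.approx(12.0)

    def test_gap_breaks_run(self):
        series = flat_daily(15.0, n_years=4, shape=(1, 1))
        vals = series.values.copy()
        vals[100:104] -= 2.0  # 4 cold
        vals[105:109] -= 2.0  # 1 warm gap, then 4 cold
        cold = daily_series(vals, series.lat, series.lon)
        clim = build_climatology(flat_daily(15.0, n_years=4, shape=(1, 1)), (2000, 2003))
        assert detect_mcs_runs(cold, clim, (2000, 2003)) == []

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        times = pd.date_range("2000-01-01", "2009-12-31", freq="D")
        vals = 15.0 + rng.normal(0, 1.0, (times.size, 1, 5))
        # sprinkle genuine cold episodes
        for k in range(25):
            t0 = rng.integers(0, times.size - 12)
            j = rng.integers(0, 5)
            vals[t0 : t0 + rng.integers(3, 12), 0, j] -= rng.uniform(1.5, 3.5)
        series = daily_series(vals, [0.0], np.arange(5.0))
        clim = build_climatology(series, (2000, 2009))
        events = detect_mcs_runs(series, clim, (2000, 2009))
        oracle = mcs_oracle(series, clim, (2000, 2009))
        assert len(events) == len(oracle)
        got = sorted(((e.cell, str(e.start), str(e.end), e.duration) for e in events))
        want = sorted(((o["cell"], str(o["start"]), str(o["end"]), o["duration"]) for o in oracle))
        assert got == want
        by_key = {(o["cell"], str(o["start"])): o["mean_intensity"] for o in oracle}
        for e in events:
            assert e.mean_intensity == pytest.approx(by_key[(e.cell, str(e.start))], abs=1e-9)


class TestCumulativeIntensity:
    def run_ev(self, cell, year, mean_int, dur):
        start = pd.Timestamp(f"{year}-06-01")
        return ExtremeEvent(
            kind="MCS_run", cell=cell, start=start, end=start + pd.Timedelta(days=dur - 1),
            duration=dur, mean_intensity=mean_int, cumulative_intensity=abs(mean_int) * dur,
        )

    def test_no_events(self):
        assert mcs_cumulative_intensity([]) == 0.0

    def test_single_event(self):
        assert mcs_cumulative_intensity([self.run_ev((0, 0), 2005, -2.0, 6)]) == pytest.approx(12.0)

    def test_bruteforce_sum(self):
        rng = np.random.default_rng(3)
        events = [
            self.run_ev((int(rng.integers(3)), 0), 2000 + int(rng.integers(10)),
                        -float(rng.uniform(0.5, 3)), int(rng.integers(5, 15)))
            for _ in range(30)
        ]
        cells = [(0, 0), (1, 0)]
        window = (2003, 2007)
        expect = sum(
            abs(e.mean_intensity) * e.duration
            for e in events
            if e.cell in cells and window[0] <= e.start.year <= window[1]
        )
        assert mcs_cumulative_intensity(events, cells, window) == pytest.approx(expect)

    def test_additive_over_disjoint_windows(self):
        rng = np.random.default_rng(4)
        events = [
            self.run_ev((0, 0), 2000 + int(rng.integers(10)), -1.0, int(rng.integers(5, 10)))
            for _ in range(20)
        ]
        total = mcs_cumulative_intensity(events, None, (2000, 2009))
        a = mcs_cumulative_intensity(events, None, (2000, 2004))
        b = mcs_cumulative_intensity(events, None, (2005, 2009))
        assert total == pytest.approx(a + b)


class TestTranslationInvariance:
    def test_shifted_series_same_detections(self):
        rng = np.random.default_rng(5)
        times = pd.date_range("2000-01-01", "2005-12-31", freq="D")
        vals = 15.0 + rng.normal(0, 1.0, (times.size, 1, 2))
        vals[500:510] -= 3.0
        s1 = daily_series(vals, [0.0], np.arange(2.0))
        s2 = daily_series(vals + 4.0, [0.0], np.arange(2.0))
        c1 = build_climatology(s1, (2000, 2005))
        c2 = build_climatology(s2, (2000, 2005))
        e1 = detect_mcs_runs(s1, c1, (2000, 2005))
        e2 = detect_mcs_runs(s2, c2, (2000, 2005))
        assert [(e.cell, str(e.start), e.duration) for e in e1] == [
            (e.cell, str(e.start), e.duration) for e in e2
        ]
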
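"""Marine heatwave (monthly) and cold-spell (daily) detection and metrics.

Heatwave months are months whose linearly detrended SST anomaly (relative
to a baseline monthly climatology) exceeds the seasonally adjusted 90th
percentile of the detrended anomaly distribution for that calendar month.
Each heatwave month carries a thermal displacement: the distance to the
geographically closest cell whose temperature that month is at or below
the focal cell's baseline temperature (observed minus anomaly).

Cold spells are runs of >= 5 consecutive days with SST below a seasonally
varying 10th-percentile threshold; their cumulative intensity is
|mean anomaly| x duration in degC day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from poleward.grid_io import GridField, GridSeries, haversine_km

MCS_MIN_DURATION = 5
#: half-width (days) of the window pooling calendar days across baseline years
CLIM_WINDOW_HALF = 5
#: length (days) of the moving average smoothing the daily climatology
CLIM_SMOOTH = 31


@dataclass
class Climatology:
    """Baseline climatology: daily mean/10th-percentile, monthly mean.

    Daily statistics are pooled over an 11-day centered calendar window
    across baseline years and smoothed with a 31-day circular moving
    average.  A 365-day calendar is used; Feb 29 observations pool into
    the Feb 28 bin and Feb 29 lookups interpolate the two adjacent bins.
    ``monthly_q90`` (threshold of detrended monthly anomalies) is filled in
    by :func:`detect_mhw_months` since it depends on the analysis period.
    """

    baseline: tuple[int, int]
    daily_mean: np.ndarray  # (365, lat, lon)
    daily_q10: np.ndarray  # (365, lat, lon)
    monthly_mean: np.ndarray  # (12, lat, lon)
    monthly_q90: np.ndarray | None = None  # (12, lat, lon), detrended-anomaly scale


@dataclass
class ExtremeEvent:
    """One detected heatwave month or cold-spell run at one cell."""

    kind: str  # "MHW_month" | "MCS_run"
    cell: tuple[int, int]
    start: object  # (year, month) for MHW, Timestamp for MCS
    end: object
    duration: int  # days (MCS) or 1 (MHW months)
    mean_intensity: float  # degC anomaly vs climatological mean (negative for MCS)
    cumulative_intensity: float = 0.0  # degC day, >= 0
    displacement_km: float | None = None  # MHW only

    @property
    def year(self) -> int:
        if self.kind == "MHW_month":
            return int(self.start[0])
        return int(pd.Timestamp(self.start).year)


def _day_index_365(times: pd.DatetimeIndex) -> np.ndarray:
    """Map dates to a 0..364 index on a fixed 365-day calendar.

    In leap years days after Feb 29 shift back one; Feb 29 itself maps to
    the Feb 28 bin (58).
    """
    doy = np.asarray(times.dayofyear)
    leap = np.asarray(times.is_leap_year)
    idx = doy - 1
    after = leap & (doy >= 60)
    idx = np.where(after, idx - 1, idx)
    return idx.astype(int)


# first day-of-365 index of each calendar month
_MONTH_STARTS = np.cumsum([0, 31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30])


def build_climatology(
    sst_daily: GridSeries,
    baseline: tuple[int, int] = (1982, 2011),
    window_half_days: int = CLIM_WINDOW_HALF,
    smooth_days: int = CLIM_SMOOTH,
) -> Climatology:
    """Per-cell daily mean and 10th-percentile climatology over the baseline.

    Statistics for calendar day d pool all observations within
    ``window_half_days`` of d (circularly) across all baseline years, then
    both curves are smoothed with a ``smooth_days`` circular moving average.
    Monthly means aggregate the smoothed daily means.
    """
    start, end = baseline
    sub = sst_daily.slice_years(start, end)
    if sub.values.shape[0] == 0 or sub.years.min() > start or sub.years.max() < end:
        raise ValueError(f"daily series does not cover baseline {baseline}")
    times = pd.DatetimeIndex(sub.time_index)
    idx365 = _day_index_365(times)
    nlat, nlon = sub.values.shape[1:]
    flat = sub.values.reshape(sub.values.shape[0], -1)

    groups = [np.flatnonzero(idx365 == d) for d in range(365)]
    daily_mean = np.empty((365, nlat * nlon))
    daily_q10 = np.empty((365, nlat * nlon))
    for d in range(365):
        members = np.concatenate(
            [groups[(d + off) % 365] for off in range(-window_half_days, window_half_days + 1)]
        )
        pool = flat[members]
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN land columns
            daily_mean[d] = np.nanmean(pool, axis=0)
            daily_q10[d] = np.nanpercentile(pool, 10.0, axis=0)

    if smooth_days > 1:
        daily_mean = uniform_filter1d(daily_mean, smooth_days, axis=0, mode="wrap")
        daily_q10 = uniform_filter1d(daily_q10, smooth_days, axis=0, mode="wrap")

    daily_mean = daily_mean.reshape(365, nlat, nlon)
    daily_q10 = daily_q10.reshape(365, nlat, nlon)

    monthly_mean = np.stack(
        [
            daily_mean[_MONTH_STARTS[m] : (_MONTH_STARTS[m + 1] if m < 11 else 365)].mean(axis=0)
            for m in range(12)
        ]
    )
    return Climatology(baseline=baseline, daily_mean=daily_mean, daily_q10=daily_q10, monthly_mean=monthly_mean)


def _cell_mask(series: GridSeries, cells) -> np.ndarray:
    """Boolean (lat, lon) mask of cells under consideration."""
    if cells is None:
        return ~series.landmask
    mask = np.zeros_like(series.landmask, dtype=bool)
    for i, j in cells:
        mask[i, j] = True
    return mask & ~series.landmask


def detect_mhw_months(
    sst_monthly: GridSeries,
    clim: Climatology,
    period: tuple[int, int],
    cells=None,
) -> list[ExtremeEvent]:
    """Flag heatwave months: detrended anomaly above the monthly 90th percentile.

    Anomalies are monthly SST minus the baseline monthly climatology,
    linearly detrended per cell over the period; the threshold is the
    empirical 90th percentile of those detrended anomalies per calendar
    month.  The per-cell monthly thresholds are stored on ``clim``.
    ``cells`` optionally restricts the returned events (thresholds are
    always computed on the full grid).
    """
    start, end = period
    if end - start + 1 < 2:
        raise ValueError("period must span at least 2 years for detrending")
    sub = sst_monthly.slice_years(start, end)
    times = pd.DatetimeIndex(sub.time_index)
    months = times.month.to_numpy()
    anom = sub.values - clim.monthly_mean[months - 1]

    # per-cell linear detrend over the period
    t = np.arange(anom.shape[0], dtype=float)
    valid = ~np.isnan(anom)
    n = valid.sum(axis=0)
    a0 = np.where(valid, anom, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tbar = (t[:, None, None] * valid).sum(axis=0) / n
        abar = a0.sum(axis=0) / n
        tc = t[:, None, None] - tbar
        den = (tc**2 * valid).sum(axis=0)
        slope = np.where(den > 0, (tc * (a0 - abar) * valid).sum(axis=0) / den, 0.0)
        detr = anom - (abar + slope * tc)

    q90 = np.full((12,) + anom.shape[1:], np.nan)
    for m in range(12):
        sel = months == m + 1
        if sel.any():
            with np.errstate(invalid="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                q90[m] = np.nanpercentile(detr[sel], 90.0, axis=0)
    clim.monthly_q90 = q90

    consider = _cell_mask(sub, cells)
    # strict exceedance with an absolute guard against detrending round-off
    with np.errstate(invalid="ignore"):
        hot = detr > q90[months - 1] + 1e-9
    hot &= consider[None, :, :]
    events: list[ExtremeEvent] = []
    tt, ii, jj = np.nonzero(hot)
    for k in range(tt.size):
        t_i, i, j = int(tt[k]), int(ii[k]), int(jj[k])
        ym = (int(times[t_i].year), int(times[t_i].month))
        events.append(
            ExtremeEvent(
                kind="MHW_month",
                cell=(i, j),
                start=ym,
                end=ym,
                duration=1,
                mean_intensity=float(detr[t_i, i, j]),
            )
        )
    return events


def thermal_displacement(
    event: ExtremeEvent,
    sst_monthly: GridSeries,
    clim: Climatology,
    landmask: np.ndarray | None = None,
) -> float:
    """Distance (km) to the nearest cell at or below the baseline temperature.

    The baseline temperature is the observed SST at the focal cell minus its
    anomaly; the search covers every ocean cell in the same month.  Returns
    0 when the focal cell itself qualifies (anomaly <= 0) and NaN when no
    cell in the domain does.
    """
    if event.kind != "MHW_month":
        raise ValueError("thermal displacement is defined for MHW months only")
    if landmask is None:
        landmask = sst_monthly.landmask
    year, month = event.start
    years = sst_monthly.years
    months = pd.DatetimeIndex(sst_monthly.time_index).month.to_numpy()
    sel = np.flatnonzero((years == year) & (months == month))
    if sel.size != 1:
        raise ValueError(f"month {year}-{month} not found in monthly series")
    sst = sst_monthly.values[sel[0]]
    i, j = event.cell
    if event.mean_intensity <= 0:
        return 0.0
    baseline_temp = sst[i, j] - event.mean_intensity
    with np.errstate(invalid="ignore"):
        qualifies = (sst <= baseline_temp) & ~landmask
    if qualifies[i, j]:
        return 0.0
    qi, qj = np.nonzero(qualifies)
    if qi.size == 0:
        return float("nan")
    d = haversine_km(sst_monthly.lat[i], sst_monthly.lon[j], sst_monthly.lat[qi], sst_monthly.lon[qj])
    return float(np.min(d))


def fill_displacements(
    events: list[ExtremeEvent], sst_monthly: GridSeries, clim: Climatology
) -> list[ExtremeEvent]:
    """Compute ``displacement_km`` in place for every MHW event."""
    for ev in events:
        if ev.kind == "MHW_month":
            ev.displacement_km = thermal_displacement(ev, sst_monthly, clim)
    return events


def median_edge_displacement(
    events: list[ExtremeEvent], edge_cells, window_years: tuple[int, int]
) -> float:
    """Median thermal displacement over (edge cell x MHW month) pairs.

    0 when the window contains no heatwave months at the edge cells.
    Undefined (NaN) displacements are excluded.
    """
    cells = set(map(tuple, edge_cells))
    start, end = window_years
    vals = [
        ev.displacement_km
        for ev in events
        if ev.kind == "MHW_month"
        and ev.cell in cells
        and start <= ev.year <= end
        and ev.displacement_km is not None
        and np.isfinite(ev.displacement_km)
    ]
    if not vals:
        return 0.0
    return float(np.median(vals))


def detect_mcs_runs(
    sst_daily: GridSeries,
    clim: Climatology,
    period: tuple[int, int],
    cells=None,
    min_duration: int = MCS_MIN_DURATION,
) -> list[ExtremeEvent]:
    """Cold-spell runs: >= ``min_duration`` consecutive days below the daily q10.

    Runs are maximal strictly-consecutive stretches (no gap joining).
    ``mean_intensity`` is the mean anomaly versus the daily climatological
    mean over the run (negative); ``cumulative_intensity`` is
    |mean_intensity| x duration.
    """
    start, end = period
    sub = sst_daily.slice_years(start, end)
    times = pd.DatetimeIndex(sub.time_index)
    idx365 = _day_index_365(times)
    consider = _cell_mask(sub, cells)
    ii, jj = np.nonzero(consider)
    events: list[ExtremeEvent] = []
    thresh = clim.daily_q10[idx365]  # (t, lat, lon)
    mean_ref = clim.daily_mean[idx365]
    for i, j in zip(ii.tolist(), jj.tolist()):
        s = sub.values[:, i, j]
        with np.errstate(invalid="ignore"):
            below = (s < thresh[:, i, j]) & ~np.isnan(s)
        b = below.astype(np.int8)
        d = np.diff(b, prepend=0, append=0)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)  # exclusive
        for s0, s1 in zip(starts, ends):
            dur = int(s1 - s0)
            if dur < min_duration:
                continue
            mi = float(np.mean(s[s0:s1] - mean_ref[s0:s1, i, j]))
            events.append(
                ExtremeEvent(
                    kind="MCS_run",
                    cell=(i, j),
                    start=times[s0],
                    end=times[s1 - 1],
                    duration=dur,
                    mean_intensity=mi,
                    cumulative_intensity=abs(mi) * dur,
                )
            )
    return events


def mcs_cumulative_intensity(
    events: list[ExtremeEvent], cells=None, window_years: tuple[int, int] | None = None
) -> float:
    """Total cold-spell cumulative intensity (degC day) over cells and window."""
    cellset = None if cells is None else set(map(tuple, cells))
    total = 0.0
    for ev in events:
        if ev.kind != "MCS_run":
            continue
        if cellset is not None and ev.cell not in cellset:
            continue
        if window_years is not None and not (window_years[0] <= ev.year <= window_years[1]):
            continue
        total += ev.cumulative_intensity
    return total


def mcs_intensity_field(
    events: list[ExtremeEvent],
    lat: np.ndarray,
    lon: np.ndarray,
    landmask: np.ndarray,
    window_years: tuple[int, int] | None = None,
) -> GridField:
    """Per-cell cumulative cold-spell intensity as a field (0 where no events)."""
    vals = np.zeros((lat.size, lon.size))
    for ev in events:
        if ev.kind != "MCS_run":
            continue
        if window_years is not None and not (window_years[0] <= ev.year <= window_years[1]):
            continue
        vals[ev.cell] += ev.cumulative_intensity
    vals[landmask] = np.nan
    return GridField(vals, lat, lon, landmask=landmask, units="degC day")


def events_to_frame(events: list[ExtremeEvent]) -> pd.DataFrame:
    """Flatten events to a table for CSV export."""
    rows = []
    for ev in events:
        rows.append(
            {
                "kind": ev.kind,
                "cell_i": ev.cell[0],
                "cell_j": ev.cell[1],
                "start": str(ev.start),
                "end": str(ev.end),
                "duration": ev.duration,
                "mean_intensity": ev.mean_intensity,
                "cumulative_intensity": ev.cumulative_intensity,
                "displacement_km": ev.displacement_km,
            }
        )
    return pd.DataFrame(rows)
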
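"""Warming trend, spatial temperature gradient and the velocity of climate change.

The velocity field is computed from the annual minimum of mean monthly SST:
per-cell OLS warming trend (degC yr-1) divided by the magnitude of the
spatial temperature gradient (degC km-1), giving km yr-1.  The bearing of
the velocity points toward cooler water when the trend is positive
(thermal conditions displace down-gradient under warming).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from poleward.grid_io import KM_PER_DEG, GridField, GridSeries

#: gradient magnitudes at or below this floor give undefined velocity
GRADIENT_FLOOR = 1e-5


@dataclass
class VelocityField:
    """Per-cell climate-change velocity and its ingredients.

    ``velocity`` is signed (positive under warming); ``velocity_bearing``
    is the compass direction thermal conditions are displacing toward.
    Cells where the gradient magnitude is at or below the floor are NaN.
    """

    trend: GridField
    gradient_mag: GridField
    gradient_bearing: GridField
    velocity: GridField
    velocity_bearing: GridField
    window: tuple[int, int]


def annual_min_monthly_mean(sst_monthly: GridSeries, window_years: tuple[int, int]) -> GridSeries:
    """Annual minimum of the 12 monthly means, per cell.

    Requires complete 12-month coverage of every year in the window.
    """
    start, end = window_years
    sub = sst_monthly.slice_years(start, end)
    years = np.arange(start, end + 1)
    vals = []
    sub_years = sub.years
    for y in years:
        sel = sub_years == y
        if sel.sum() != 12:
            raise ValueError(f"year {y} has {int(sel.sum())} months; need 12")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN land columns
            vals.append(np.nanmin(sub.values[sel], axis=0))
    return GridSeries(
        values=np.stack(vals),
        lat=sst_monthly.lat,
        lon=sst_monthly.lon,
        time_index=years,
        cadence="annual",
        landmask=sst_monthly.landmask,
        units=sst_monthly.units,
    )


def cell_trend(annual: GridSeries) -> GridField:
    """Per-cell OLS slope of value against year (degC yr-1)."""
    years = annual.years.astype(float)
    if years.size < 3:
        raise ValueError("need >=3 annual values for a trend")
    y = annual.values  # (t, lat, lon)
    x = years - years.mean()
    valid = ~np.isnan(y)
    nvalid = valid.sum(axis=0)
    ym = np.where(valid, y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ybar = ym.sum(axis=0) / nvalid
        xbar = (x[:, None, None] * valid).sum(axis=0) / nvalid
        xc = x[:, None, None] - xbar
        num = (xc * (ym - ybar) * valid).sum(axis=0)
        den = (xc**2 * valid).sum(axis=0)
        slope = np.where((nvalid >= 3) & (den > 0), num / den, np.nan)
    return GridField(slope, annual.lat, annual.lon, landmask=None, units="degC/yr")


def _pairwise_axis_gradient(v: np.ndarray, spacing_km: np.ndarray, axis: int) -> np.ndarray:
    """Mean of valid adjacent-pair finite differences over the 3x3 neighbourhood.

    For the along-``axis`` component at cell c, every adjacent pair inside
    the 3-wide band of the cross axis contributes (v_hi - v_lo) / spacing;
    the component is the mean of the valid pair gradients.  Cells with no
    valid pair are NaN (an interior cell automatically degrades to a
    one-sided difference when neighbours on one side are missing).
    """
    v = np.asarray(v, dtype=float)
    nlat, nlon = v.shape
    if axis == 0:
        diff = (v[1:, :] - v[:-1, :]) / spacing_km[:, :]  # (nlat-1, nlon) pair gradients
    else:
        diff = (v[:, 1:] - v[:, :-1]) / spacing_km
    acc = np.zeros_like(v)
    cnt = np.zeros_like(v)

    def add(sl_target, sl_source):
        d = diff[sl_source]
        ok = ~np.isnan(d)
        acc[sl_target][ok] += d[ok]
        cnt[sl_target][ok] += 1

    # each pair gradient is attributed to every cell whose 3x3 window contains it
    if axis == 0:
        for drow in (-1, 0):  # pair (i+drow, i+drow+1) relative to target row i
            for dcol in (-1, 0, 1):
                r0 = max(0, -drow)
                r1 = min(nlat, nlat - 1 - drow)
                c0 = max(0, -dcol)
                c1 = min(nlon, nlon - dcol)
                tgt = (slice(r0, r1), slice(c0, c1))
                src = (slice(r0 + drow, r1 + drow), slice(c0 + dcol, c1 + dcol))
                add(tgt, src)
    else:
        for dcol in (-1, 0):
            for drow in (-1, 0, 1):
                r0 = max(0, -drow)
                r1 = min(nlat, nlat - drow)
                c0 = max(0, -dcol)
                c1 = min(nlon, nlon - 1 - dcol)
                tgt = (slice(r0, r1), slice(c0, c1))
                src = (slice(r0 + drow, r1 + drow), slice(c0 + dcol, c1 + dcol))
                add(tgt, src)

    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    out[np.isnan(v)] = np.nan
    return out


def spatial_gradient(mean_field: GridField) -> tuple[GridField, GridField]:
    """Spatial temperature gradient magnitude and bearing from a 3x3 scheme.

    North-south and east-west components are means of the adjacent-pair
    finite differences inside each cell's 3x3 neighbourhood, each pair
    divided by its great-circle spacing (the east-west spacing is scaled by
    cos(latitude) of the pair's row).  The bearing is the compass direction
    of *increasing* temperature, ``atan2(EW, NS)``.
    """
    lat, lon = mean_field.lat, mean_field.lon
    dlat_km = np.diff(lat) * KM_PER_DEG  # spacing between row pairs
    ns_spacing = dlat_km[:, None] * np.ones((1, lon.size))
    dlon_deg = np.diff(lon)
    ew_spacing = (dlon_deg[None, :] * KM_PER_DEG) * np.cos(np.radians(lat))[:, None]

    ns = _pairwise_axis_gradient(mean_field.values, ns_spacing, axis=0)
    ew = _pairwise_axis_gradient(mean_field.values, ew_spacing, axis=1)

    mag = np.hypot(ns, ew)
    bearing = np.degrees(np.arctan2(ew, ns)) % 360.0
    bearing[np.isnan(mag)] = np.nan
    gm = GridField(mag, lat, lon, landmask=None, units="degC/km")
    gb = GridField(bearing, lat, lon, landmask=None, units="deg")
    return gm, gb


def climate_velocity(
    trend: GridField,
    gradient: tuple[GridField, GridField],
    window: tuple[int, int] = (0, 0),
    gradient_floor: float = GRADIENT_FLOOR,
) -> VelocityField:
    """Climate velocity = trend / gradient magnitude, with bearing.

    Velocity bearing points down-gradient (toward cooler water) when the
    trend is positive, up-gradient when negative; a zero trend keeps the
    gradient bearing.  Cells with gradient magnitude <= ``gradient_floor``
    are undefined (NaN) and drop out of downstream averages.
    """
    gradient_mag, gradient_bearing = gradient
    if trend.values.shape != gradient_mag.values.shape:
        raise ValueError("trend and gradient grids do not match")
    gm = gradient_mag.values
    with np.errstate(invalid="ignore", divide="ignore"):
        vel = np.where(gm > gradient_floor, trend.values / gm, np.nan)
    tr = trend.values
    vb = np.where(tr > 0, (gradient_bearing.values + 180.0) % 360.0, gradient_bearing.values)
    vb = np.where(np.isnan(vel), np.nan, vb)
    return VelocityField(
        trend=trend,
        gradient_mag=gradient_mag,
        gradient_bearing=gradient_bearing,
        velocity=GridField(vel, trend.lat, trend.lon, landmask=None, units="km/yr"),
        velocity_bearing=GridField(vb, trend.lat, trend.lon, landmask=None, units="deg"),
        window=window,
    )


def velocity_from_monthly(sst_monthly: GridSeries, window_years: tuple[int, int]) -> VelocityField:
    """Convenience: annual-minimum series -> trend, gradient, velocity."""
    annual = annual_min_monthly_mean(sst_monthly, window_years)
    trend = cell_trend(annual)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN land columns
        mean = np.nanmean(annual.values, axis=0)
    mean_field = GridField(mean, annual.lat, annual.lon, landmask=None, units="degC")
    grad = spatial_gradient(mean_field)
    return climate_velocity(trend, grad, window=window_years)
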
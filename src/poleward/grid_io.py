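"""Gridded data model, NetCDF I/O, bilinear regridding and spherical geodesy.

Conventions
-----------
* Latitude axis is stored ascending (south -> north); longitude ascending.
* Grids are cell-center registered; a point maps to the cell whose center
  is nearest.
* Missing/land values are ``NaN`` and are propagated (never zero-filled)
  through every derived metric.
* Distances are km, temperatures degC, currents m s-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

EARTH_RADIUS_KM = 6371.0
#: km per degree of latitude (and of longitude at the equator).
KM_PER_DEG = np.pi / 180.0 * EARTH_RADIUS_KM

CADENCES = ("daily", "monthly", "annual")


@dataclass
class GridSeries:
    """A time-stacked physical field on a regular lat-lon grid.

    Parameters
    ----------
    values : ndarray, shape (time, lat, lon)
        Field values; NaN marks missing/land.
    lat, lon : ndarray
        Cell-center coordinates in degrees, strictly monotonic increasing.
    time_index : pandas.DatetimeIndex or array of int years
        Labels for the leading axis.  Integer years imply annual cadence.
    cadence : {"daily", "monthly", "annual"}
    landmask : ndarray of bool, shape (lat, lon)
        True where land.  Derived from all-NaN columns when omitted.
    """

    values: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    time_index: object
    cadence: str
    landmask: np.ndarray | None = None
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be 3-D [time, lat, lon]")
        if self.values.shape[1:] != (self.lat.size, self.lon.size):
            raise ValueError("spatial dims do not match coordinate lengths")
        if len(self.time_index) != self.values.shape[0]:
            raise ValueError("time dim does not match time_index length")
        if self.cadence not in CADENCES:
            raise ValueError(f"unknown cadence {self.cadence!r}")
        for name, coord in (("lat", self.lat), ("lon", self.lon)):
            if coord.size > 1 and not (np.all(np.diff(coord) > 0)):
                raise ValueError(f"{name} must be strictly increasing")
        if self.landmask is None:
            self.landmask = np.all(np.isnan(self.values), axis=0)
        else:
            self.landmask = np.asarray(self.landmask, dtype=bool)
            if self.landmask.shape != self.values.shape[1:]:
                raise ValueError("landmask shape mismatch")
            self.values[:, self.landmask] = np.nan

    @property
    def resolution_deg(self) -> float:
        steps = []
        if self.lat.size > 1:
            steps.append(float(np.mean(np.diff(self.lat))))
        if self.lon.size > 1:
            steps.append(float(np.mean(np.diff(self.lon))))
        return float(np.mean(steps)) if steps else np.nan

    @property
    def years(self) -> np.ndarray:
        if isinstance(self.time_index, pd.DatetimeIndex):
            return np.asarray(self.time_index.year)
        return np.asarray(self.time_index, dtype=int)

    def slice_years(self, start: int, end: int) -> "GridSeries":
        """Subset to calendar years ``start..end`` inclusive."""
        keep = (self.years >= start) & (self.years <= end)
        ti = self.time_index[keep]
        return replace(self, values=self.values[keep], time_index=ti)

    def field(self, t: int, units: str | None = None) -> "GridField":
        return GridField(
            values=self.values[t].copy(),
            lat=self.lat,
            lon=self.lon,
            landmask=self.landmask,
            units=self.units if units is None else units,
        )

    def nearest_cell(self, lat: float, lon: float) -> tuple[int, int]:
        return (int(np.argmin(np.abs(self.lat - lat))), int(np.argmin(np.abs(self.lon - lon))))


@dataclass
class GridField:
    """A single time slice of a :class:`GridSeries`."""

    values: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    landmask: np.ndarray | None = None
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if self.values.shape != (self.lat.size, self.lon.size):
            raise ValueError("field shape does not match coordinates")
        if self.landmask is None:
            self.landmask = np.isnan(self.values)
        else:
            self.landmask = np.asarray(self.landmask, dtype=bool)
            self.values[self.landmask] = np.nan

    def nearest_cell(self, lat: float, lon: float) -> tuple[int, int]:
        return (int(np.argmin(np.abs(self.lat - lat))), int(np.argmin(np.abs(self.lon - lon))))


def _infer_cadence(times: pd.DatetimeIndex) -> str:
    if len(times) < 2:
        raise ValueError("cannot infer cadence from fewer than 2 timestamps")
    deltas = np.diff(times.values).astype("timedelta64[D]").astype(int)
    if np.all(deltas == 1):
        return "daily"
    if np.all((deltas >= 28) & (deltas <= 31)):
        return "monthly"
    if np.all((deltas >= 365) & (deltas <= 366)):
        return "annual"
    raise ValueError("mixed or unsupported time cadence")


def write_grid_series(series: GridSeries, path, variable_name: str = "field") -> None:
    """Write a :class:`GridSeries` to a CF-style NetCDF file."""
    if isinstance(series.time_index, pd.DatetimeIndex):
        time_coord = series.time_index
    else:  # annual: encode years as Jan-1 dates
        time_coord = pd.to_datetime([f"{int(y)}-01-01" for y in series.time_index])
    da = xr.DataArray(
        series.values,
        dims=("time", "lat", "lon"),
        coords={"time": time_coord, "lat": series.lat, "lon": series.lon},
        name=variable_name,
        attrs={"units": series.units, "cadence": series.cadence},
    )
    ds = da.to_dataset()
    ds["landmask"] = xr.DataArray(
        series.landmask.astype(np.int8), dims=("lat", "lon"), attrs={"flag_meanings": "ocean land"}
    )
    ds.to_netcdf(path)


def read_grid_series(path, variable_name: str) -> GridSeries:
    """Read one variable of a CF-style NetCDF file into a :class:`GridSeries`.

    Cadence is taken from the ``cadence`` attribute when present, else
    inferred from the time spacing.  Fill values are mapped to NaN by the
    NetCDF backend; the landmask is read if stored, otherwise derived from
    cells that are missing in every time slice.
    """
    with xr.open_dataset(path) as ds:
        if variable_name not in ds:
            avail = [v for v in ds.data_vars if v != "landmask"]
            raise KeyError(f"variable {variable_name!r} not found; available: {avail}")
        da = ds[variable_name].load()
        landmask = ds["landmask"].values.astype(bool) if "landmask" in ds else None
        lat = ds["lat"].values
        lon = ds["lon"].values
        times = pd.DatetimeIndex(ds["time"].values)
        cadence = da.attrs.get("cadence") or _infer_cadence(times)
        if cadence not in CADENCES:
            raise ValueError(f"unknown cadence {cadence!r}")
        time_index: object = times
        if cadence == "annual":
            time_index = np.asarray(times.year)
        return GridSeries(
            values=da.values.astype(float),
            lat=lat,
            lon=lon,
            time_index=time_index,
            cadence=cadence,
            landmask=landmask,
            units=str(da.attrs.get("units", "")),
        )


def _bilinear_weights(src: np.ndarray, targets: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bracketing indices (i0, i1) and fractional weight of i1 per target."""
    i1 = np.searchsorted(src, targets)
    i1 = np.clip(i1, 1, src.size - 1)
    i0 = i1 - 1
    frac = (targets - src[i0]) / (src[i1] - src[i0])
    frac = np.clip(frac, 0.0, 1.0)
    return i0, i1, frac


def regrid_bilinear(series: GridSeries, target_resolution_deg: float) -> GridSeries:
    """Regrid to a coarser (or equal) resolution by bilinear interpolation.

    Target cell centers are laid out from the source extent at the requested
    resolution.  Each target value is the 4-point bilinear combination of the
    surrounding source centers; source cells that are land are excluded and
    the remaining weights renormalised.  Targets whose entire 4-neighbourhood
    is land become land.
    """
    if target_resolution_deg + 1e-12 < series.resolution_deg:
        raise ValueError("target resolution must be >= source resolution")
    new_lat = np.arange(series.lat[0], series.lat[-1] + 1e-9, target_resolution_deg)
    new_lon = np.arange(series.lon[0], series.lon[-1] + 1e-9, target_resolution_deg)
    if new_lat.size < 2 or new_lon.size < 2:
        raise ValueError("target grid not coverable by source extent")

    ia0, ia1, fa = _bilinear_weights(series.lat, new_lat)
    io0, io1, fo = _bilinear_weights(series.lon, new_lon)

    # corner values: shape (time, nlat_t, nlon_t) per corner
    v = series.values
    corners = [
        (v[:, ia0][:, :, io0], (1 - fa)[:, None] * (1 - fo)[None, :]),
        (v[:, ia0][:, :, io1], (1 - fa)[:, None] * fo[None, :]),
        (v[:, ia1][:, :, io0], fa[:, None] * (1 - fo)[None, :]),
        (v[:, ia1][:, :, io1], fa[:, None] * fo[None, :]),
    ]
    num = np.zeros((v.shape[0], new_lat.size, new_lon.size))
    den = np.zeros_like(num)
    for cv, w in corners:
        valid = ~np.isnan(cv)
        num[valid] += (cv * w[None, :, :])[valid]
        den += w[None, :, :] * valid
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / den, np.nan)

    return GridSeries(
        values=out,
        lat=new_lat,
        lon=new_lon,
        time_index=series.time_index,
        cadence=series.cadence,
        landmask=None,
        units=series.units,
    )


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km (Earth radius 6371.0 km).

    Accepts scalars or broadcastable arrays of coordinates in degrees.
    """
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if np.isscalar(lat1) and np.isscalar(lat2) else d
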
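"""Mean surface-current fields, kinetic energy and directional agreement."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from poleward.grid_io import GridField, GridSeries

#: mean-vector magnitudes below this (m s-1) have undefined bearing
BEARING_FLOOR = 1e-6


@dataclass
class CurrentField:
    """Time-mean surface current with derived strength and direction.

    ``ke`` is 0.5*(u^2+v^2) in m2 s-2; ``bearing`` is the compass direction
    of the mean vector, ``atan2(u, v)``, undefined where the mean vector is
    negligibly small.
    """

    u: GridField
    v: GridField
    ke: GridField
    bearing: GridField
    averaging_window: tuple[int, int]


def mean_annual_currents(
    u_series: GridSeries, v_series: GridSeries, window_years: tuple[int, int]
) -> CurrentField:
    """Per-cell vector mean of u and v over the window; bearing of the mean."""
    start, end = window_years
    u_sub = u_series.slice_years(start, end)
    v_sub = v_series.slice_years(start, end)
    for sub, name in ((u_sub, "u"), (v_sub, "v")):
        present = set(sub.years.tolist())
        missing = sorted(set(range(start, end + 1)) - present)
        if missing:
            raise ValueError(f"{name} series does not cover years {missing}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN land columns
        um = np.nanmean(u_sub.values, axis=0)
        vm = np.nanmean(v_sub.values, axis=0)
    lat, lon = u_series.lat, u_series.lon
    uf = GridField(um, lat, lon, landmask=None, units="m/s")
    vf = GridField(vm, lat, lon, landmask=None, units="m/s")
    ke = kinetic_energy_uv(um, vm)
    speed = np.hypot(um, vm)
    bearing = np.degrees(np.arctan2(um, vm)) % 360.0
    bearing = np.where(speed < BEARING_FLOOR, np.nan, bearing)
    return CurrentField(
        u=uf,
        v=vf,
        ke=GridField(ke, lat, lon, landmask=None, units="m2/s2"),
        bearing=GridField(bearing, lat, lon, landmask=None, units="deg"),
        averaging_window=window_years,
    )


def kinetic_energy_uv(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    return 0.5 * (np.asarray(u, float) ** 2 + np.asarray(v, float) ** 2)


def kinetic_energy(current: CurrentField) -> GridField:
    """0.5*(u^2+v^2) per cell of the supplied velocity field.

    If anomaly (deviation-from-mean) components are supplied, the same
    formula yields eddy kinetic energy.
    """
    ke = kinetic_energy_uv(current.u.values, current.v.values)
    return GridField(ke, current.u.lat, current.u.lon, landmask=None, units="m2/s2")


def directional_agreement(current_bearing: GridField | np.ndarray, velocity_bearing: GridField | np.ndarray):
    """Cosine of the bearing difference, in [-1, 1].

    1 for matching directions, -1 for opposite; NaN wherever either bearing
    is undefined.  Accepts :class:`GridField` or bare arrays/scalars.
    """
    cb = current_bearing.values if isinstance(current_bearing, GridField) else np.asarray(current_bearing, float)
    vb = velocity_bearing.values if isinstance(velocity_bearing, GridField) else np.asarray(velocity_bearing, float)
    agree = np.cos(np.radians(cb - vb))
    if isinstance(current_bearing, GridField):
        return GridField(agree, current_bearing.lat, current_bearing.lon, landmask=None, units="")
    return agree
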
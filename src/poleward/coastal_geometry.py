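"""Coastal strips, cost lattices, least-cost along-coast paths and buffers.

The land/sea mask is rasterised onto a 5-km equirectangular lattice.  A
10-km-wide strip of ocean cells along the coast gets traversal weight 1,
other ocean cells 1e6 and land is impassable, so least-cost routing hugs
the coast but may cross open water when there is no alternative.  The
reported along-coast distance is the geometric length of the optimal path
(the 1e6 weight only steers routing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.graph import MCP_Geometric

from poleward.grid_io import KM_PER_DEG, GridField, haversine_km

OPEN_WATER_WEIGHT = 1.0e6
STRIP_WEIGHT = 1.0
DEFAULT_LATTICE_KM = 5.0
DEFAULT_STRIP_KM = 10.0
DEFAULT_BUFFER_KM = 25.0
#: snapping an observation further than this is flagged
SNAP_FLAG_KM = 10.0


@dataclass
class CoastGeometry:
    """5-km raster of land, coastal strip and traversal weights.

    The lattice is an equirectangular projection about the domain's mean
    latitude; rows run south to north.  ``nearest_ocean`` holds, for every
    lattice cell, the indices of its closest ocean cell (for snapping).
    """

    land: np.ndarray  # bool (rows, cols)
    strip: np.ndarray  # bool, ocean cells within strip_width_km of land
    cost: np.ndarray  # float weights; inf on land
    lattice_lat: np.ndarray  # row-center latitudes (ascending)
    lattice_lon: np.ndarray  # col-center longitudes (ascending)
    cell_km: float
    strip_width_km: float
    buffer_width_km: float
    dist_to_land_km: np.ndarray
    nearest_ocean: np.ndarray  # (2, rows, cols) int indices
    hemisphere: str = "south"

    @property
    def shape(self) -> tuple[int, int]:
        return self.land.shape

    def to_latlon(self, cell: tuple[int, int]) -> tuple[float, float]:
        return float(self.lattice_lat[cell[0]]), float(self.lattice_lon[cell[1]])

    def to_cell(self, lat: float, lon: float, snap_to_ocean: bool = True) -> tuple[tuple[int, int], float]:
        """Nearest lattice cell and the km moved by snapping to ocean."""
        i = int(np.clip(np.argmin(np.abs(self.lattice_lat - lat)), 0, self.shape[0] - 1))
        j = int(np.clip(np.argmin(np.abs(self.lattice_lon - lon)), 0, self.shape[1] - 1))
        if snap_to_ocean and self.land[i, j]:
            i, j = int(self.nearest_ocean[0, i, j]), int(self.nearest_ocean[1, i, j])
        slat, slon = self.to_latlon((i, j))
        return (i, j), float(haversine_km(lat, lon, slat, slon))

    def land_centroid_lon(self) -> float:
        return float(np.mean(self.lattice_lon[np.nonzero(self.land)[1]]))


@dataclass
class ExtensionDistances:
    """The two extension-distance metrics for one out-of-range record."""

    latitudinal_km: float
    coastal_km: float
    path: list[tuple[int, int]]
    open_water_fraction: float = 0.0


def build_coast_geometry(
    landmask: GridField,
    strip_width_km: float = DEFAULT_STRIP_KM,
    lattice_res_km: float = DEFAULT_LATTICE_KM,
    buffer_width_km: float = DEFAULT_BUFFER_KM,
    hemisphere: str = "south",
) -> CoastGeometry:
    """Rasterise a land/sea mask onto the 5-km cost lattice.

    ``landmask`` is a :class:`GridField` whose values are 1/True on land.
    """
    src_land = np.asarray(landmask.values, dtype=float) > 0.5
    if not src_land.any():
        raise ValueError("no coastline present: mask is all ocean")
    if src_land.all():
        raise ValueError("no coastline present: mask is all land")
    lat, lon = landmask.lat, landmask.lon
    ref_lat = float(np.mean(lat))
    ky = KM_PER_DEG
    kx = KM_PER_DEG * np.cos(np.radians(ref_lat))
    dlat = lattice_res_km / ky
    dlon = lattice_res_km / kx
    lattice_lat = np.arange(lat[0], lat[-1] + 1e-12, dlat)
    lattice_lon = np.arange(lon[0], lon[-1] + 1e-12, dlon)

    # nearest source row/col for each lattice row/col
    ii = np.argmin(np.abs(lat[None, :] - lattice_lat[:, None]), axis=1)
    jj = np.argmin(np.abs(lon[None, :] - lattice_lon[:, None]), axis=1)
    land = src_land[np.ix_(ii, jj)]

    dist_to_land = distance_transform_edt(~land) * lattice_res_km
    strip = (~land) & (dist_to_land <= strip_width_km)

    cost = np.full(land.shape, OPEN_WATER_WEIGHT)
    cost[strip] = STRIP_WEIGHT
    cost[land] = np.inf

    _, idx = distance_transform_edt(land, return_indices=True)

    return CoastGeometry(
        land=land,
        strip=strip,
        cost=cost,
        lattice_lat=lattice_lat,
        lattice_lon=lattice_lon,
        cell_km=lattice_res_km,
        strip_width_km=strip_width_km,
        buffer_width_km=buffer_width_km,
        dist_to_land_km=dist_to_land,
        nearest_ocean=idx,
        hemisphere=hemisphere,
    )


def _poleward_sign(hemisphere: str) -> float:
    # poleward = decreasing latitude in the southern hemisphere
    return -1.0 if hemisphere == "south" else 1.0


def intersect_limit_with_coast(
    limit_latitude: float, geometry: CoastGeometry, coast_id: str = "east"
) -> tuple[int, int]:
    """Strip cell on the named coast whose center latitude is nearest the limit.

    ``coast_id`` selects strip cells east or west of the land centroid.
    Ties break deterministically to the more poleward cell, then to the
    cell closest to land.
    """
    si, sj = np.nonzero(geometry.strip)
    if coast_id == "east":
        side = geometry.lattice_lon[sj] >= geometry.land_centroid_lon()
    elif coast_id == "west":
        side = geometry.lattice_lon[sj] <= geometry.land_centroid_lon()
    else:
        raise ValueError(f"unknown coast {coast_id!r}")
    si, sj = si[side], sj[side]
    if si.size == 0:
        raise ValueError(f"no strip cells on coast {coast_id!r}")
    lats = geometry.lattice_lat[si]
    dl = np.abs(lats - limit_latitude)
    dmin = dl.min()
    if dmin > 2 * geometry.cell_km / KM_PER_DEG + 1e-9:
        raise ValueError(
            f"limit latitude {limit_latitude} outside coast extent "
            f"[{lats.min():.3f}, {lats.max():.3f}]"
        )
    cand = np.flatnonzero(np.abs(dl - dmin) < 1e-9)
    sign = _poleward_sign(geometry.hemisphere)
    # most poleward first, then closest to land, then lowest column
    order = sorted(
        cand.tolist(),
        key=lambda k: (sign * -lats[k], geometry.dist_to_land_km[si[k], sj[k]], sj[k]),
    )
    k = order[0]
    return int(si[k]), int(sj[k])


def latitudinal_distance(
    obs_lat: float, obs_lon: float, limit_lat: float, hemisphere: str = "south"
) -> float:
    """Meridional extension distance in km; negative when not poleward."""
    d = haversine_km(limit_lat, obs_lon, obs_lat, obs_lon)
    poleward = (obs_lat - limit_lat) * _poleward_sign(hemisphere) > 0
    return float(d if poleward else -d)


class CoastRouter:
    """Least-cost routing from a fixed origin over the coast cost lattice.

    Wraps :class:`skimage.graph.MCP_Geometric` (8-connected; the cost of a
    step is its length times the mean weight of the two cells) so that one
    cost sweep serves many destinations.
    """

    def __init__(self, geometry: CoastGeometry, origin: tuple[int, int]):
        if geometry.land[origin]:
            raise ValueError("origin is on land")
        self.geometry = geometry
        self.origin = origin
        self._mcp = MCP_Geometric(
            geometry.cost, sampling=(geometry.cell_km, geometry.cell_km), fully_connected=True
        )
        self._costs, _ = self._mcp.find_costs([origin])

    def cost_to(self, cell: tuple[int, int]) -> float:
        return float(self._costs[cell])

    def path_to(self, cell: tuple[int, int]) -> list[tuple[int, int]]:
        if not np.isfinite(self._costs[cell]):
            raise ValueError(f"no path from {self.origin} to {cell}: disconnected ocean")
        return [tuple(map(int, c)) for c in self._mcp.traceback(cell)]

    def distance_to(self, cell: tuple[int, int]) -> tuple[float, list[tuple[int, int]]]:
        path = self.path_to(cell)
        return path_length_km(path, self.geometry.cell_km), path


def path_length_km(path: list[tuple[int, int]], cell_km: float) -> float:
    """Geometric length of a lattice path (sum of step lengths)."""
    if len(path) < 2:
        return 0.0
    steps = np.diff(np.asarray(path, dtype=float), axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum() * cell_km)


def open_water_fraction(path: list[tuple[int, int]], geometry: CoastGeometry) -> float:
    """Fraction of path cells outside the coastal strip (routing ambiguity flag)."""
    if not path:
        return 0.0
    off = sum(1 for c in path if not geometry.strip[c])
    return off / len(path)


def coastal_path_distance(
    limit_point: tuple[int, int],
    obs_point: tuple[int, int],
    geometry: CoastGeometry,
    router: CoastRouter | None = None,
) -> tuple[float, list[tuple[int, int]]]:
    """Along-coast distance: geometric length of the least-cost path (km)."""
    if router is None or router.origin != limit_point:
        router = CoastRouter(geometry, limit_point)
    return router.distance_to(obs_point)


def coastal_buffer(
    limit_point: tuple[int, int],
    obs_point: tuple[int, int],
    geometry: CoastGeometry,
    width_km: float | None = None,
    path: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Ocean cells within ``width_km`` of the limit->observation least-cost path."""
    if width_km is None:
        width_km = geometry.buffer_width_km
    if path is None:
        _, path = coastal_path_distance(limit_point, obs_point, geometry)
    on_path = np.ones(geometry.shape, dtype=bool)
    for c in path:
        on_path[c] = False
    dist = distance_transform_edt(on_path) * geometry.cell_km
    return (dist <= width_km) & ~geometry.land


def buffer_to_grid_cells(
    geometry: CoastGeometry, mask: np.ndarray, grid_lat: np.ndarray, grid_lon: np.ndarray
) -> list[tuple[int, int]]:
    """Unique source-grid cells underlying a set of lattice cells."""
    ri, rj = np.nonzero(mask)
    gi = np.argmin(np.abs(grid_lat[None, :] - geometry.lattice_lat[ri][:, None]), axis=1)
    gj = np.argmin(np.abs(grid_lon[None, :] - geometry.lattice_lon[rj][:, None]), axis=1)
    return sorted(set(zip(gi.tolist(), gj.tolist())))
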
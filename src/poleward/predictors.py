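"""Per-record predictor assembly: buffer summaries over the stated windows.

Each extension record gets: climate velocity (buffer mean over the fixed
long-term window), current kinetic energy and directional agreement
(buffer means, currents averaged over the 10 years before the observation
year), median MHW thermal displacement at the range-edge cells, and the
buffer mean of per-cell MCS cumulative intensity -- plus the species'
six traits and both response distances.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from poleward.coastal_geometry import (
    CoastGeometry,
    CoastRouter,
    buffer_to_grid_cells,
    coastal_buffer,
)
from poleward.currents import directional_agreement, mean_annual_currents
from poleward.extremes import (
    Climatology,
    detect_mcs_runs,
    detect_mhw_months,
    median_edge_displacement,
    thermal_displacement,
)
from poleward.grid_io import GridField, GridSeries
from poleward.screening import TRAIT_COLUMNS, ExtensionRecord
from poleward.thermal_change import VelocityField

logger = logging.getLogger(__name__)

EDGE_RADIUS_KM = 25.0
PREDICTOR_COLUMNS = ("climate_velocity", "kinetic_energy", "directional_agreement",
                     "mhw_displacement", "mcs_cumulative_intensity")


def summarise_buffer(field: GridField, buffer_cells) -> float:
    """Arithmetic mean of the defined field values over the buffer.

    ``buffer_cells`` is either a boolean mask aligned with the field or an
    iterable of (i, j) grid indices.  NaN when every cell is undefined.
    """
    if isinstance(buffer_cells, np.ndarray) and buffer_cells.dtype == bool:
        vals = field.values[buffer_cells]
    else:
        cells = list(buffer_cells)
        if not cells:
            return float("nan")
        ij = np.asarray(cells)
        vals = field.values[ij[:, 0], ij[:, 1]]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def edge_cells(
    limit_point: tuple[int, int], geometry: CoastGeometry, radius_km: float = EDGE_RADIUS_KM
) -> list[tuple[int, int]]:
    """Coastal-strip lattice cells within ``radius_km`` of the limit point."""
    si, sj = np.nonzero(geometry.strip)
    d = np.hypot(si - limit_point[0], sj - limit_point[1]) * geometry.cell_km
    keep = d <= radius_km
    out = list(zip(si[keep].tolist(), sj[keep].tolist()))
    if not out:
        logger.warning("empty edge-cell set at %s", limit_point)
    return out


class PredictorContext:
    """Caches gridded metrics and answers per-record buffer queries.

    Heatwave months are detected once over the analysis period (full
    grid); their thermal displacements are computed lazily per requested
    cell.  Cold-spell runs are detected lazily per cell over the full
    period and filtered to each record's window by event start year.
    Current means are cached per 10-year window.
    """

    def __init__(
        self,
        geometry: CoastGeometry,
        velocity: VelocityField,
        u_series: GridSeries,
        v_series: GridSeries,
        sst_monthly: GridSeries,
        sst_daily: GridSeries,
        clim: Climatology,
        period: tuple[int, int],
    ):
        self.geometry = geometry
        self.velocity = velocity
        self.u_series = u_series
        self.v_series = v_series
        self.sst_monthly = sst_monthly
        self.sst_daily = sst_daily
        self.clim = clim
        self.period = period
        self._currents: dict[tuple[int, int], object] = {}
        self._routers: dict[tuple[int, int], CoastRouter] = {}
        mhw = detect_mhw_months(sst_monthly, clim, period)
        self._mhw_by_cell: dict[tuple[int, int], list] = {}
        for ev in mhw:
            self._mhw_by_cell.setdefault(ev.cell, []).append(ev)
        self._mcs_by_cell: dict[tuple[int, int], list] = {}

    # -- cached primitives -------------------------------------------------
    def router(self, origin: tuple[int, int]) -> CoastRouter:
        if origin not in self._routers:
            self._routers[origin] = CoastRouter(self.geometry, origin)
        return self._routers[origin]

    def currents_for(self, window: tuple[int, int]):
        if window not in self._currents:
            self._currents[window] = mean_annual_currents(self.u_series, self.v_series, window)
        return self._currents[window]

    def mhw_events(self, cells, window: tuple[int, int]):
        out = []
        for c in cells:
            for ev in self._mhw_by_cell.get(tuple(c), []):
                if window[0] <= ev.year <= window[1]:
                    if ev.displacement_km is None:
                        ev.displacement_km = thermal_displacement(ev, self.sst_monthly, self.clim)
                    out.append(ev)
        return out

    def mcs_events(self, cells, window: tuple[int, int]):
        missing = [c for c in map(tuple, cells) if c not in self._mcs_by_cell]
        if missing:
            for c in missing:
                self._mcs_by_cell[c] = []
            for ev in detect_mcs_runs(self.sst_daily, self.clim, self.period, cells=missing):
                self._mcs_by_cell[ev.cell].append(ev)
        out = []
        for c in map(tuple, cells):
            out.extend(ev for ev in self._mcs_by_cell[c] if window[0] <= ev.year <= window[1])
        return out

    # -- per-record predictors --------------------------------------------
    def predictors_for(
        self, limit_cell: tuple[int, int], obs_cell: tuple[int, int], year: int
    ) -> dict[str, float]:
        geom = self.geometry
        window = (year - 10, year - 1)
        router = self.router(limit_cell)
        _, path = router.distance_to(obs_cell)
        buf = coastal_buffer(limit_cell, obs_cell, geom, path=path)
        grid_cells = buffer_to_grid_cells(geom, buf, self.sst_monthly.lat, self.sst_monthly.lon)

        cv = summarise_buffer(self.velocity.velocity, grid_cells)

        cur = self.currents_for(window)
        ke = summarise_buffer(cur.ke, grid_cells)
        agree = directional_agreement(cur.bearing, self.velocity.velocity_bearing)
        da = summarise_buffer(agree, grid_cells)

        edge_lattice = edge_cells(limit_cell, geom)
        edge_mask = np.zeros(geom.shape, dtype=bool)
        for c in edge_lattice:
            edge_mask[c] = True
        edge_grid = buffer_to_grid_cells(geom, edge_mask, self.sst_monthly.lat, self.sst_monthly.lon)
        edge_grid = [c for c in edge_grid if not self.sst_monthly.landmask[c]]
        mhw_evs = self.mhw_events(edge_grid, window)
        mhw = median_edge_displacement(mhw_evs, edge_grid, window)

        ocean_cells = [c for c in grid_cells if not self.sst_daily.landmask[c]]
        mcs_evs = self.mcs_events(ocean_cells, window)
        per_cell = {c: 0.0 for c in ocean_cells}
        for ev in mcs_evs:
            per_cell[ev.cell] += ev.cumulative_intensity
        mcs = float(np.mean(list(per_cell.values()))) if per_cell else float("nan")

        return {
            "climate_velocity": cv,
            "kinetic_energy": ke,
            "directional_agreement": da,
            "mhw_displacement": mhw,
            "mcs_cumulative_intensity": mcs,
        }


def assemble_design_table(
    extensions: list[ExtensionRecord],
    context: PredictorContext,
    species_table: pd.DataFrame,
) -> pd.DataFrame:
    """One analysis row per extension record: responses, predictors, traits.

    Rows with any missing predictor are excluded with a log entry.  Raises
    when a record's 10-year window is not covered by the current series.
    """
    traits = species_table.drop_duplicates("species_id").set_index("species_id")
    years_u = context.u_series.years
    rows = []
    for rec in extensions:
        window = (rec.year - 10, rec.year - 1)
        if window[0] < years_u.min() or window[1] > years_u.max():
            raise ValueError(f"current series does not cover window {window} for year {rec.year}")
        pred = context.predictors_for(rec.limit_cell, rec.obs_cell, rec.year)
        row = {
            "species_id": rec.species_id,
            "year": rec.year,
            "latitudinal_km": rec.latitudinal_km,
            "coastal_km": rec.coastal_km,
            **pred,
        }
        for t in TRAIT_COLUMNS:
            row[t] = traits.loc[rec.species_id, t]
        if any(np.isnan(v) for v in pred.values()):
            logger.warning("record %s/%s dropped: missing predictor", rec.species_id, rec.year)
            continue
        rows.append(row)
    return pd.DataFrame(rows)
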
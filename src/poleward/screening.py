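"""Historical poleward limits and screening of raw out-of-range observations.

Filters applied to raw sightings, in any order (set semantics):

* record scale <= 10 km,
* observation strictly poleward of the species' coast limit by > 20 km,
* not longitudinal-dominant (east-west displacement from the limit point
  greater than ``lon_ratio`` times the latitudinal extension),
* one record per species-year: the annual maximum, taken separately for
  the latitudinal and along-coast response metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from poleward.coastal_geometry import (
    CoastGeometry,
    CoastRouter,
    coastal_path_distance,
    intersect_limit_with_coast,
    latitudinal_distance,
    open_water_fraction,
)
from poleward.grid_io import KM_PER_DEG, haversine_km

logger = logging.getLogger(__name__)

MIN_EXTENSION_KM = 20.0
MAX_RECORD_SCALE_KM = 10.0
#: longitudinal-dominance ratio: drop when |dlon km| > ratio x latitudinal km
LON_DOMINANCE_RATIO = 3.0

TRAIT_COLUMNS = (
    "trophic_category",
    "reproductive_mode",
    "adult_mobility",
    "habitat",
    "water_column",
    "range_size",
)

TRAIT_LEVELS = {
    "trophic_category": ("herbivore", "omnivore", "carnivore"),
    "reproductive_mode": ("planktonic", "non-planktonic", "live-bearing"),
    "adult_mobility": ("high", "low"),
    "habitat": ("inshore/sandy", "rocky", "reef", "oceanic"),
    "water_column": ("benthic", "demersal/benthic", "pelagic"),
}


@dataclass
class ExtensionRecord:
    """One species-year maximum out-of-range record with both distances."""

    species_id: str
    year: int
    obs_lat: float  # observation achieving the latitudinal maximum
    obs_lon: float
    latitudinal_km: float
    coastal_km: float
    coastal_obs_lat: float  # observation achieving the coastal maximum
    coastal_obs_lon: float
    limit_lat: float
    coast: str
    limit_cell: tuple[int, int] | None = None
    obs_cell: tuple[int, int] | None = None
    open_water_fraction: float = 0.0
    flagged: bool = False


def historical_limit(
    occurrences: pd.DataFrame,
    coast: str,
    cutoff_year: int = 2001,
    min_records: int = 200,
    hemisphere: str = "south",
) -> float | None:
    """Poleward-most pre-cutoff latitude, or None when records are too few.

    ``occurrences`` needs columns ``year`` (or ``date``), ``lat`` and
    ``coast``; only rows on the named coast logged before ``cutoff_year``
    count toward the ``min_records`` threshold.
    """
    if occurrences.empty:
        raise ValueError("empty occurrence table")
    df = occurrences
    if "year" not in df.columns:
        df = df.assign(year=pd.to_datetime(df["date"]).dt.year)
    sel = (df["coast"] == coast) & (df["year"] < cutoff_year)
    sub = df.loc[sel]
    if len(sub) < min_records:
        return None
    if hemisphere == "south":
        return float(sub["lat"].min())
    return float(sub["lat"].max())


def _limit_lookup(species_table: pd.DataFrame) -> dict[tuple[str, str], float]:
    out = {}
    for _, row in species_table.iterrows():
        out[(row["species_id"], row["coast"])] = float(row["historical_limit_lat"])
    return out


def filter_to_extensions(
    observations: pd.DataFrame,
    species_table: pd.DataFrame,
    geometry: CoastGeometry | None = None,
    min_extension_km: float = MIN_EXTENSION_KM,
    max_scale_km: float = MAX_RECORD_SCALE_KM,
    lon_ratio: float = LON_DOMINANCE_RATIO,
    hemisphere: str = "south",
) -> list[ExtensionRecord]:
    """Screen raw sightings down to species-year maximum extension records.

    ``observations`` columns: species_id, date (or year), lat, lon,
    record_scale_km.  ``species_table`` columns: species_id, coast,
    historical_limit_lat (one row per species-coast).  When ``geometry``
    is given, along-coast distances are routed on its cost lattice;
    otherwise ``coastal_km`` is NaN.
    """
    limits = _limit_lookup(species_table)
    df = observations.copy()
    if "year" not in df.columns:
        df["year"] = pd.to_datetime(df["date"]).dt.year

    routers: dict[tuple[str, str], CoastRouter] = {}
    limit_cells: dict[tuple[str, str], tuple[int, int]] = {}

    rows = []
    for idx, obs in df.iterrows():
        sp = obs["species_id"]
        coast = obs.get("coast")
        if coast is None:
            match = species_table.loc[species_table["species_id"] == sp, "coast"]
            if match.empty:
                logger.warning("species %s unknown; record skipped", sp)
                continue
            coast = match.iloc[0]
        key = (sp, coast)
        if key not in limits:
            logger.warning("species %s has no %s-coast limit; record skipped", sp, coast)
            continue
        limit_lat = limits[key]
        lat_km = latitudinal_distance(obs["lat"], obs["lon"], limit_lat, hemisphere)
        if lat_km <= min_extension_km:
            continue
        if float(obs.get("record_scale_km", 0.0)) > max_scale_km:
            continue

        if geometry is not None:
            if key not in limit_cells:
                limit_cells[key] = intersect_limit_with_coast(limit_lat, geometry, coast)
            lcell = limit_cells[key]
            limit_lon = geometry.to_latlon(lcell)[1]
        else:
            lcell = None
            limit_lon = float(obs.get("limit_lon", obs["lon"]))
        dlon_km = abs(haversine_km(obs["lat"], limit_lon, obs["lat"], obs["lon"]))
        if dlon_km > lon_ratio * lat_km:
            continue

        coastal_km = np.nan
        ocell = None
        owf = 0.0
        if geometry is not None:
            if key not in routers:
                routers[key] = CoastRouter(geometry, limit_cells[key])
            ocell, snap_km = geometry.to_cell(obs["lat"], obs["lon"])
            try:
                coastal_km, path = routers[key].distance_to(ocell)
            except ValueError:
                logger.warning("no coastal path for %s record at (%s,%s)", sp, obs["lat"], obs["lon"])
                continue
            owf = open_water_fraction(path, geometry)
        rows.append(
            {
                "species_id": sp,
                "coast": coast,
                "year": int(obs["year"]),
                "lat": float(obs["lat"]),
                "lon": float(obs["lon"]),
                "lat_km": float(lat_km),
                "coastal_km": float(coastal_km),
                "limit_lat": limit_lat,
                "limit_cell": lcell,
                "obs_cell": ocell,
                "owf": owf,
            }
        )

    if not rows:
        return []
    tab = pd.DataFrame(rows)
    records: list[ExtensionRecord] = []
    for (sp, year), grp in tab.groupby(["species_id", "year"], sort=True):
        best_lat = grp.loc[grp["lat_km"].idxmax()]
        if grp["coastal_km"].notna().any():
            best_coast = grp.loc[grp["coastal_km"].idxmax()]
        else:
            best_coast = best_lat
        records.append(
            ExtensionRecord(
                species_id=sp,
                year=int(year),
                obs_lat=best_lat["lat"],
                obs_lon=best_lat["lon"],
                latitudinal_km=best_lat["lat_km"],
                coastal_km=best_coast["coastal_km"],
                coastal_obs_lat=best_coast["lat"],
                coastal_obs_lon=best_coast["lon"],
                limit_lat=best_lat["limit_lat"],
                coast=best_lat["coast"],
                limit_cell=best_lat["limit_cell"],
                obs_cell=best_coast["obs_cell"],
                open_water_fraction=float(best_coast["owf"]),
                flagged=bool(best_coast["owf"] > 0.5),
            )
        )
    return records


def records_to_frame(records: list[ExtensionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_id": r.species_id,
                "year": r.year,
                "obs_lat": r.obs_lat,
                "obs_lon": r.obs_lon,
                "latitudinal_km": r.latitudinal_km,
                "coastal_km": r.coastal_km,
                "limit_lat": r.limit_lat,
                "coast": r.coast,
                "open_water_fraction": r.open_water_fraction,
                "flagged": r.flagged,
            }
            for r in records
        ]
    )
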
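"""Ingest protected-area vectors and raster layers into the per-cell table.

Implements the record filtering (strict protection classes only), circular
buffering of point records with reported extents, cumulative dissolving of the
network at decadal cutoffs, geodesic gridding of the dissolved protection with
territory clipping, and the per-variable raster sampling statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from shapely import STRtree
from shapely.geometry import mapping, shape

from .geo import GEOGRAPHIC_CRS, geodesic_area_km2, circle_polygon
from .grid import ALL_VARIABLES, SAMPLING_STAT, AnalysisGrid, Raster

log = logging.getLogger(__name__)

#: Strict protection classes analysed throughout (IUCN I-IV analogue).
STRICT_CATEGORIES = frozenset({"I", "II", "III", "IV"})

#: Decadal cutoffs: the first period is everything up to 1960 inclusive.
DEFAULT_PERIODS = (1960, 1970, 1980, 1990, 2000, 2010, 2016)


class CRSMismatchError(ValueError):
    """Grid and vector data disagree on coordinate reference; nothing is reprojected."""


@dataclass
class ProtectedAreaRecord:
    """One conservation unit: a polygon, or a point with a reported extent."""

    unit_id: str
    geometry: shapely.Geometry
    category: str | None
    status_year: int | None = None
    reported_extent: float | None = None  # km2, required for points
    designation: str = ""

    @property
    def is_point(self) -> bool:
        return self.geometry.geom_type == "Point"


@dataclass
class NetworkSnapshot:
    """The dissolved protection geometry up to (and including) a cutoff year."""

    cutoff_year: int
    geometry: shapely.Geometry
    area_km2: float
    crs: str = GEOGRAPHIC_CRS


def filter_strict_categories(records, allowed_categories=STRICT_CATEGORIES,
                             recategorize=None):
    """Keep only records in strict protection classes.

    ``recategorize`` is an optional ``unit_id -> category`` override applied
    before the membership test (the mechanism used for networks whose classes
    are reported as "Not Reported" but have an earlier authoritative
    categorization). Records with a missing or disallowed category are
    excluded and counted, never silently dropped.
    """
    allowed = frozenset(allowed_categories)
    kept, excluded = [], 0
    for rec in records:
        category = rec.category
        if recategorize and rec.unit_id in recategorize:
            category = recategorize[rec.unit_id]
            rec = replace(rec, category=category)
        if category in allowed:
            kept.append(rec)
        else:
            excluded += 1
    if excluded:
        log.info("filter_strict_categories: excluded %d record(s)", excluded)
    return kept


def buffer_points(point_records, existing_polygons):
    """Turn point records into circles of their reported extent.

    A buffered circle that intersects any existing protected-area *polygon* is
    discarded (the rule is applied against polygons only; two buffered circles
    may overlap each other). Points without a positive reported extent are
    rejected.
    """
    polygons = [r.geometry for r in existing_polygons]
    tree = STRtree(polygons) if polygons else None
    out = []
    for rec in point_records:
        if not rec.is_point:
            raise ValueError(f"record {rec.unit_id} is not a point")
        if rec.reported_extent is None or rec.reported_extent <= 0:
            raise ValueError(
                f"point record {rec.unit_id} lacks a positive reported extent"
            )
        circle = circle_polygon(rec.geometry.x, rec.geometry.y, rec.reported_extent)
        if tree is not None:
            hits = tree.query(circle, predicate="intersects")
            if len(hits) > 0:
                log.info("buffer_points: %s intersects existing polygons, dropped",
                         rec.unit_id)
                continue
        out.append(replace(rec, geometry=circle))
    return out


def dissolve_network(records, cutoff_year, missing_year_policy="include") -> NetworkSnapshot:
    """Union of all geometries established up to ``cutoff_year`` (cumulative).

    Records with a missing ``status_year`` are included in every snapshot by
    default (``missing_year_policy="exclude"`` drops them instead); overlapping
    units contribute their area once.
    """
    if missing_year_policy not in ("include", "exclude"):
        raise ValueError(f"unknown missing-year policy {missing_year_policy!r}")
    geoms = []
    for rec in records:
        if rec.is_point:
            raise ValueError(
                f"record {rec.unit_id} is still a point; buffer before dissolving"
            )
        if rec.status_year is None:
            if missing_year_policy == "include":
                geoms.append(rec.geometry)
        elif rec.status_year <= cutoff_year:
            geoms.append(rec.geometry)
    geometry = shapely.union_all(geoms) if geoms else shapely.Polygon()
    return NetworkSnapshot(
        cutoff_year=int(cutoff_year),
        geometry=geometry,
        area_km2=float(geodesic_area_km2(geometry)) if not geometry.is_empty else 0.0,
    )


def territory_land(grid: AnalysisGrid, territory_geoms=None) -> pd.DataFrame:
    """Land area per (cell, territory) in km2.

    Without territory polygons each cell belongs wholly to its assigned
    ``territory`` column; with polygons, cells shared by two or more
    territories are split by geodesic area so every analysis sees only the
    targeted territory's share.
    """
    if territory_geoms is None:
        if "territory" not in grid.cells.columns:
            raise ValueError("grid has no territory assignment and no polygons given")
        out = pd.DataFrame(
            {
                "cell_id": grid.cells.index,
                "territory": grid.cells["territory"].to_numpy(),
                "land_km2": grid.land_area_km2().to_numpy(),
            }
        )
        return out
    boxes = grid.cell_boxes()
    land_frac = grid.cells["land_frac"].to_numpy()
    rows = []
    for terr, geom in territory_geoms.items():
        tree_idx = shapely.STRtree(boxes).query(geom, predicate="intersects")
        pieces = shapely.intersection(boxes[tree_idx], geom)
        areas = geodesic_area_km2(pieces) * land_frac[tree_idx]
        for cid, a in zip(grid.cells.index[tree_idx], areas):
            if a > 0:
                rows.append((cid, terr, float(a)))
    return pd.DataFrame(rows, columns=["cell_id", "territory", "land_km2"])


def grid_protection(snapshot: NetworkSnapshot, grid: AnalysisGrid,
                    territory_geoms=None) -> pd.DataFrame:
    """Protected km2 per (cell, territory) from a dissolved snapshot.

    Protection is intersected with each cell (and with territory polygons when
    given) and measured geodesically, so summing the column recovers the
    snapshot area up to the sliver lost outside the grid/territories.
    """
    if snapshot.crs != grid.crs:
        raise CRSMismatchError(
            f"snapshot CRS {snapshot.crs} != grid CRS {grid.crs}; reproject explicitly"
        )
    boxes = grid.cell_boxes()
    cell_ids = grid.cells.index.to_numpy()
    acc: dict[tuple, float] = {}
    if snapshot.geometry.is_empty:
        parts = []
    else:
        parts = shapely.get_parts(snapshot.geometry)
    tree = STRtree(boxes)
    cell_terr = (
        grid.cells["territory"].to_numpy()
        if territory_geoms is None and "territory" in grid.cells.columns
        else None
    )
    for part in parts:
        idx = tree.query(part, predicate="intersects")
        if len(idx) == 0:
            continue
        pieces = shapely.intersection(boxes[idx], part)
        if territory_geoms is None:
            areas = geodesic_area_km2(pieces)
            for i, a in zip(idx, areas):
                if a > 0:
                    terr = cell_terr[i] if cell_terr is not None else None
                    key = (cell_ids[i], terr)
                    acc[key] = acc.get(key, 0.0) + float(a)
        else:
            for terr, tgeom in territory_geoms.items():
                sub = shapely.intersection(pieces, tgeom)
                areas = geodesic_area_km2(sub)
                for i, a in zip(idx, areas):
                    if a > 0:
                        key = (cell_ids[i], terr)
                        acc[key] = acc.get(key, 0.0) + float(a)
    if not acc:
        return pd.DataFrame(columns=["cell_id", "territory", "protected_km2"])
    out = pd.DataFrame(
        [(c, t, a) for (c, t), a in acc.items()],
        columns=["cell_id", "territory", "protected_km2"],
    )
    return out.sort_values(["cell_id", "territory"]).reset_index(drop=True)


def sample_layers(rasters, grid: AnalysisGrid, stats=None) -> AnalysisGrid:
    """Aggregate raster layers into per-cell values with per-variable statistics.

    ``rasters`` maps variable name to a :class:`Raster`; tourism attractiveness
    takes a ``(photos, population)`` pair and stores the cell-level ratio of
    totals. Statistics: MEAN for the climatic/topographic/edaphic layers and
    distances-to-frontiers/cropland suitability, SUM for population, MIN for
    distance to roads. ``stats`` overrides the statistic per variable (e.g. for
    layers that are already cell-level values). Cells with no valid pixels are
    left missing.
    """
    cells = grid.cells.copy()
    stats = stats or {}
    for var, ras in rasters.items():
        stat = stats.get(var, SAMPLING_STAT.get(var, "mean"))
        if stat == "ratio":
            num, den = ras
            cells[var] = _aggregate(num, grid, "sum") / _aggregate(den, grid, "sum")
        else:
            cells[var] = _aggregate(ras, grid, stat)
    return AnalysisGrid(grid.lon_min, grid.lat_min, grid.nx, grid.ny,
                        grid.resolution, cells, grid.crs)


def _aggregate(raster: Raster, grid: AnalysisGrid, stat: str) -> pd.Series:
    if raster.resolution > grid.resolution * (1 + 1e-9) and stat == "mean":
        raise ValueError(
            "raster coarser than the grid; mean sampling needs resolution <= cell size"
        )
    x, y = raster.pixel_centers()
    vals = raster.data.ravel()
    col = np.floor((x - grid.lon_min) / grid.resolution).astype(int)
    row = np.floor((y - grid.lat_min) / grid.resolution).astype(int)
    inside = (col >= 0) & (col < grid.nx) & (row >= 0) & (row < grid.ny) & ~np.isnan(vals)
    cell = row[inside] * grid.nx + col[inside]
    s = pd.Series(vals[inside]).groupby(cell).agg(stat)
    return s.reindex(grid.cells.index)


def build_cell_table(grid: AnalysisGrid, records, periods=DEFAULT_PERIODS,
                     territory_geoms=None, missing_year_policy="include",
                     allowed_categories=STRICT_CATEGORIES,
                     recategorize=None) -> pd.DataFrame:
    """Full ingest: filter, buffer, dissolve per period, grid, and assemble.

    Returns the canonical tidy table with one row per cell x territory x
    period: cell ids, coordinates, territory/ecoregion, land area, sampled
    variable values, and cumulative protected km2 at each cutoff.
    """
    records = filter_strict_categories(records, allowed_categories, recategorize)
    points = [r for r in records if r.is_point]
    polys = [r for r in records if not r.is_point]
    records = polys + buffer_points(points, polys)

    land = territory_land(grid, territory_geoms)
    var_cols = [v for v in ALL_VARIABLES if v in grid.cells.columns]
    meta_cols = ["lon", "lat"] + (["ecoregion"] if "ecoregion" in grid.cells.columns else [])
    meta = grid.cells[meta_cols + var_cols]

    frames = []
    for period in periods:
        snap = dissolve_network(records, period, missing_year_policy)
        prot = grid_protection(snap, grid, territory_geoms)
        tab = land.merge(prot, on=["cell_id", "territory"], how="left")
        tab["protected_km2"] = tab["protected_km2"].fillna(0.0)
        # numerical guard: clipped to the cell's land share (no double counting)
        tab["protected_km2"] = np.minimum(tab["protected_km2"], tab["land_km2"])
        tab["period"] = int(period)
        frames.append(tab)
    table = pd.concat(frames, ignore_index=True)
    table = table.merge(meta, left_on="cell_id", right_index=True, how="left")
    return table


# -- GeoJSON / CSV interchange ---------------------------------------------

def records_to_geojson(records, path) -> None:
    features = []
    for rec in records:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(rec.geometry),
                "properties": {
                    "unit_id": rec.unit_id,
                    "category": rec.category,
                    "status_year": rec.status_year,
                    "reported_extent": rec.reported_extent,
                    "designation": rec.designation,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def records_from_geojson(path) -> list:
    with open(path) as fh:
        fc = json.load(fh)
    out = []
    for feat in fc["features"]:
        p = feat.get("properties", {})
        out.append(
            ProtectedAreaRecord(
                unit_id=str(p.get("unit_id")),
                geometry=shape(feat["geometry"]),
                category=p.get("category"),
                status_year=p.get("status_year"),
                reported_extent=p.get("reported_extent"),
                designation=p.get("designation") or "",
            )
        )
    return out


def geoms_to_geojson(geoms: dict, path, key="name") -> None:
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": {key: str(k)}}
        for k, g in geoms.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def geoms_from_geojson(path, key="name") -> dict:
    with open(path) as fh:
        fc = json.load(fh)
    return {f["properties"][key]: shape(f["geometry"]) for f in fc["features"]}


def write_cell_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
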
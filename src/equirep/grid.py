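"""The analysis grid and text raster container.

The sampling backbone of the whole pipeline is a regular lon/lat lattice of
0.1-degree cells. Each cell carries its centre coordinates, a geodesic area in
km^2, a land fraction, a territory and ecoregion assignment, and the sampled
values of the ten analysis variables (five physical, five human).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .geo import GEOGRAPHIC_CRS, band_cell_area_km2

#: Physical (climatic/topographic/edaphic) gradients, in their fixed analysis order.
PHYSICAL_VARIABLES = (
    "temperature",
    "precipitation",
    "elevation",
    "slope",
    "soil_fertility",
)

#: Human-related (demographic/economic/geopolitical) gradients, fixed order.
HUMAN_VARIABLES = (
    "tourism_attractiveness",
    "distance_to_frontiers",
    "population",
    "distance_to_roads",
    "cropland_suitability",
)

ALL_VARIABLES = PHYSICAL_VARIABLES + HUMAN_VARIABLES

#: How each variable is aggregated from finer rasters into grid cells.
SAMPLING_STAT = {
    "temperature": "mean",
    "precipitation": "mean",
    "elevation": "mean",
    "slope": "mean",
    "soil_fertility": "mean",
    "tourism_attractiveness": "ratio",  # total photos / total population
    "distance_to_frontiers": "mean",
    "population": "sum",
    "distance_to_roads": "min",
    "cropland_suitability": "mean",
}


@dataclass
class AnalysisGrid:
    """Regular lon/lat cell lattice with per-cell attributes.

    ``cells`` is indexed by integer ``cell_id`` (row-major, row 0 = southern
    row) and holds at least ``lon``, ``lat`` (centres), ``area_km2`` and
    ``land_frac``; territory/ecoregion ids and variable columns are added by
    the landscape generator or the ingest readers.
    """

    lon_min: float
    lat_min: float
    nx: int
    ny: int
    resolution: float
    cells: pd.DataFrame
    crs: str = GEOGRAPHIC_CRS

    @classmethod
    def create(cls, lon_min, lat_min, nx, ny, resolution=0.1) -> "AnalysisGrid":
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        if nx < 1 or ny < 1:
            raise ValueError("grid must have at least one cell per axis")
        cols, rows = np.meshgrid(np.arange(nx), np.arange(ny))
        cols = cols.ravel()
        rows = rows.ravel()
        lon = lon_min + (cols + 0.5) * resolution
        lat = lat_min + (rows + 0.5) * resolution
        area = band_cell_area_km2(
            lat_min + rows * resolution, lat_min + (rows + 1) * resolution, resolution
        )
        cells = pd.DataFrame(
            {
                "row": rows,
                "col": cols,
                "lon": lon,
                "lat": lat,
                "area_km2": area,
                "land_frac": 1.0,
            },
            index=pd.RangeIndex(nx * ny, name="cell_id"),
        )
        return cls(lon_min, lat_min, nx, ny, resolution, cells)

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.nx * self.resolution

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.ny * self.resolution

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def land_area_km2(self) -> pd.Series:
        return self.cells["area_km2"] * self.cells["land_frac"]

    def cell_boxes(self) -> np.ndarray:
        """Shapely boxes of every cell, aligned with ``cells.index``."""
        r = self.resolution
        x0 = self.lon_min + self.cells["col"].to_numpy() * r
        y0 = self.lat_min + self.cells["row"].to_numpy() * r
        return shapely.box(x0, y0, x0 + r, y0 + r)

    def cell_box(self, cell_id: int):
        r = self.resolution
        row, col = self.cells.loc[cell_id, ["row", "col"]]
        x0 = self.lon_min + col * r
        y0 = self.lat_min + row * r
        return shapely.box(x0, y0, x0 + r, y0 + r)

    def values_2d(self, column: str) -> np.ndarray:
        """A cell column reshaped to (ny, nx), row 0 = southern row."""
        return self.cells[column].to_numpy().reshape(self.ny, self.nx)

    # -- serialization ------------------------------------------------------

    def to_csv(self, path) -> None:
        header = (
            f"# equirep-grid lon_min={self.lon_min!r} lat_min={self.lat_min!r} "
            f"nx={self.nx} ny={self.ny} resolution={self.resolution!r} crs={self.crs}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            self.cells.to_csv(fh)

    @classmethod
    def from_csv(cls, path) -> "AnalysisGrid":
        with open(path) as fh:
            header = fh.readline()
            m = re.match(
                r"# equirep-grid lon_min=(\S+) lat_min=(\S+) nx=(\d+) ny=(\d+) "
                r"resolution=(\S+) crs=(\S+)",
                header,
            )
            if not m:
                raise ValueError(f"{path} is not an equirep grid CSV")
            cells = pd.read_csv(fh, index_col="cell_id")
        return cls(
            lon_min=float(m.group(1)),
            lat_min=float(m.group(2)),
            nx=int(m.group(3)),
            ny=int(m.group(4)),
            resolution=float(m.group(5)),
            cells=cells,
            crs=m.group(6),
        )


@dataclass
class Raster:
    """A single-band raster on a regular lon/lat grid, row 0 = northern row.

    Serialized as ESRI ASCII grid, a plain-text interchange format every GIS
    reads; values are pixel-centre point samples or totals depending on the
    variable's sampling statistic.
    """

    data: np.ndarray
    x_min: float
    y_min: float
    resolution: float
    nodata: float = -9999.0
    crs: str = GEOGRAPHIC_CRS

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    def pixel_centers(self):
        """(x, y) arrays of pixel centres, flattened row-major."""
        cols, rows = np.meshgrid(np.arange(self.ncols), np.arange(self.nrows))
        x = self.x_min + (cols.ravel() + 0.5) * self.resolution
        y_max = self.y_min + self.nrows * self.resolution
        y = y_max - (rows.ravel() + 0.5) * self.resolution
        return x, y

    def write_ascii(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.x_min!r}\n")
            fh.write(f"yllcorner {self.y_min!r}\n")
            fh.write(f"cellsize {self.resolution!r}\n")
            fh.write(f"NODATA_value {self.nodata!r}\n")
            data = np.where(np.isnan(self.data), self.nodata, self.data)
            np.savetxt(fh, data, fmt="%.10g")

    @classmethod
    def read_ascii(cls, path) -> "Raster":
        with open(path) as fh:
            head = {}
            for _ in range(6):
                key, val = fh.readline().split()
                head[key.lower()] = float(val)
            data = np.loadtxt(io.StringIO(fh.read()))
        data = np.atleast_2d(data)
        nodata = head.get("nodata_value", -9999.0)
        data = np.where(data == nodata, np.nan, data)
        return cls(
            data=data,
            x_min=head["xllcorner"],
            y_min=head["yllcorner"],
            resolution=head["cellsize"],
            nodata=nodata,
        )
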
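"""Synthetic landscapes with planted protection structure.

Generates the three inputs the pipeline consumes — smooth autocorrelated
environmental/human fields, contiguous territory and ecoregion partitions, and
protected-area networks with controllable placement bias and establishment
years — so that every downstream statistic can be checked against a known
ground truth. Nothing here aims at climatological realism; fields are white
noise smoothed with a Gaussian kernel plus a monotone large-scale trend, and
territories/ecoregions are Voronoi partitions of random seed points, which is
enough to give irregular, contiguous regions and non-degenerate gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from scipy.ndimage import gaussian_filter

from .grid import ALL_VARIABLES, HUMAN_VARIABLES, PHYSICAL_VARIABLES, AnalysisGrid, Raster
from .ingest import ProtectedAreaRecord
from .representation import assign_bins, trimmed_equal_width_edges


class ScenarioShortfallError(ValueError):
    """Requested protected area exceeds what the targeted cells can supply."""


@dataclass
class FieldSpec:
    """Generator parameters for one continuous field.

    The field is ``baseline + trend + noise`` where the trend changes by
    ``trend_magnitude`` (variable units) across the extent along ``trend_axis``
    and the noise is unit-variance Gaussian noise smoothed over
    ``autocorr_length`` cells, scaled by ``noise_amplitude``.
    """

    baseline: float = 0.0
    trend_axis: str = "lon"  # "lon" (west-east) or "lat" (south-north)
    trend_magnitude: float = 1.0
    noise_amplitude: float = 0.1
    autocorr_length: float = 3.0
    lower_bound: float | None = None
    log_scale: bool = False  # exponentiate (for heavy-tailed fields like population)


def default_field_specs() -> dict:
    """Realistic-order-of-magnitude defaults for the ten analysis variables."""
    return {
        "temperature": FieldSpec(25.0, "lat", -18.0, 1.5, 5.0),  # degC, cooler poleward
        "precipitation": FieldSpec(2000.0, "lon", -1600.0, 200.0, 4.0, lower_bound=0.0),
        "elevation": FieldSpec(0.2, "lon", 3.0, 0.4, 3.0, lower_bound=0.0),  # km
        "slope": FieldSpec(1.0, "lon", 8.0, 1.5, 2.0, lower_bound=0.0),  # degrees
        "soil_fertility": FieldSpec(12.0, "lat", 10.0, 3.0, 4.0, lower_bound=0.0),
        "tourism_attractiveness": FieldSpec(-4.0, "lon", 1.0, 1.2, 3.0, log_scale=True),
        "distance_to_frontiers": FieldSpec(20.0, "lat", 300.0, 40.0, 5.0, lower_bound=0.0),
        "population": FieldSpec(4.0, "lat", 3.0, 1.8, 3.0, log_scale=True),
        "distance_to_roads": FieldSpec(1.0, "lon", 60.0, 10.0, 3.0, lower_bound=0.0),
        "cropland_suitability": FieldSpec(20.0, "lat", 60.0, 12.0, 4.0, lower_bound=0.0),
    }


@dataclass
class LandscapeSpec:
    """Full specification of a synthetic landscape; a pure function of (spec, seed)."""

    lon_min: float = -65.0
    lat_min: float = -35.0
    lon_max: float = -55.0
    lat_max: float = -25.0
    resolution: float = 0.1
    n_territories: int = 3
    n_ecoregions: int = 12
    field_specs: dict = field(default_factory=default_field_specs)
    seed: int = 0

    @property
    def nx(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.resolution))

    @property
    def ny(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.resolution))

    def validate(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.nx < 10 or self.ny < 10:
            raise ValueError(
                f"degenerate extent: {self.nx} x {self.ny} cells; at least 10 cells "
                "are needed along each axis so that 10 histogram bins are populated"
            )
        if self.n_territories < 1 or self.n_ecoregions < 1:
            raise ValueError("need at least one territory and one ecoregion")


def _generate_field(spec: FieldSpec, nx, ny, rng) -> np.ndarray:
    noise = rng.standard_normal((ny, nx))
    if spec.autocorr_length > 0:
        noise = gaussian_filter(noise, sigma=spec.autocorr_length, mode="reflect")
        sd = noise.std()
        if sd > 0:
            noise /= sd
    f = spec.baseline + spec.noise_amplitude * noise
    if spec.trend_axis == "lon":
        t = np.linspace(0.0, 1.0, nx)[np.newaxis, :]
    elif spec.trend_axis == "lat":
        t = np.linspace(0.0, 1.0, ny)[:, np.newaxis]
    else:
        raise ValueError(f"unknown trend axis {spec.trend_axis!r}")
    f = f + spec.trend_magnitude * t
    if spec.log_scale:
        f = np.exp(f)
    if spec.lower_bound is not None:
        f = np.maximum(f, spec.lower_bound)
    return f


def _voronoi_labels(grid: AnalysisGrid, n_regions, rng, prefix) -> np.ndarray:
    """Nearest-seed (Voronoi) partition of the cells; retries until every
    region captures at least one cell."""
    lon = grid.cells["lon"].to_numpy()
    lat = grid.cells["lat"].to_numpy()
    for _ in range(100):
        sx = rng.uniform(grid.lon_min, grid.lon_max, n_regions)
        sy = rng.uniform(grid.lat_min, grid.lat_max, n_regions)
        d2 = (lon[:, None] - sx[None, :]) ** 2 + (lat[:, None] - sy[None, :]) ** 2
        lab = np.argmin(d2, axis=1)
        if len(np.unique(lab)) == n_regions:
            width = len(str(n_regions))
            return np.array([f"{prefix}{i + 1:0{width}d}" for i in lab])
    raise RuntimeError("could not seat all regions; extent too small for n_regions")


def generate_landscape(spec: LandscapeSpec) -> AnalysisGrid:
    """Build the full synthetic grid: fields, territories, ecoregions, areas."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    grid = AnalysisGrid.create(spec.lon_min, spec.lat_min, spec.nx, spec.ny,
                               spec.resolution)
    for var in ALL_VARIABLES:
        fs = spec.field_specs.get(var)
        if fs is None:
            continue
        grid.cells[var] = _generate_field(fs, spec.nx, spec.ny, rng).ravel()
    grid.cells["territory"] = _voronoi_labels(grid, spec.n_territories, rng, "T")
    grid.cells["ecoregion"] = _voronoi_labels(grid, spec.n_ecoregions, rng, "E")
    return grid


def territory_polygons(grid: AnalysisGrid, column="territory") -> dict:
    """Dissolved cell-aligned polygons per territory (or ecoregion)."""
    boxes = grid.cell_boxes()
    out = {}
    for name, idx in grid.cells.groupby(column).groups.items():
        pos = grid.cells.index.get_indexer(idx)
        out[name] = shapely.union_all(boxes[pos])
    return out


def landscape_rasters(grid: AnalysisGrid) -> dict:
    """Per-variable Raster views of the landscape (row 0 = northern row)."""
    out = {}
    for var in ALL_VARIABLES:
        if var not in grid.cells.columns:
            continue
        data = grid.values_2d(var)[::-1]  # south-up storage -> north-up raster
        out[var] = Raster(data, grid.lon_min, grid.lat_min, grid.resolution)
    return out


@dataclass
class PlacementScenario:
    """Where and when protection is planted.

    * ``uniform`` — every cell is protected over ``total_protected_fraction``
      of its area (a centred sub-rectangle), the idealized spatially uniform
      network: every bin of every gradient gets the same PEx.
    * ``single_bin`` — all protection falls inside one bin (``target_bin``,
      1-based) of ``target_variable`` under the standard 10-bin trimmed
      binning: the maximally concentrated network.
    * ``biased`` — whole cells are drawn without replacement with probability
      proportional to ``exp(-bias_strength * z(target_variable))``, emulating
      placement that avoids high values of a driver (population, road access).
    """

    scenario_name: str = "uniform"
    target_variable: str | None = None
    target_bin: int | None = None
    bias_strength: float = 0.0
    total_protected_fraction: float = 0.1
    establishment_years: dict = field(
        default_factory=lambda: {d: 1.0 for d in range(1930, 2020, 10)}
    )
    n_units: int = 25
    point_fraction: float = 0.05
    n_bins: int = 10

    def validate(self) -> None:
        if self.scenario_name not in ("uniform", "single_bin", "biased"):
            raise ValueError(f"unknown scenario {self.scenario_name!r}")
        if not (0.0 < self.total_protected_fraction < 1.0):
            raise ValueError("total_protected_fraction must be in (0, 1)")
        if self.scenario_name in ("single_bin", "biased") and not self.target_variable:
            raise ValueError(f"{self.scenario_name} scenario needs a target_variable")
        if self.scenario_name == "single_bin" and self.target_bin is None:
            raise ValueError("single_bin scenario needs a target_bin")
        if self.n_units < 0:
            raise ValueError("n_units must be >= 0")


@dataclass
class PlacementTruth:
    """Machine-readable ground truth emitted alongside a planted network."""

    scenario: PlacementScenario
    cell_fraction: pd.Series  # protected fraction of each cell's area
    target_edges: np.ndarray | None
    bin_area_km2: np.ndarray | None
    bin_protected_km2: np.ndarray | None

    @property
    def bin_pex(self) -> np.ndarray | None:
        if self.bin_area_km2 is None:
            return None
        with np.errstate(invalid="ignore", divide="ignore"):
            p = 100.0 * self.bin_protected_km2 / self.bin_area_km2
        return np.where(self.bin_area_km2 > 0, p, 0.0)


def _cell_patch(grid: AnalysisGrid, cell_id: int, fraction: float):
    """Centred sub-rectangle covering ``fraction`` of the cell's area."""
    r = grid.resolution
    row, col = grid.cells.loc[cell_id, ["row", "col"]]
    cx = grid.lon_min + (col + 0.5) * r
    cy = grid.lat_min + (row + 0.5) * r
    h = r * np.sqrt(fraction) / 2.0
    return shapely.box(cx - h, cy - h, cx + h, cy + h)


def _uniform_unit_geoms(grid: AnalysisGrid, selected: pd.Series, n_units: int):
    """Units for the uniform scenario: each unit takes one vertical sliver of
    every cell's centred sub-rectangle, so every unit is itself spatially
    uniform and the network stays uniform at every decadal cutoff."""
    r = grid.resolution
    rows = grid.cells.loc[selected.index, "row"].to_numpy()
    cols = grid.cells.loc[selected.index, "col"].to_numpy()
    frac = selected.to_numpy()
    cx = grid.lon_min + (cols + 0.5) * r
    cy = grid.lat_min + (rows + 0.5) * r
    h = r * np.sqrt(frac) / 2.0
    geoms = []
    for u in range(n_units):
        x0 = cx - h + (2 * h) * u / n_units
        x1 = cx - h + (2 * h) * (u + 1) / n_units
        geoms.append(shapely.union_all(shapely.box(x0, cy - h, x1, cy + h)))
    return geoms


def generate_protected_network(grid: AnalysisGrid, scenario: PlacementScenario,
                               seed: int):
    """Plant a protected network on the grid.

    Returns ``(records, truth)``: the protected-area records (polygons, plus a
    configurable fraction of point+extent records for the ``biased`` scenario)
    and the :class:`PlacementTruth` with per-cell protected fractions and the
    per-bin protected areas of the target variable.
    """
    scenario.validate()
    rng = np.random.default_rng(seed)
    areas = grid.land_area_km2()
    total_area = float(areas.sum())
    requested = scenario.total_protected_fraction * total_area

    fractions = pd.Series(0.0, index=grid.cells.index)
    edges = None
    if scenario.scenario_name == "uniform":
        fractions[:] = scenario.total_protected_fraction
    else:
        var = grid.cells[scenario.target_variable].to_numpy(dtype=float)
        edges = trimmed_equal_width_edges(var, areas.to_numpy(), n_bins=scenario.n_bins)
        bins = assign_bins(var, edges)
        if scenario.scenario_name == "single_bin":
            if not (1 <= scenario.target_bin <= scenario.n_bins):
                raise ValueError(
                    f"target_bin {scenario.target_bin} outside 1..{scenario.n_bins}"
                )
            pool = np.flatnonzero(bins == scenario.target_bin - 1)
            available = float(areas.iloc[pool].sum())
            if requested > available:
                raise ScenarioShortfallError(
                    f"requested {requested:.1f} km2 but bin {scenario.target_bin} of "
                    f"{scenario.target_variable} holds only {available:.1f} km2 "
                    f"(shortfall {requested - available:.1f} km2)"
                )
            order = rng.permutation(pool)
        else:  # biased
            # normal scores of the driver's ranks: the log-odds weight acts on
            # the variable's ordering, robust to heavy-tailed fields
            ranks = stats.rankdata(var, method="average")
            z = stats.norm.ppf((ranks - 0.5) / len(var))
            logw = -scenario.bias_strength * z
            # Gumbel-max trick: exact weighted sampling without replacement
            order = np.argsort(-(logw + rng.gumbel(size=len(logw))))
        cum = np.cumsum(areas.to_numpy()[order])
        n_take = int(np.searchsorted(cum, requested) + 1)
        n_take = min(n_take, len(order))
        fractions.iloc[order[:n_take]] = 1.0

    if scenario.n_units == 0:
        truth = _truth(grid, scenario, fractions, edges, areas)
        return [], truth

    selected = fractions[fractions > 0]
    point_fraction = scenario.point_fraction if scenario.scenario_name == "biased" else 0.0
    n_points = int(point_fraction * scenario.n_units)
    point_units = set(rng.choice(scenario.n_units, size=n_points, replace=False)) \
        if n_points else set()

    decades = np.array(sorted(scenario.establishment_years))
    weights = np.array([scenario.establishment_years[d] for d in decades], dtype=float)
    weights /= weights.sum()

    if scenario.scenario_name == "uniform":
        unit_geoms = _uniform_unit_geoms(grid, selected, scenario.n_units)
        unit_areas = [
            float((areas[selected.index] * selected).sum()) / scenario.n_units
        ] * scenario.n_units
    else:
        # whole-cell scenarios: units are blocks of the selected cells in
        # lattice order (contiguous-ish patches)
        unit_idx = np.minimum(
            np.arange(len(selected)) * scenario.n_units // max(len(selected), 1),
            scenario.n_units - 1,
        )
        unit_geoms, unit_areas = [], []
        for u in range(scenario.n_units):
            cells_u = selected.index[unit_idx == u]
            if len(cells_u) == 0:
                unit_geoms.append(None)
                unit_areas.append(0.0)
                continue
            unit_geoms.append(
                shapely.union_all([_cell_patch(grid, c, fractions[c]) for c in cells_u])
            )
            unit_areas.append(float((areas[cells_u] * fractions[cells_u]).sum()))

    records = []
    categories = ("I", "II", "III", "IV")
    for u in range(scenario.n_units):
        geom = unit_geoms[u]
        if geom is None:
            continue
        area_u = unit_areas[u]
        year = min(int(rng.choice(decades, p=weights)) + int(rng.integers(0, 10)), 2016)
        if u in point_units:
            rec = ProtectedAreaRecord(
                unit_id=f"U{u + 1:04d}",
                geometry=shapely.centroid(geom),
                category=categories[u % 4],
                status_year=year,
                reported_extent=area_u,
                designation="synthetic point unit",
            )
        else:
            rec = ProtectedAreaRecord(
                unit_id=f"U{u + 1:04d}",
                geometry=geom,
                category=categories[u % 4],
                status_year=year,
                designation="synthetic polygon unit",
            )
        records.append(rec)
    truth = _truth(grid, scenario, fractions, edges, areas)
    return records, truth


def _truth(grid, scenario, fractions, edges, areas) -> PlacementTruth:
    bin_area = bin_prot = None
    if scenario.target_variable is not None:
        var = grid.cells[scenario.target_variable].to_numpy(dtype=float)
        if edges is None:
            edges = trimmed_equal_width_edges(var, areas.to_numpy(),
                                              n_bins=scenario.n_bins)
        bins = assign_bins(var, edges)
        a = areas.to_numpy()
        bin_area = np.bincount(bins, weights=a, minlength=scenario.n_bins)
        bin_prot = np.bincount(bins, weights=a * fractions.to_numpy(),
                               minlength=scenario.n_bins)
    return PlacementTruth(
        scenario=scenario,
        cell_fraction=fractions,
        target_edges=edges,
        bin_area_km2=bin_area,
        bin_protected_km2=bin_prot,
    )
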
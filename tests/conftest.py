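import numpy as np
import pandas as pd
import pytest

from equirep import (AnalysisGrid, LandscapeSpec, PlacementScenario,
                     build_cell_table, generate_landscape,
                     generate_protected_network)
from equirep.synthetic import FieldSpec, default_field_specs


def small_spec(seed=11, **kw):
    """A 30x30-cell landscape spanning 3x3 degrees."""
    defaults = dict(lon_min=-65.0, lat_min=-35.0, lon_max=-62.0, lat_max=-32.0,
                    n_territories=2, n_ecoregions=6, seed=seed)
    defaults.update(kw)
    return LandscapeSpec(**defaults)


def noise_human_fields():
    """Field specs whose human variables are trendless smoothed noise.

    Used by planted-driver checks: without shared large-scale trends the five
    human gradients are approximately independent, so a placement bias planted
    on one of them is attributable to that variable alone.
    """
    specs = default_field_specs()
    specs["tourism_attractiveness"] = FieldSpec(0.0, "lon", 0.0, 1.0, 3.0,
                                                log_scale=True)
    specs["distance_to_frontiers"] = FieldSpec(150.0, "lon", 0.0, 60.0, 4.0,
                                               lower_bound=0.0)
    specs["population"] = FieldSpec(4.0, "lat", 0.0, 1.5, 3.0, log_scale=True)
    specs["distance_to_roads"] = FieldSpec(30.0, "lat", 0.0, 12.0, 2.0,
                                           lower_bound=0.0)
    specs["cropland_suitability"] = FieldSpec(50.0, "lon", 0.0, 15.0, 5.0,
                                              lower_bound=0.0)
    return specs


@pytest.fixture(scope="session")
def landscape():
    return generate_landscape(small_spec())


@pytest.fixture(scope="session")
def uniform_cells(landscape):
    """Cell table of a 10% spatially uniform network, all periods."""
    scenario = PlacementScenario(scenario_name="uniform",
                                 total_protected_fraction=0.10, n_units=8)
    records, _ = generate_protected_network(landscape, scenario, seed=5)
    return build_cell_table(landscape, records)


def toy_cell_table(land, protected, values, territory="T1", ecoregion=None,
                   period=2016, **extra_vars):
    """Hand-built tidy cell table for arithmetic checks.

    ``values`` maps variable name -> per-cell values; all arrays share length.
    """
    n = len(land)
    base = {
        "cell_id": np.arange(n),
        "territory": territory if np.isscalar(territory) else territory,
        "ecoregion": ecoregion if ecoregion is not None else ["E1"] * n,
        "period": period,
        "land_km2": np.asarray(land, dtype=float),
        "protected_km2": np.asarray(protected, dtype=float),
    }
    base.update({k: np.asarray(v, dtype=float) for k, v in values.items()})
    base.update(extra_vars)
    return pd.DataFrame(base)
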
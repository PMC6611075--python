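"""Geodesic helpers on the authalic sphere.

All geometries are geographic (longitude/latitude, WGS84 ensemble). Areas are
computed by projecting onto a cylindrical equal-area surface of the authalic
sphere (x = R*lambda, y = R*sin(phi)); planar area there equals spherical
surface area, so a single transform gives consistent areas for cells, protected
polygons and their intersections. For 0.1-degree analysis cells the departure
from ellipsoidal areas is far below analysis noise.
"""

from __future__ import annotations

import numpy as np
import shapely

#: Authalic Earth radius in km (sphere with the WGS84 ellipsoid's surface area).
EARTH_RADIUS_KM = 6371.0072

#: Geographic CRS tag used for mismatch checks; no reprojection is performed.
GEOGRAPHIC_CRS = "EPSG:4326"


def _cea_coords(coords: np.ndarray) -> np.ndarray:
    out = np.empty_like(coords, dtype=float)
    out[:, 0] = np.radians(coords[:, 0]) * EARTH_RADIUS_KM
    out[:, 1] = np.sin(np.radians(coords[:, 1])) * EARTH_RADIUS_KM
    return out


def to_equal_area(geometry):
    """Project a lon/lat geometry (or array of geometries) to equal-area km."""
    return shapely.transform(geometry, _cea_coords)


def geodesic_area_km2(geometry):
    """Spherical surface area in km^2 of a lon/lat geometry (elementwise on arrays)."""
    return shapely.area(to_equal_area(geometry))


def band_cell_area_km2(lat_lo, lat_hi, dlon_deg):
    """Area of a lon/lat rectangle spanning ``dlon_deg`` between two parallels."""
    lat_lo = np.asarray(lat_lo, dtype=float)
    lat_hi = np.asarray(lat_hi, dtype=float)
    return (
        EARTH_RADIUS_KM**2
        * np.radians(dlon_deg)
        * (np.sin(np.radians(lat_hi)) - np.sin(np.radians(lat_lo)))
    )


def circle_polygon(lon: float, lat: float, area_km2: float, n_vertices: int = 64):
    """Circular polygon of the given spherical area centred at (lon, lat).

    The radius is ``sqrt(area/pi)`` (planar approximation); the circle is drawn
    in degrees with the longitudinal axis stretched by 1/cos(lat) so its
    geodesic area matches the request to well under 1% for radii up to ~100 km.
    """
    if area_km2 <= 0:
        raise ValueError(f"circle area must be positive, got {area_km2}")
    radius_km = float(np.sqrt(area_km2 / np.pi))
    km_per_deg_lat = np.pi * EARTH_RADIUS_KM / 180.0
    r_lat = radius_km / km_per_deg_lat
    r_lon = r_lat / np.cos(np.radians(lat))
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    ring = np.column_stack(
        (lon + r_lon * np.cos(theta), lat + r_lat * np.sin(theta))
    )
    return shapely.Polygon(ring)
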
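"""Spherical area and length measures for lon/lat polygons.

All geographic measures in this package are evaluated on the WGS84
authalic sphere (the sphere with the same total surface area as the
WGS84 ellipsoid, R = 6371.0072 km).  Polygon edges are straight lines
in lon/lat degree space; rings are densified before integration so the
measures converge to the exact area/length of the degree-space shape
on the sphere.  Regional areas computed this way are within ~0.5% of
fully ellipsoidal values at mid-latitudes, and using one sphere for
both area and perimeter keeps isoperimetric quantities consistent.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import MultiPolygon, Polygon
from shapely.geometry.base import BaseGeometry

#: WGS84 authalic sphere radius in km.
AUTHALIC_RADIUS_KM = 6371.0071809184747

_DENSIFY_DEG = 0.05  # max segment length (degrees) before integration


def densify_ring(coords: np.ndarray, max_seg_deg: float = _DENSIFY_DEG) -> np.ndarray:
    """Insert vertices so no segment exceeds ``max_seg_deg`` in lon/lat space."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        return coords
    out = [coords[0]]
    for a, b in zip(coords[:-1], coords[1:]):
        seg = np.hypot(*(b - a))
        n = max(1, int(np.ceil(seg / max_seg_deg)))
        for i in range(1, n + 1):
            out.append(a + (b - a) * (i / n))
    return np.asarray(out)


def ring_signed_area_km2(coords: np.ndarray) -> float:
    """Signed spherical area (km^2) of a closed lon/lat ring.

    Green's-theorem form A = R^2 * oint sin(phi) dlambda, evaluated by the
    trapezoid rule on the densified ring.  Counter-clockwise rings are
    positive.
    """
    c = densify_ring(coords)
    lam = np.deg2rad(c[:, 0])
    sphi = np.sin(np.deg2rad(c[:, 1]))
    dlam = np.diff(lam)
    return float(AUTHALIC_RADIUS_KM**2 * np.sum(dlam * (sphi[:-1] + sphi[1:]) / 2.0))


def ring_length_km(coords: np.ndarray) -> float:
    """Great-circle length (km) of a lon/lat polyline, densified first."""
    c = densify_ring(coords)
    lon = np.deg2rad(c[:, 0])
    lat = np.deg2rad(c[:, 1])
    dlat = np.diff(lat)
    dlon = np.diff(lon)
    # haversine on consecutive vertices
    h = np.sin(dlat / 2) ** 2 + np.cos(lat[:-1]) * np.cos(lat[1:]) * np.sin(dlon / 2) ** 2
    return float(AUTHALIC_RADIUS_KM * np.sum(2 * np.arcsin(np.sqrt(np.clip(h, 0, 1)))))


def _check_lon_extent(geom: BaseGeometry) -> None:
    minx, _, maxx, _ = geom.bounds
    if maxx - minx > 180.0 or minx < -180.0 or maxx > 180.0:
        raise ValueError(
            "polygon appears to cross the antimeridian or leave [-180, 180]; not supported"
        )


def polygon_area_perimeter_km(geom: BaseGeometry) -> tuple[float, float]:
    """Geodesic (authalic-sphere) area in km^2 and perimeter in km.

    Holes subtract from area and add to perimeter.  Multipolygon parts sum.
    """
    if geom.is_empty:
        raise ValueError("empty polygon")
    _check_lon_extent(geom)
    if isinstance(geom, Polygon):
        parts = [geom]
    elif isinstance(geom, MultiPolygon):
        parts = list(geom.geoms)
    else:
        raise TypeError(f"expected Polygon or MultiPolygon, got {geom.geom_type}")
    area = 0.0
    perim = 0.0
    for poly in parts:
        ext = np.asarray(poly.exterior.coords)
        area += abs(ring_signed_area_km2(ext))
        perim += ring_length_km(ext)
        for hole in poly.interiors:
            h = np.asarray(hole.coords)
            area -= abs(ring_signed_area_km2(h))
            perim += ring_length_km(h)
    return area, perim


def geodesic_area_km2(geom: BaseGeometry) -> float:
    """Authalic-sphere area (km^2) of a polygon/multipolygon; 0 for empty."""
    if geom.is_empty:
        return 0.0
    return polygon_area_perimeter_km(geom)[0]


def lat_band_cell_area_km2(
    lon_width_deg: float, lat_south_deg: np.ndarray, lat_north_deg: np.ndarray
) -> np.ndarray:
    """Exact sphere area of graticule-aligned cells: R^2 * dlam * (sin N - sin S)."""
    dlam = np.deg2rad(lon_width_deg)
    return AUTHALIC_RADIUS_KM**2 * dlam * (
        np.sin(np.deg2rad(lat_north_deg)) - np.sin(np.deg2rad(lat_south_deg))
    )
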
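"""Range-map geometry: shape metrics, study-area construction, map agreement.

An expert range map is a polygon (or multipolygon) in lon/lat WGS84
delineating where naturalists believe a species occurs.  This module
provides the map-shape metrics used as predictors of map performance
(Polsby–Popper compactness, convex hull score, detailed edge), the
alpha-hull / convex-hull / land-clip construction of a species' study
area, and the Jaccard overlap between two expert maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import MultiPoint, MultiPolygon, Polygon
from shapely.geometry.base import BaseGeometry
from shapely import make_valid
from shapely.ops import unary_union

from .geodesy import geodesic_area_km2, polygon_area_perimeter_km

__all__ = [
    "RangePolygon",
    "MapGeometry",
    "AgreementResult",
    "StudyArea",
    "geodesic_measures",
    "polsby_popper",
    "convex_hull_score",
    "detailed_edge",
    "map_geometry",
    "alpha_hull",
    "build_study_area",
    "expert_agreement",
]


def _repair(geom: BaseGeometry) -> BaseGeometry:
    """Repair invalid (e.g. self-intersecting) geometry; keep polygonal parts only."""
    if geom.is_valid:
        return geom
    fixed = make_valid(geom, method="structure", keep_collapsed=False)
    if fixed.geom_type == "GeometryCollection":
        polys = [g for g in fixed.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        fixed = unary_union(polys) if polys else Polygon()
    return fixed


@dataclass
class RangePolygon:
    """A polygonal range map (or study-area boundary) in lon/lat WGS84.

    Invalid input geometry — routine in digitized expert shapefiles — is
    repaired on construction.  Areas are km^2, perimeters km, measured on
    the WGS84 authalic sphere.
    """

    geom: BaseGeometry
    label: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.geom, BaseGeometry):
            raise TypeError("geom must be a shapely geometry")
        self.geom = _repair(self.geom)

    @classmethod
    def from_coords(cls, exterior: Sequence[Sequence[float]], label: str = "") -> "RangePolygon":
        return cls(Polygon(exterior), label=label)

    @property
    def is_empty(self) -> bool:
        return self.geom.is_empty or geodesic_area_km2(self.geom) == 0.0

    @property
    def area_km2(self) -> float:
        return geodesic_measures(self)[0]

    @property
    def perimeter_km(self) -> float:
        return geodesic_measures(self)[1]


@dataclass(frozen=True)
class MapGeometry:
    """Shape metrics of a range map (predictors of map performance)."""

    polsby_popper: float
    convex_hull_score: float
    detailed_edge: float  # km


@dataclass(frozen=True)
class AgreementResult:
    """Jaccard overlap between two range maps."""

    agreement: float
    intersection_area_km2: float
    union_area_km2: float


@dataclass
class StudyArea:
    """The region S over which a species' maps are evaluated."""

    boundary: RangePolygon
    provenance: dict = field(default_factory=dict)

    @property
    def geom(self) -> BaseGeometry:
        return self.boundary.geom

    @property
    def area_km2(self) -> float:
        return self.boundary.area_km2


def geodesic_measures(poly: RangePolygon) -> tuple[float, float]:
    """Geodesic (area km^2, perimeter km) of a range map.

    Holes count against area and add to perimeter; multipolygon parts sum.
    Raises ValueError for empty or zero-area geometry.
    """
    if poly.geom.is_empty:
        raise ValueError("empty polygon")
    area, perim = polygon_area_perimeter_km(poly.geom)
    if area <= 0.0:
        raise ValueError("empty polygon (zero geodesic area)")
    return area, perim


def polsby_popper(poly: RangePolygon) -> float:
    """Polsby–Popper compactness 4*pi*A/P^2; 1 for a circle, -> 0 for elongate shapes."""
    area, perim = geodesic_measures(poly)
    if perim <= 0.0:
        raise ValueError("zero perimeter")
    score = 4.0 * np.pi * area / perim**2
    if 1.0 < score < 1.0 + 1e-9:  # floating error only
        score = 1.0
    return float(score)


def convex_hull_score(poly: RangePolygon) -> float:
    """Area of the map over the area of its minimum convex polygon, in (0, 1]."""
    area, _ = geodesic_measures(poly)
    hull_area = geodesic_area_km2(poly.geom.convex_hull)
    return float(area / hull_area)


def detailed_edge(poly: RangePolygon) -> float:
    """Area-to-perimeter ratio in km; smaller means more boundary detail."""
    area, perim = geodesic_measures(poly)
    if perim <= 0.0:
        raise ValueError("zero perimeter")
    return float(area / perim)


def map_geometry(poly: RangePolygon) -> MapGeometry:
    """All three shape metrics of a map in one pass."""
    return MapGeometry(
        polsby_popper=polsby_popper(poly),
        convex_hull_score=convex_hull_score(poly),
        detailed_edge=detailed_edge(poly),
    )


def _circumradius(pts: np.ndarray) -> float:
    """Circumradius of a planar triangle (degree units); inf if degenerate."""
    a = np.hypot(*(pts[1] - pts[0]))
    b = np.hypot(*(pts[2] - pts[1]))
    c = np.hypot(*(pts[0] - pts[2]))
    cross = (pts[1][0] - pts[0][0]) * (pts[2][1] - pts[0][1]) - (
        pts[1][1] - pts[0][1]
    ) * (pts[2][0] - pts[0][0])
    area2 = abs(cross)
    if area2 == 0.0:
        return np.inf
    return a * b * c / (2.0 * area2)


def alpha_hull(points: np.ndarray, alpha_deg: float = 8.0, label: str = "alpha hull") -> RangePolygon:
    """Alpha shape of occurrence points in lon/lat degree space.

    A generalization of the convex hull that drops highly distant,
    isolated records and may split into disjoint components.  The
    parameter is the disk radius in decimal degrees: a Delaunay triangle
    is kept iff its circumradius is <= ``alpha_deg`` (the convention of
    the R ``alphahull`` package).  As ``alpha_deg`` grows the result
    converges to the convex hull.  Fewer than 3 non-collinear points fall
    back to a buffered convex hull with a warning.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of lon/lat")
    pts = np.unique(pts, axis=0)

    def _fallback() -> RangePolygon:
        warnings.warn(
            "fewer than 3 non-collinear points: falling back to a buffered convex hull",
            stacklevel=3,
        )
        hull = MultiPoint([tuple(p) for p in pts]).convex_hull
        return RangePolygon(hull.buffer(alpha_deg / 10.0), label=label)

    if len(pts) < 3:
        return _fallback()
    try:
        tri = Delaunay(pts)
    except QhullError:
        return _fallback()
    keep = [
        Polygon(pts[simplex])
        for simplex in tri.simplices
        if _circumradius(pts[simplex]) <= alpha_deg
    ]
    if not keep:
        return _fallback()
    return RangePolygon(unary_union(keep), label=label)


def build_study_area(
    occurrences: np.ndarray | None,
    map_a: RangePolygon | None,
    map_b: RangePolygon | None,
    land: RangePolygon,
    alpha_deg: float = 8.0,
) -> StudyArea:
    """Construct the study area S for one species.

    S = convex_hull( alpha_hull(occurrences) U map_a U map_b ), clipped by
    the land boundary — the spatial union of all data relevant to the
    species, restricted to land.
    """
    parts: list[BaseGeometry] = []
    prov: dict = {"alpha_deg": alpha_deg, "land": land.label or "land"}
    if occurrences is not None and len(occurrences) > 0:
        parts.append(alpha_hull(np.asarray(occurrences), alpha_deg).geom)
        prov["n_occurrences"] = int(len(occurrences))
    for name, m in (("map_a", map_a), ("map_b", map_b)):
        if m is not None and not m.geom.is_empty:
            parts.append(m.geom)
            prov[name] = m.label or name
    if not parts:
        raise ValueError("need occurrences or at least one expert map")
    hull = unary_union(parts).convex_hull
    clipped = hull.intersection(land.geom)
    if clipped.is_empty or geodesic_area_km2(clipped) == 0.0:
        raise ValueError("study area off land")
    return StudyArea(RangePolygon(clipped, label="study area"), provenance=prov)


def expert_agreement(map_a: RangePolygon, map_b: RangePolygon) -> AgreementResult:
    """Jaccard agreement between two expert maps.

    Geodesic area of the intersection over geodesic area of the union:
    1 for identical ranges, 0 for disjoint ones.
    """
    if map_a.geom.is_empty and map_b.geom.is_empty:
        raise ValueError("no ranges to compare")
    inter = map_a.geom.intersection(map_b.geom)
    union = map_a.geom.union(map_b.geom)
    ai = geodesic_area_km2(inter)
    au = geodesic_area_km2(union)
    if au == 0.0:
        raise ValueError("no ranges to compare")
    return AgreementResult(agreement=ai / au, intersection_area_km2=ai, union_area_km2=au)
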
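"""The expert score: proper-scoring-rule deviance of a binary map.

A binary range map y(s) is scored against a continuous occupancy
probability surface p(s) with the Bernoulli log-loss scoring rule

    l(y, p) = -2 [ y log p + (1 - y) log(1 - p) ],

integrated over the study area S by numerical quadrature on a lon/lat
grid (cells weighted by geodesic area).  Normalizing by the deviance of
the null map — the map that covers all of S — gives the deviance-
explained *expert score*

    expert score = 1 - D_expert / D_null,

which is 0 for the null map, at most 1, and negative for a map less
accurate than the null.  Splitting S into the area inside the map (I)
and outside it (O) decomposes D_expert into a commission term (inside:
claiming unsuitable landscape) and an omission term (outside: excluding
suitable landscape); scaled by D_null these satisfy
expert score = 1 - (scaled_inside + scaled_outside) identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely import contains_xy

from .geodesy import lat_band_cell_area_km2
from .geometry import RangePolygon, StudyArea

__all__ = [
    "GridSpec",
    "BinaryMapGrid",
    "ProbabilitySurface",
    "DevianceResult",
    "make_grid",
    "rasterize_map",
    "occupancy_probability",
    "scoring_rule",
    "total_deviance",
    "expert_score",
]

DEFAULT_RESOLUTION_ARCMIN = 10.0
DEFAULT_CLAMP_EPS = 1e-10


@dataclass
class GridSpec:
    """An axis-aligned lon/lat grid over a study area.

    The grid origin is snapped to multiples of the resolution so cells
    align with the graticule.  Cells are half-open [west, east) x
    [south, north); a cell belongs to S iff its center lies inside the
    study-area polygon.  Cell areas are geodesic (latitude-dependent),
    in km^2.
    """

    resolution_arcmin: float
    origin_lon: float  # west edge of column 0
    origin_lat: float  # south edge of row 0
    n_cols: int
    n_rows: int
    mask: np.ndarray = field(repr=False)  # (n_rows, n_cols) bool
    cell_areas_km2: np.ndarray = field(repr=False)  # (n_rows, n_cols)

    @property
    def resolution_deg(self) -> float:
        return self.resolution_arcmin / 60.0

    @property
    def lon_centers(self) -> np.ndarray:
        r = self.resolution_deg
        return self.origin_lon + r * (np.arange(self.n_cols) + 0.5)

    @property
    def lat_centers(self) -> np.ndarray:
        r = self.resolution_deg
        return self.origin_lat + r * (np.arange(self.n_rows) + 0.5)

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.lon_centers, self.lat_centers)

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    @property
    def masked_area_km2(self) -> float:
        return float(self.cell_areas_km2[self.mask].sum())

    def cell_index(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the half-open cell containing each point."""
        r = self.resolution_deg
        col = np.floor((np.asarray(lon) - self.origin_lon) / r).astype(int)
        row = np.floor((np.asarray(lat) - self.origin_lat) / r).astype(int)
        return row, col

    def same_shape(self, other: "GridSpec") -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and np.isclose(self.origin_lon, other.origin_lon)
            and np.isclose(self.origin_lat, other.origin_lat)
            and np.isclose(self.resolution_arcmin, other.resolution_arcmin)
        )


@dataclass
class BinaryMapGrid:
    """A rasterized binary map y on a GridSpec (1 = indicated occupied)."""

    y: np.ndarray  # (n_rows, n_cols) of {0,1}
    grid: GridSpec


@dataclass
class ProbabilitySurface:
    """Per-cell occupancy probability p = 1 - exp(-lambda_bar), clamped.

    ``lambda_bar`` is the integrated point-process intensity per cell
    (expected occurrence count); ``clamp_eps`` bounds p away from {0, 1}
    so the scoring rule stays finite, with the number of clamped cells
    recorded.
    """

    p: np.ndarray  # (n_rows, n_cols)
    lambda_bar: np.ndarray
    clamp_eps: float = DEFAULT_CLAMP_EPS
    n_clamped: int = 0


@dataclass(frozen=True)
class DevianceResult:
    """Expert-score decomposition for one map on one surface."""

    deviance_expert: float
    deviance_null: float
    deviance_inside: float
    deviance_outside: float
    scaled_inside: float
    scaled_outside: float
    expert_score: float
    discretization_bound: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "deviance_expert": self.deviance_expert,
            "deviance_null": self.deviance_null,
            "deviance_inside": self.deviance_inside,
            "deviance_outside": self.deviance_outside,
            "scaled_inside": self.scaled_inside,
            "scaled_outside": self.scaled_outside,
            "expert_score": self.expert_score,
            "discretization_bound": self.discretization_bound,
        }


def make_grid(
    study_area: StudyArea, resolution_arcmin: float = DEFAULT_RESOLUTION_ARCMIN
) -> GridSpec:
    """Lay a graticule-aligned grid over a study area and mask it.

    Raises ValueError if the resolution is non-positive or no cell
    center falls inside the study area ("grid too coarse").
    """
    if resolution_arcmin <= 0:
        raise ValueError("resolution must be positive")
    geom = study_area.geom
    if geom.is_empty:
        raise ValueError("empty study area")
    r = resolution_arcmin / 60.0
    minx, miny, maxx, maxy = geom.bounds
    origin_lon = np.floor(minx / r) * r
    origin_lat = np.floor(miny / r) * r
    n_cols = int(np.ceil((maxx - origin_lon) / r - 1e-12))
    n_rows = int(np.ceil((maxy - origin_lat) / r - 1e-12))
    n_cols = max(n_cols, 1)
    n_rows = max(n_rows, 1)
    lon_c = origin_lon + r * (np.arange(n_cols) + 0.5)
    lat_c = origin_lat + r * (np.arange(n_rows) + 0.5)
    gx, gy = np.meshgrid(lon_c, lat_c)
    mask = contains_xy(geom, gx.ravel(), gy.ravel()).reshape(n_rows, n_cols)
    if not mask.any():
        raise ValueError("grid too coarse: no cell center falls inside the study area")
    lat_s = origin_lat + r * np.arange(n_rows)
    band = lat_band_cell_area_km2(r, lat_s, lat_s + r)  # (n_rows,)
    areas = np.repeat(band[:, None], n_cols, axis=1)
    return GridSpec(
        resolution_arcmin=float(resolution_arcmin),
        origin_lon=float(origin_lon),
        origin_lat=float(origin_lat),
        n_cols=n_cols,
        n_rows=n_rows,
        mask=mask,
        cell_areas_km2=areas,
    )


def rasterize_map(poly: RangePolygon, grid: GridSpec) -> BinaryMapGrid:
    """y_j = 1 iff the cell center lies inside the map polygon."""
    if poly.geom.is_empty:
        return BinaryMapGrid(np.zeros((grid.n_rows, grid.n_cols), dtype=np.int8), grid)
    gx, gy = grid.center_mesh()
    inside = contains_xy(poly.geom, gx.ravel(), gy.ravel())
    return BinaryMapGrid(inside.reshape(grid.n_rows, grid.n_cols).astype(np.int8), grid)


def occupancy_probability(
    lambda_bar: np.ndarray, clamp_eps: float = DEFAULT_CLAMP_EPS
) -> ProbabilitySurface:
    """p_j = 1 - exp(-lambda_bar_j), clamped into [eps, 1-eps]."""
    lb = np.asarray(lambda_bar, dtype=float)
    if np.any(lb < 0):
        raise ValueError("negative integrated intensity")
    if not (0 < clamp_eps < 0.5):
        raise ValueError("clamp_eps must be in (0, 0.5)")
    p = -np.expm1(-lb)
    n_clamped = int(np.sum((p < clamp_eps) | (p > 1 - clamp_eps)))
    p = np.clip(p, clamp_eps, 1 - clamp_eps)
    return ProbabilitySurface(p=p, lambda_bar=lb, clamp_eps=clamp_eps, n_clamped=n_clamped)


def scoring_rule(y, p):
    """Bernoulli log-loss l(y, p) = -2[y log p + (1-y) log(1-p)], elementwise.

    A proper scoring rule: its expectation under the true occupancy
    probability is minimized by predicting that probability.  Requires
    p strictly inside (0, 1) — clamping happens upstream.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly in (0, 1); clamp first")
    return -2.0 * (y * np.log(p) + (1.0 - y) * np.log1p(-p))


def total_deviance(
    binary: BinaryMapGrid, surface: ProbabilitySurface, grid: GridSpec
) -> float:
    """Quadrature deviance: sum over masked cells of l(y_j, p_j) * a_j."""
    if not binary.grid.same_shape(grid):
        raise ValueError("binary map grid does not match the quadrature grid")
    if surface.p.shape != (grid.n_rows, grid.n_cols):
        raise ValueError("surface shape does not match the grid")
    m = grid.mask
    l = scoring_rule(binary.y[m], surface.p[m])
    return float(np.sum(l * grid.cell_areas_km2[m]))


def _boundary_bound(
    y: np.ndarray, l1: np.ndarray, l0: np.ndarray, grid: GridSpec, d_null: float
) -> float:
    """Bound on the expert-score error from boundary-cell assignment.

    Boundary cells are masked cells whose y differs from a rook
    neighbour (also masked); re-assigning such a cell changes the expert
    deviance by a_j * |l(1,p_j) - l(0,p_j)|.
    """
    m = grid.mask
    diff = np.zeros_like(m)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        ys = np.roll(y, shift, axis=axis)
        ms = np.roll(m, shift, axis=axis)
        edge = np.zeros_like(m)
        if axis == 0:
            if shift == 1:
                edge[0, :] = True
            else:
                edge[-1, :] = True
        else:
            if shift == 1:
                edge[:, 0] = True
            else:
                edge[:, -1] = True
        diff |= m & ms & ~edge & (ys != y)
    delta = np.abs(l1 - l0) * grid.cell_areas_km2
    return float(delta[diff].sum() / d_null)


def expert_score(
    range_map: RangePolygon,
    surface: ProbabilitySurface,
    study_area: StudyArea,
    grid: GridSpec,
) -> DevianceResult:
    """Score an expert map against an occupancy surface over a study area.

    The null map z covers every masked cell; the expert map is clipped
    to the study area (with a warning if it extends beyond).  Returns
    the full deviance decomposition.
    """
    geom = range_map.geom
    if not geom.is_empty:
        outside = geom.difference(study_area.geom)
        if not outside.is_empty and outside.area > 1e-12 * max(geom.area, 1e-300):
            warnings.warn("expert map extends beyond the study area; clipping", stacklevel=2)
            geom = geom.intersection(study_area.geom)
    clipped = RangePolygon(geom, label=range_map.label)
    binary = rasterize_map(clipped, grid)

    m = grid.mask
    p = surface.p
    if p.shape != m.shape:
        raise ValueError("surface shape does not match the grid")
    if np.all(p[m] >= 1 - 2 * surface.clamp_eps):
        raise ValueError("degenerate surface: p at the upper clamp everywhere")

    a = grid.cell_areas_km2
    l1 = scoring_rule(np.ones_like(p), p)
    l0 = scoring_rule(np.zeros_like(p), p)
    d_null = float((l1 * a)[m].sum())
    if d_null == 0.0:
        raise ValueError("degenerate surface: null deviance is zero")

    inside = m & (binary.y == 1)
    outside = m & (binary.y == 0)
    d_in = float((l1 * a)[inside].sum())
    d_out = float((l0 * a)[outside].sum())
    d_exp = d_in + d_out
    bound = _boundary_bound(binary.y, l1, l0, grid, d_null)
    return DevianceResult(
        deviance_expert=d_exp,
        deviance_null=d_null,
        deviance_inside=d_in,
        deviance_outside=d_out,
        scaled_inside=d_in / d_null,
        scaled_outside=d_out / d_null,
        expert_score=1.0 - d_exp / d_null,
        discretization_bound=bound,
    )
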
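"""Synthetic scenarios: intensity surfaces, IPP point patterns, expert maps.

Everything the scoring pipeline consumes can be generated here without
external data: a parametric intensity surface (sum of Gaussian kernels
over a baseline, or a log-linear covariate model), a seeded draw from
the implied inhomogeneous Poisson process, and two stylized expert-map
generators that emulate the two philosophies real range maps follow —
a "tight" map that traces only high-suitability patches (maps drawn
around confirmed breeding areas) and a "generous" map that convexifies
and dilates the suitable region (maps that sweep in every area a
species ever reaches).  All draws are reproducible from one integer
seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from shapely.geometry import box
from shapely.ops import unary_union

from .geometry import RangePolygon, StudyArea
from .scoring import GridSpec, ProbabilitySurface, make_grid, occupancy_probability

__all__ = [
    "MapStyle",
    "Scenario",
    "random_scenario",
    "make_intensity",
    "simulate_ipp",
    "make_expert_map",
    "TIGHT_STYLE",
    "GENEROUS_STYLE",
]


@dataclass(frozen=True)
class MapStyle:
    """Parameters of a stylized expert-map drawing rule."""

    threshold: float  # keep cells with p >= threshold
    dilation_deg: float = 0.0
    simplify_deg: float = 0.0
    convexify: bool = False


#: Traces high-suitability cells with no smoothing: detailed, concave maps.
TIGHT_STYLE = MapStyle(threshold=0.5)
#: Sweeps in all marginally suitable area, convexified and dilated:
#: compact blob-like maps with heavy commission.
GENEROUS_STYLE = MapStyle(threshold=0.05, dilation_deg=0.5, convexify=True)


@dataclass
class Scenario:
    """A fully seeded synthetic study: region, intensity, map styles.

    ``kernels`` is a list of (lon, lat, amplitude, length_deg) tuples;
    amplitude is intensity per km^2 at the kernel center, length the
    Gaussian scale in degrees.  ``baseline`` is a uniform background
    intensity per km^2.
    """

    seed: int
    region: list[list[float]]  # exterior ring lon/lat
    baseline: float = 1e-5
    kernels: list[tuple[float, float, float, float]] = field(default_factory=list)
    tight: MapStyle = TIGHT_STYLE
    generous: MapStyle = GENEROUS_STYLE

    def region_polygon(self) -> RangePolygon:
        return RangePolygon.from_coords(self.region, label=f"scenario-{self.seed}")

    def study_area(self) -> StudyArea:
        return StudyArea(self.region_polygon(), provenance={"scenario_seed": self.seed})

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Scenario":
        d = json.loads(text)
        d["tight"] = MapStyle(**d["tight"])
        d["generous"] = MapStyle(**d["generous"])
        d["kernels"] = [tuple(k) for k in d["kernels"]]
        return cls(**d)


def random_scenario(
    seed: int,
    lon0: float = -100.0,
    lat0: float = 35.0,
    width_deg: float = 10.0,
    n_kernels: tuple[int, int] = (4, 7),
    amplitude: tuple[float, float] = (0.005, 0.015),
    length_deg: tuple[float, float] = (0.6, 1.2),
    baseline: float = 1e-5,
) -> Scenario:
    """A patchy-suitability scenario: scattered Gaussian habitat patches
    over a low uniform background, in a square region.

    Defaults give per-cell occupancy peaks of ~0.9 in patches against a
    background of ~0.003 at a 10-arc-minute grid — the regime of a
    habitat-specialist species with a few core areas inside a much
    larger study region.
    """
    rng = np.random.default_rng(seed)
    nk = int(rng.integers(n_kernels[0], n_kernels[1] + 1))
    margin = 0.15 * width_deg
    kernels = [
        (
            float(rng.uniform(lon0 + margin, lon0 + width_deg - margin)),
            float(rng.uniform(lat0 + margin, lat0 + width_deg - margin)),
            float(rng.uniform(*amplitude)),
            float(rng.uniform(*length_deg)),
        )
        for _ in range(nk)
    ]
    region = [
        [lon0, lat0],
        [lon0 + width_deg, lat0],
        [lon0 + width_deg, lat0 + width_deg],
        [lon0, lat0 + width_deg],
        [lon0, lat0],
    ]
    return Scenario(seed=seed, region=region, baseline=baseline, kernels=kernels)


def make_intensity(scenario: Scenario, grid: GridSpec) -> np.ndarray:
    """Per-cell intensity lambda (per km^2) on the grid: baseline plus
    Gaussian kernels evaluated at cell centers in degree space."""
    if scenario.baseline < 0:
        raise ValueError("baseline intensity must be non-negative")
    gx, gy = grid.center_mesh()
    lam = np.full(gx.shape, float(scenario.baseline))
    for lon, lat, amp, length in scenario.kernels:
        if amp <= 0:
            raise ValueError("kernel amplitude must be positive")
        if length <= 0:
            raise ValueError("kernel length scale must be positive")
        d2 = (gx - lon) ** 2 + (gy - lat) ** 2
        lam += amp * np.exp(-d2 / (2.0 * length**2))
    return lam


def intensity_to_surface(
    lam: np.ndarray, grid: GridSpec, clamp_eps: float = 1e-10
) -> ProbabilitySurface:
    """Midpoint-rule integrated intensity and occupancy probability per cell."""
    return occupancy_probability(lam * grid.cell_areas_km2, clamp_eps=clamp_eps)


def simulate_ipp(lambda_bar: np.ndarray, grid: GridSpec, seed: int) -> np.ndarray:
    """Draw one point pattern from the IPP with per-cell mass lambda_bar.

    N ~ Poisson(sum of masses over masked cells); cells are drawn
    multinomially proportional to mass; positions are uniform within
    the cell.  Deterministic given the seed.  Returns an (N, 2) lon/lat
    array (empty, with a warning from the caller's view, if total mass
    is zero).
    """
    rng = np.random.default_rng(seed)
    m = grid.mask
    mass = np.where(m, lambda_bar, 0.0).ravel()
    if np.any(~np.isfinite(mass)):
        raise ValueError("non-finite intensity mass")
    total = mass.sum()
    if total <= 0:
        import warnings

        warnings.warn("total intensity mass is zero; no points simulated", stacklevel=2)
        return np.empty((0, 2))
    n = int(rng.poisson(total))
    if n == 0:
        return np.empty((0, 2))
    cells = rng.choice(len(mass), size=n, p=mass / total)
    rows, cols = np.unravel_index(cells, (grid.n_rows, grid.n_cols))
    r = grid.resolution_deg
    lon = grid.origin_lon + (cols + rng.uniform(0, 1, size=n)) * r
    lat = grid.origin_lat + (rows + rng.uniform(0, 1, size=n)) * r
    return np.column_stack([lon, lat])


def make_expert_map(
    surface: ProbabilitySurface, grid: GridSpec, style: MapStyle, label: str = ""
) -> RangePolygon:
    """Draw a stylized expert map from an occupancy surface.

    Cells with p >= threshold (inside the mask) are polygonized and
    unioned; the result is optionally replaced by its convex hull,
    dilated, and simplified.  Raises if no cell passes the threshold.
    """
    if not (0.0 < style.threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    keep = grid.mask & (surface.p >= style.threshold)
    if not keep.any():
        raise ValueError("no suitable cells above the threshold")
    r = grid.resolution_deg
    rows, cols = np.nonzero(keep)
    boxes = [
        box(
            grid.origin_lon + c * r,
            grid.origin_lat + w * r,
            grid.origin_lon + (c + 1) * r,
            grid.origin_lat + (w + 1) * r,
        )
        for w, c in zip(rows, cols)
    ]
    geom = unary_union(boxes)
    if style.convexify:
        geom = geom.convex_hull
    if style.dilation_deg > 0:
        geom = geom.buffer(style.dilation_deg)
    if style.simplify_deg > 0:
        geom = geom.simplify(style.simplify_deg)
    return RangePolygon(geom, label=label or ("convex" if style.convexify else "detailed"))


def scenario_fixture(scenario: Scenario, resolution_arcmin: float = 10.0):
    """Build the full fixture bundle for a scenario.

    Returns (study_area, grid, surface, points, tight_map, generous_map).
    """
    sa = scenario.study_area()
    grid = make_grid(sa, resolution_arcmin)
    lam = make_intensity(scenario, grid)
    surface = intensity_to_surface(lam, grid)
    points = simulate_ipp(surface.lambda_bar, grid, seed=scenario.seed)
    tight = make_expert_map(surface, grid, scenario.tight, label="tight")
    generous = make_expert_map(surface, grid, scenario.generous, label="generous")
    return sa, grid, surface, points, tight, generous
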
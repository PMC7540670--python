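"""File formats and run configuration.

Polygons travel as GeoJSON (RFC 7946, lon/lat WGS84); occurrence points
as CSV with ``lon,lat[,species]`` columns; probability surfaces as
long-format CSV with ``lon,lat,lambda_bar,p`` rows for masked cells
(the grid is recovered from the regular cell-center lattice); model
and score reports as JSON with the run configuration echoed for
provenance.  CSV dialect: UTF-8, comma-separated, header row, '.'
decimal.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .geodesy import lat_band_cell_area_km2
from .geometry import RangePolygon, StudyArea
from .scoring import (
    DEFAULT_CLAMP_EPS,
    DEFAULT_RESOLUTION_ARCMIN,
    GridSpec,
    ProbabilitySurface,
    occupancy_probability,
)

__all__ = [
    "RunConfig",
    "read_geojson",
    "write_geojson",
    "read_points_csv",
    "write_points_csv",
    "read_surface_csv",
    "write_surface_csv",
    "write_report",
]


@dataclass
class RunConfig:
    """Pipeline defaults; echoed into every output for provenance."""

    resolution_arcmin: float = DEFAULT_RESOLUTION_ARCMIN
    alpha_deg: float = 8.0
    clamp_eps: float = DEFAULT_CLAMP_EPS
    importance_threshold: float = 0.8
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_dict(self) -> dict:
        return asdict(self)


def read_geojson(path: str | Path, label: str | None = None) -> RangePolygon:
    """Read the first polygonal geometry from a GeoJSON file."""
    data = json.loads(Path(path).read_text())
    crs = data.get("crs", {}).get("properties", {}).get("name", "")
    if crs and "4326" not in crs and "CRS84" not in crs:
        raise ValueError(f"unsupported CRS {crs!r}: polygons must be lon/lat EPSG:4326")
    if data.get("type") == "FeatureCollection":
        feats = data.get("features", [])
        if not feats:
            raise ValueError("empty FeatureCollection")
        geom = shape(feats[0]["geometry"])
        props = feats[0].get("properties") or {}
        name = props.get("label", "")
    elif data.get("type") == "Feature":
        geom = shape(data["geometry"])
        name = (data.get("properties") or {}).get("label", "")
    else:
        geom = shape(data)
        name = ""
    if geom.geom_type not in ("Polygon", "MultiPolygon"):
        raise ValueError(f"expected a polygonal geometry, got {geom.geom_type}")
    return RangePolygon(geom, label=label if label is not None else name)


def write_geojson(path: str | Path, poly: RangePolygon) -> None:
    feature = {
        "type": "Feature",
        "properties": {"label": poly.label},
        "geometry": mapping(poly.geom),
    }
    doc = {"type": "FeatureCollection", "features": [feature]}
    Path(path).write_text(json.dumps(doc, sort_keys=True) + "\n")


def read_points_csv(path: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    """Occurrence CSV with lon,lat[,species] columns -> (points, full table)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "lon" not in cols or "lat" not in cols:
        raise ValueError("points CSV must have 'lon' and 'lat' columns")
    pts = df[[cols["lon"], cols["lat"]]].to_numpy(dtype=float)
    if np.any(~np.isfinite(pts)):
        raise ValueError("non-finite coordinates in points CSV")
    return pts, df


def write_points_csv(path: str | Path, points: np.ndarray) -> None:
    pd.DataFrame(np.asarray(points, dtype=float), columns=["lon", "lat"]).to_csv(
        path, index=False, float_format="%.10g"
    )


def write_surface_csv(path: str | Path, grid: GridSpec, surface: ProbabilitySurface) -> None:
    """Long-format surface CSV: one row per masked cell."""
    m = grid.mask
    gx, gy = grid.center_mesh()
    pd.DataFrame(
        {
            "lon": gx[m],
            "lat": gy[m],
            "lambda_bar": surface.lambda_bar[m],
            "p": surface.p[m],
        }
    ).to_csv(path, index=False, float_format="%.12g")


def read_surface_csv(
    path: str | Path, clamp_eps: float = DEFAULT_CLAMP_EPS
) -> tuple[GridSpec, ProbabilitySurface]:
    """Rebuild the grid and surface from a long-format surface CSV.

    The resolution is inferred from the regular cell-center lattice; the
    mask is the set of cells present in the file.
    """
    df = pd.read_csv(path)
    for c in ("lon", "lat", "lambda_bar"):
        if c not in df.columns:
            raise ValueError(f"surface CSV missing column '{c}'")
    lons = np.sort(df["lon"].unique())
    lats = np.sort(df["lat"].unique())
    steps = np.concatenate([np.diff(lons), np.diff(lats)])
    steps = steps[steps > 1e-9]
    if len(steps) == 0:
        raise ValueError("cannot infer grid resolution from a single cell")
    r = float(steps.min())
    origin_lon = float(lons[0] - r / 2)
    origin_lat = float(lats[0] - r / 2)
    # snap origin to the graticule
    origin_lon = round(origin_lon / r) * r
    origin_lat = round(origin_lat / r) * r
    col = np.rint((df["lon"].to_numpy() - origin_lon) / r - 0.5).astype(int)
    row = np.rint((df["lat"].to_numpy() - origin_lat) / r - 0.5).astype(int)
    n_cols = int(col.max()) + 1
    n_rows = int(row.max()) + 1
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    mask[row, col] = True
    lam = np.zeros((n_rows, n_cols))
    lam[row, col] = df["lambda_bar"].to_numpy(dtype=float)
    lat_s = origin_lat + r * np.arange(n_rows)
    band = lat_band_cell_area_km2(r, lat_s, lat_s + r)
    grid = GridSpec(
        resolution_arcmin=r * 60.0,
        origin_lon=origin_lon,
        origin_lat=origin_lat,
        n_cols=n_cols,
        n_rows=n_rows,
        mask=mask,
        cell_areas_km2=np.repeat(band[:, None], n_cols, axis=1),
    )
    return grid, occupancy_probability(lam, clamp_eps=clamp_eps)


def write_report(path: str | Path, payload: dict, config: RunConfig | None = None) -> None:
    """JSON report with the run configuration echoed for provenance."""
    doc = dict(payload)
    if config is not None:
        doc["config"] = config.to_dict()
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
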
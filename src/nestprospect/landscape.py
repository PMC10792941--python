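"""Landcover rasters, distance-to-feature surfaces, and covariate extraction.

Landcover is a single-band integer raster on square 30-m cells with a
six-class legend (water, pine, hardwood, mixed pine-hardwood, open
treeless, shrub/scrub).  Rasters are stored as ESRI ASCII grid text with a
JSON legend sidecar — the same semantics as a georeferenced GeoTIFF (grid,
origin, cell size) in a plain-text container.  Distance surfaces hold, at
each cell center, the planar Euclidean distance to the nearest cell center
of the target class, computed with an exact Euclidean distance transform;
road distances are point-to-segment against vector polylines.

Grid convention: row 0 is the southernmost row; cell (i, j) has its center
at ``(x0 + (j + 0.5) * cell, y0 + (i + 0.5) * cell)`` with (x0, y0) the
lower-left corner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import distance_transform_edt

CLASS_NAMES = ["water", "pine", "hardwood", "mixed", "open", "shrub"]
DEFAULT_LEGEND = {i + 1: name for i, name in enumerate(CLASS_NAMES)}


class LandcoverError(ValueError):
    pass


@dataclass
class LandcoverRaster:
    grid: np.ndarray  # 2-D int array, row 0 = south
    origin: tuple[float, float]  # lower-left corner (x0, y0), meters
    cell_size: float = 30.0
    legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        codes = np.unique(self.grid)
        missing = [int(c) for c in codes if int(c) not in self.legend]
        if missing:
            raise LandcoverError(f"cell codes not in legend: {missing}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.grid.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return xs, ys

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        j = np.floor((np.asarray(x, float) - self.origin[0]) / self.cell_size).astype(int)
        i = np.floor((np.asarray(y, float) - self.origin[1]) / self.cell_size).astype(int)
        return i, j

    def contains(self, x, y) -> np.ndarray:
        i, j = self.cell_index(x, y)
        ny, nx = self.grid.shape
        return (i >= 0) & (i < ny) & (j >= 0) & (j < nx)


def write_ascii_grid(raster: LandcoverRaster, path, legend_path=None) -> None:
    """ESRI ASCII grid (rows written north to south) plus JSON legend sidecar."""
    ny, nx = raster.grid.shape
    header = (f"ncols {nx}\nnrows {ny}\nxllcorner {raster.origin[0]:.3f}\n"
              f"yllcorner {raster.origin[1]:.3f}\ncellsize {raster.cell_size:.3f}\n"
              f"NODATA_value -9999\n")
    body = "\n".join(" ".join(str(int(v)) for v in row) for row in raster.grid[::-1])
    Path(path).write_text(header + body + "\n")
    if legend_path is not None:
        Path(legend_path).write_text(json.dumps({str(k): v for k, v in raster.legend.items()}, indent=1))


def read_ascii_grid(path, legend_path=None) -> LandcoverRaster:
    lines = Path(path).read_text().splitlines()
    hdr = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
        k, v = lines[i].split()
        hdr[k.lower()] = float(v)
        i += 1
    grid = np.array([[int(float(v)) for v in ln.split()] for ln in lines[i:] if ln.strip()])
    grid = grid[::-1]  # file is north-to-south; internal row 0 is south
    legend = dict(DEFAULT_LEGEND)
    if legend_path is not None:
        legend = {int(k): v for k, v in json.loads(Path(legend_path).read_text()).items()}
    return LandcoverRaster(grid, (hdr["xllcorner"], hdr["yllcorner"]), hdr["cellsize"], legend)


def reclass_landcover(raster: LandcoverRaster, mapping: dict[int, int],
                      legend: dict[int, str] | None = None) -> LandcoverRaster:
    """Recode raw cell codes into the analysis legend (surjective merge).

    ``mapping`` must cover every code present in the raster; unmapped codes
    raise listing the offenders.  Cell count is preserved exactly.
    """
    codes = np.unique(raster.grid)
    unmapped = [int(c) for c in codes if int(c) not in mapping]
    if unmapped:
        raise LandcoverError(f"reclass mapping missing raw codes: {unmapped}")
    lut = np.zeros(int(codes.max()) + 1, dtype=int)
    for k, v in mapping.items():
        if k <= codes.max():
            lut[k] = v
    return LandcoverRaster(lut[raster.grid], raster.origin, raster.cell_size,
                           legend or dict(DEFAULT_LEGEND))


def distance_surface(raster: LandcoverRaster, target_class: int) -> np.ndarray:
    """Exact Euclidean distance (meters) from every cell center to the
    nearest cell center of ``target_class``; all-inf when absent."""
    target = raster.grid == target_class
    if not target.any():
        import warnings

        warnings.warn(f"target class {target_class} absent from raster; all-inf surface")
        return np.full(raster.grid.shape, np.inf)
    return distance_transform_edt(~target) * raster.cell_size


def roads_distance_surface(raster: LandcoverRaster, roads) -> np.ndarray:
    """Distance (meters) from each cell center to the nearest road polyline."""
    xs, ys = raster.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    pts = shapely.points(gx.ravel(), gy.ravel())
    merged = shapely.union_all([shapely.LineString(r) if not isinstance(r, shapely.Geometry) else r
                                for r in roads])
    return shapely.distance(pts, merged).reshape(raster.grid.shape)


def build_surfaces(raster: LandcoverRaster, roads=None) -> dict[str, np.ndarray]:
    """One distance surface per landcover class (``dist_<name>``) plus roads."""
    surfaces = {f"dist_{name}": distance_surface(raster, code)
                for code, name in sorted(raster.legend.items())}
    if roads is not None:
        surfaces["dist_road"] = roads_distance_surface(raster, roads)
    return surfaces


def extract_covariates(points: np.ndarray, raster: LandcoverRaster,
                       surfaces: dict[str, np.ndarray], nest_xy=None) -> pd.DataFrame:
    """Covariate vector per point: containing-cell lookup on each distance
    surface, plus point-to-point distance to the nest.

    Points outside the raster extent get NaN covariates and an error note
    rather than aborting the extraction.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    inside = raster.contains(pts[:, 0], pts[:, 1])
    i, j = raster.cell_index(pts[:, 0], pts[:, 1])
    out = {}
    for name, surf in surfaces.items():
        v = np.full(len(pts), np.nan)
        v[inside] = surf[i[inside], j[inside]]
        out[name] = v
    df = pd.DataFrame(out)
    if nest_xy is not None:
        nest = np.asarray(nest_xy, float)
        df.insert(0, "dist_nest", np.hypot(pts[:, 0] - nest[0], pts[:, 1] - nest[1]))
    df["error"] = np.where(inside, "", "outside raster extent")
    return df


def roads_to_geojson(roads) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature",
             "geometry": json.loads(shapely.to_geojson(
                 r if isinstance(r, shapely.Geometry) else shapely.LineString(r))),
             "properties": {"road_id": k}}
            for k, r in enumerate(roads)
        ],
    }


def roads_from_geojson(obj: dict) -> list:
    return [shapely.from_geojson(json.dumps(f["geometry"])) for f in obj["features"]]
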
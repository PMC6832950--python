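"""Minimal geospatial containers and file I/O.

Rasters are north-up regular grids with an affine origin/cell-size
transform, stored as GeoTIFF via tifffile (ModelPixelScale +
ModelTiepoint tags).  County polygons travel as GeoJSON handled with
shapely.  This is deliberately small: the pipeline needs cell-center
coordinates, point-in-polygon tests and nearest-cell sampling — nothing
more.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
import shapely.geometry as sgeom
from shapely.validation import make_valid
import tifffile

__all__ = ["Raster", "read_geotiff", "write_geotiff", "read_county_polygons", "write_county_polygons"]

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


@dataclass
class Raster:
    """A single-band north-up grid.

    ``origin`` is the (x, y) of the *top-left corner* of the top-left
    cell; ``cell`` the positive cell size (square cells).  Row index
    grows southward.
    """

    data: np.ndarray  # 2-D
    origin: tuple[float, float]
    cell: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, each shaped like data."""
        ny, nx = self.data.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nx) + 0.5) * self.cell
        ys = y0 - (np.arange(ny) + 0.5) * self.cell
        return np.meshgrid(xs, ys)

    def sample_nearest(self, x: np.ndarray, y: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Value of the cell containing each (x, y) point; `fill` outside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell).astype(int)
        row = np.floor((y0 - y) / self.cell).astype(int)
        ny, nx = self.data.shape
        inside = (col >= 0) & (col < nx) & (row >= 0) & (row < ny)
        out = np.full(x.shape, fill, dtype=float)
        out[inside] = self.data[row[inside], col[inside]]
        return out


def write_geotiff(path: str | Path, raster: Raster) -> None:
    x0, y0 = raster.origin
    tags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (raster.cell, raster.cell, 0.0), True),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0), True),
    ]
    tifffile.imwrite(path, raster.data, extratags=tags)


def read_geotiff(path: str | Path) -> Raster:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        try:
            scale = tags[_MODEL_PIXEL_SCALE].value
            tie = tags[_MODEL_TIEPOINT].value
        except KeyError as exc:
            raise ValueError(f"{path}: missing georeferencing tags") from exc
    return Raster(data=data, origin=(float(tie[3]), float(tie[4])), cell=float(scale[0]))


def read_county_polygons(path: str | Path, id_field: str = "county_id") -> dict[str, sgeom.base.BaseGeometry]:
    """Load county polygons from GeoJSON; repairs invalid rings, rejects
    duplicates and geometries that cannot be made valid."""
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    out: dict[str, sgeom.base.BaseGeometry] = {}
    for i, feat in enumerate(feats):
        props = feat.get("properties") or {}
        if id_field not in props:
            raise ValueError(f"feature {i}: missing id field {id_field!r}")
        cid = str(props[id_field])
        if cid in out:
            raise ValueError(f"duplicate county id {cid!r}")
        geom = sgeom.shape(feat["geometry"])
        if not geom.is_valid:
            geom = make_valid(geom)
            if not geom.is_valid or geom.is_empty:
                raise ValueError(f"county {cid!r}: geometry invalid and unrepairable")
        out[cid] = geom
    return out


def write_county_polygons(path: str | Path, polygons: dict[str, sgeom.base.BaseGeometry],
                          id_field: str = "county_id") -> None:
    feats = [
        {"type": "Feature", "properties": {id_field: cid}, "geometry": sgeom.mapping(geom)}
        for cid, geom in polygons.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
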
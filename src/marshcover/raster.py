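"""Lightweight georeferenced raster containers.

Rasters live in a planar metric frame with the origin at the study
south-west corner, x increasing east and y increasing north.  Row 0 is the
*northernmost* row (image convention), so the pixel centre of ``(row, col)``
is ``(x0 + (col + 0.5) * gsd, y_top - (row + 0.5) * gsd)``.

Pixel membership everywhere in the package uses the half-open rule: a point
with local coordinate ``u`` falls in pixel ``floor(u / gsd)``, left/top edge
inclusive.  Class rasters are uint8 with labels ``BARREN=0``, ``NONSHRUB=1``,
``SHRUB=2`` and ``NODATA=255``.

Files are written as plain uint8 TIFF via :mod:`tifffile` with a JSON
sidecar (``<name>.tif.json``) carrying ``gsd_m`` and ``origin``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

BARREN = 0
NONSHRUB = 1
SHRUB = 2
NODATA = 255

CLASS_IDS = (BARREN, NONSHRUB, SHRUB)
CLASS_NAMES = {BARREN: "barren", NONSHRUB: "non-shrub", SHRUB: "shrub"}
NAME_TO_ID = {v: k for k, v in CLASS_NAMES.items()}


@dataclass
class RGBRaster:
    """3-band 8-bit image with ground sampling distance and origin.

    ``data`` has shape (rows, cols, 3), dtype uint8.  ``origin`` is the
    (x, y) map coordinate of the raster's south-west corner in metres.
    """

    data: np.ndarray
    gsd_m: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError("RGBRaster data must have shape (rows, cols, 3)")
        if self.data.dtype != np.uint8:
            raise ValueError("RGBRaster data must be uint8")
        if not self.gsd_m > 0:
            raise ValueError("gsd_m must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def extent_m(self) -> tuple[float, float]:
        """(width, height) in metres."""
        rows, cols = self.shape
        return cols * self.gsd_m, rows * self.gsd_m


@dataclass
class ClassRaster:
    """Integer-labelled raster over {barren, non-shrub, shrub} + nodata."""

    data: np.ndarray
    gsd_m: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("ClassRaster data must be 2-D")
        if self.data.dtype != np.uint8:
            self.data = self.data.astype(np.uint8)
        if not self.gsd_m > 0:
            raise ValueError("gsd_m must be positive")
        valid = set(CLASS_IDS) | {NODATA}
        present = set(np.unique(self.data).tolist())
        if not present <= valid:
            raise ValueError(f"invalid class labels {sorted(present - valid)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def extent_m(self) -> tuple[float, float]:
        rows, cols = self.shape
        return cols * self.gsd_m, rows * self.gsd_m

    def valid_mask(self) -> np.ndarray:
        return self.data != NODATA

    def class_proportions(self) -> np.ndarray:
        """Proportions of the three classes over valid pixels."""
        counts = np.bincount(self.data[self.valid_mask()], minlength=3)[:3]
        total = counts.sum()
        if total == 0:
            raise ValueError("raster has no valid pixels")
        return counts / total


def pixel_index(coords_m: np.ndarray, raster: RGBRaster | ClassRaster) -> tuple[np.ndarray, np.ndarray]:
    """Map (x, y) metric points to (row, col) pixel indices, half-open rule.

    Points lying exactly on the raster's far (east/north) edge are clamped
    onto the last pixel so that cell corners coincident with the raster
    boundary remain sampleable; anything further out raises.
    """
    coords = np.atleast_2d(np.asarray(coords_m, dtype=float))
    x0, y0 = raster.origin
    rows, cols = raster.shape
    gsd = raster.gsd_m
    width, height = cols * gsd, rows * gsd
    xloc = coords[:, 0] - x0
    yloc = coords[:, 1] - y0
    eps = 1e-9
    if np.any(xloc < -eps) or np.any(yloc < -eps) or np.any(xloc > width + eps) or np.any(yloc > height + eps):
        raise ValueError("point outside raster extent (design/raster mismatch)")
    col = np.minimum(np.floor(xloc / gsd).astype(np.int64), cols - 1)
    row = np.minimum(np.floor((height - yloc) / gsd).astype(np.int64), rows - 1)
    col = np.maximum(col, 0)
    row = np.maximum(row, 0)
    return row, col


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_raster(raster: RGBRaster | ClassRaster, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, raster.data)
    meta = {
        "gsd_m": raster.gsd_m,
        "origin": list(raster.origin),
        "kind": "rgb" if isinstance(raster, RGBRaster) else "class",
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_raster(path: str | Path) -> RGBRaster | ClassRaster:
    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    cls = RGBRaster if meta["kind"] == "rgb" else ClassRaster
    return cls(data=data, gsd_m=meta["gsd_m"], origin=tuple(meta["origin"]))
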
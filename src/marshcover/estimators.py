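"""Per-cell cover proportions from the classified raster.

Two drone-side estimators mirror the field comparison: full pixel
enumeration per cell (``drone_pixels``) and virtual step-point transects
overlaid on the classified map (``drone_transects``).  Both emit the same
long-form CellCoverTable rows as the ground simulator so the three methods
stack into one table for the statistics.

Pixel membership in a cell uses the pixel-centre / half-open-edge rule
stated in :mod:`marshcover.raster`; each pixel belongs to exactly one cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import CELL_SIDE_M, SurveyDesign
from .ground import cell_proportions_from_points
from .raster import CLASS_IDS, NODATA, ClassRaster, pixel_index

TABLE_COLUMNS = ["plot_id", "cell_id", "method", "altitude_m", "class", "proportion", "n"]


def validate_cover_table(table: pd.DataFrame, tol: float = 1e-9) -> None:
    """Check the CellCoverTable contract: per (cell, method, altitude) the
    three class proportions sum to 1 and share one n."""
    for col in TABLE_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"missing column {col}")
    grp = table.groupby(["cell_id", "method", "altitude_m"], dropna=False)
    sums = grp["proportion"].sum()
    if np.any(np.abs(sums.to_numpy() - 1.0) > tol):
        raise ValueError("proportions do not sum to 1 within tolerance")
    if np.any(grp["n"].nunique().to_numpy() != 1):
        raise ValueError("n varies within a cell/method/altitude group")


def _cell_index_arrays(cls: ClassRaster, design: SurveyDesign) -> np.ndarray:
    """Map every pixel to a cell_id (0 where outside all cells).

    Exploits the design's 50 m cell grid: pixel centres are floor-divided
    into grid columns/rows and looked up against the design's cells.
    """
    rows, cols = cls.shape
    x0, y0 = cls.origin
    gsd = cls.gsd_m
    height = rows * gsd
    cx = np.floor((x0 + (np.arange(cols) + 0.5) * gsd) / CELL_SIDE_M).astype(np.int64)
    cy = np.floor((y0 + height - (np.arange(rows) + 0.5) * gsd) / CELL_SIDE_M).astype(np.int64)
    grid: dict[tuple[int, int], int] = {}
    for cell in design.cells:
        grid[(int(cell.x_min // CELL_SIDE_M), int(cell.y_min // CELL_SIDE_M))] = cell.cell_id
    nx = cx.max() + 1
    lut = np.zeros((cy.max() + 1, nx), dtype=np.int64)
    for (gx, gy), cid in grid.items():
        if gy <= cy.max() and gx <= cx.max():
            lut[gy, gx] = cid
    cy = np.clip(cy, 0, lut.shape[0] - 1)
    cx = np.clip(cx, 0, lut.shape[1] - 1)
    return lut[np.ix_(cy, cx)]


def pixel_count_proportions(
    cls: ClassRaster, design: SurveyDesign, altitude_m: float | None = None
) -> pd.DataFrame:
    """Per-cell proportions from full pixel enumeration (method 'drone_pixels')."""
    cell_ids = _cell_index_arrays(cls, design)
    data = cls.data
    valid = (cell_ids > 0) & (data != NODATA)
    cid = cell_ids[valid]
    lab = data[valid].astype(np.int64)
    n_cells = max(c.cell_id for c in design.cells)
    counts = np.zeros((n_cells + 1, 3), dtype=np.int64)
    np.add.at(counts, (cid, lab), 1)
    plot_of = {c.cell_id: c.plot_id for c in design.cells}
    rows = []
    for cell in design.cells:
        n = int(counts[cell.cell_id].sum())
        if n == 0:
            raise ValueError(f"cell {cell.cell_id} contains no pixels")
        for c in CLASS_IDS:
            rows.append(
                {
                    "plot_id": plot_of[cell.cell_id],
                    "cell_id": cell.cell_id,
                    "method": "drone_pixels",
                    "altitude_m": altitude_m,
                    "class": int(c),
                    "proportion": counts[cell.cell_id, c] / n,
                    "n": n,
                }
            )
    out = pd.DataFrame(rows)
    out["altitude_m"] = out["altitude_m"].astype(float)
    return out


def virtual_transect_proportions(
    cls: ClassRaster,
    design: SurveyDesign,
    spacing_m: float = 1.0,
    altitude_m: float | None = None,
) -> pd.DataFrame:
    """Per-cell proportions from step points read off the classified raster
    (method 'drone_transects'); 142 points per cell at 1 m spacing."""
    from .ground import walk_transects

    records = walk_transects(cls, design, spacing_m=spacing_m, misclass_rate=0.0)
    return cell_proportions_from_points(records, method="drone_transects", altitude_m=altitude_m)


def study_area_proportions(cls: ClassRaster, design: SurveyDesign) -> np.ndarray:
    """Class proportions pooled over every cell pixel of all plots."""
    cell_ids = _cell_index_arrays(cls, design)
    valid = (cell_ids > 0) & (cls.data != NODATA)
    counts = np.bincount(cls.data[valid].astype(np.int64), minlength=3)[:3]
    total = counts.sum()
    if total == 0:
        raise ValueError("no cell pixels in raster")
    return counts / total


def write_cover_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cover_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_cover_table(table)
    return table
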
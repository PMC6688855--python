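"""Survey geometry: plots, the 50 x 50 m cell grid, diagonal transects, and
the altitude -> ground-sampling-distance (GSD) relation.

The default design mirrors the field layout of the degradation survey: five
rectangular plots partitioning 92 adjacent 50 x 50 m cells (23 ha), with two
diagonal step-point transects per cell (NW->SE and NE->SW), 184 transects in
total.  Coordinates are planar metres with the origin at the study SW corner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

CELL_SIDE_M = 50.0
TRANSECT_LENGTH_M = CELL_SIDE_M * np.sqrt(2.0)

#: cells per plot in the default design (sums to 92)
DEFAULT_PLOT_CELL_COUNTS = (24, 20, 20, 16, 12)
#: rows of cells in every default plot; plot widths are counts / rows
DEFAULT_PLOT_ROWS = 4


@dataclass(frozen=True)
class Cell:
    plot_id: int
    cell_id: int
    x_min: float  # SW corner, metres
    y_min: float

    @property
    def corners(self) -> dict[str, tuple[float, float]]:
        s = CELL_SIDE_M
        return {
            "NW": (self.x_min, self.y_min + s),
            "NE": (self.x_min + s, self.y_min + s),
            "SW": (self.x_min, self.y_min),
            "SE": (self.x_min + s, self.y_min),
        }

    def transect_endpoints(self) -> list[tuple[tuple[float, float], tuple[float, float]]]:
        """The two diagonals: transect 1 NW->SE, transect 2 NE->SW."""
        c = self.corners
        return [(c["NW"], c["SE"]), (c["NE"], c["SW"])]

    def polygon(self) -> list[tuple[float, float]]:
        s = CELL_SIDE_M
        x, y = self.x_min, self.y_min
        return [(x, y), (x + s, y), (x + s, y + s), (x, y + s), (x, y)]


@dataclass(frozen=True)
class Plot:
    plot_id: int
    x_min: float
    y_min: float
    width_m: float
    height_m: float


@dataclass
class SurveyDesign:
    plots: list[Plot]
    cells: list[Cell]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_transects(self) -> int:
        return 2 * len(self.cells)

    @property
    def total_area_m2(self) -> float:
        return self.n_cells * CELL_SIDE_M**2

    @property
    def extent_m(self) -> tuple[float, float]:
        """(width, height) of the bounding box anchored at the origin."""
        xmax = max(p.x_min + p.width_m for p in self.plots)
        ymax = max(p.y_min + p.height_m for p in self.plots)
        return xmax, ymax

    def cells_in_plot(self, plot_id: int) -> list[Cell]:
        return [c for c in self.cells if c.plot_id == plot_id]

    def to_geojson(self) -> dict:
        feats = [
            {
                "type": "Feature",
                "properties": {"plot_id": c.plot_id, "cell_id": c.cell_id},
                "geometry": {"type": "Polygon", "coordinates": [[list(p) for p in c.polygon()]]},
            }
            for c in self.cells
        ]
        return {"type": "FeatureCollection", "features": feats}

    def to_config(self) -> str:
        counts = [len(self.cells_in_plot(p.plot_id)) for p in self.plots]
        return json.dumps({"plot_cell_counts": counts, "plot_rows": int(self.plots[0].height_m // CELL_SIDE_M)})

    @staticmethod
    def from_config(text: str) -> "SurveyDesign":
        cfg = json.loads(text)
        return default_design(plot_cell_counts=tuple(cfg["plot_cell_counts"]), plot_rows=cfg["plot_rows"], scaled=sum(cfg["plot_cell_counts"]) != 92)


def default_design(
    plot_cell_counts: tuple[int, ...] = DEFAULT_PLOT_CELL_COUNTS,
    plot_rows: int = DEFAULT_PLOT_ROWS,
    scaled: bool = False,
) -> SurveyDesign:
    """Build the survey grid: side-by-side rectangular plots of 50 m cells.

    Each plot is a column block ``(count / plot_rows)`` cells wide and
    ``plot_rows`` cells tall, abutting its neighbour so the study area is a
    single rectangle with no dead space.  The counts must sum to 92 (the
    surveyed grid) unless ``scaled=True`` for reduced desk-scale designs.
    """
    total = sum(plot_cell_counts)
    if not scaled and total != 92:
        raise ValueError(f"default design must have 92 cells, got {total}; pass scaled=True for reduced designs")
    plots: list[Plot] = []
    cells: list[Cell] = []
    x_cursor = 0.0
    cell_id = 0
    for pid, count in enumerate(plot_cell_counts, start=1):
        if count % plot_rows:
            raise ValueError(f"plot {pid}: {count} cells not divisible by {plot_rows} rows")
        ncols = count // plot_rows
        plots.append(Plot(pid, x_cursor, 0.0, ncols * CELL_SIDE_M, plot_rows * CELL_SIDE_M))
        for col in range(ncols):
            for row in range(plot_rows):
                cell_id += 1
                cells.append(Cell(pid, cell_id, x_cursor + col * CELL_SIDE_M, row * CELL_SIDE_M))
        x_cursor += ncols * CELL_SIDE_M
    return SurveyDesign(plots=plots, cells=cells)


@dataclass(frozen=True)
class GsdModel:
    """Linear altitude -> GSD relation: gsd_m = k * altitude_m.

    ``k`` is metres of GSD per metre of flight altitude, a property of the
    camera/lens.  The survey camera works out to k = 0.00032 (3.2 cm at
    100 m); the synthetic default uses a coarser k for desk-scale rasters.
    """

    k: float

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("k must be positive")

    @staticmethod
    def calibrate(altitude_m: float, gsd_cm: float) -> "GsdModel":
        if altitude_m <= 0 or gsd_cm <= 0:
            raise ValueError("calibration point must be positive")
        return GsdModel(k=(gsd_cm / 100.0) / altitude_m)

    @staticmethod
    def paper_calibrated() -> "GsdModel":
        """The survey camera: 3.2 cm GSD at 100 m AGL."""
        return GsdModel.calibrate(100.0, 3.2)

    def gsd_m(self, altitude_m: float) -> float:
        if altitude_m <= 0:
            raise ValueError("altitude must be positive")
        return self.k * altitude_m


def gsd_at_altitude(model: GsdModel, altitude_m: float) -> tuple[float, float]:
    """GSD in cm at an altitude, plus its half-away-from-zero 1-decimal rounding."""
    gsd_cm = model.gsd_m(altitude_m) * 100.0
    rounded = np.floor(gsd_cm * 10.0 + 0.5) / 10.0
    return gsd_cm, float(rounded)


def transect_sample_points(
    design: SurveyDesign, spacing_m: float = 1.0
) -> list[dict]:
    """Ordered sample points every ``spacing_m`` along each diagonal.

    Points sit at arc length 0, s, 2s, ... from the start corner; the far
    corner is included only when the 50*sqrt(2) m length is an exact
    multiple of s.  Returns one record per point with keys ``plot_id``,
    ``cell_id``, ``transect_index`` (1 or 2), ``position_m``, ``x``, ``y``.
    """
    if spacing_m <= 0:
        raise ValueError("spacing must be positive")
    L = TRANSECT_LENGTH_M
    n_pts = int(np.floor(L / spacing_m + 1e-9)) + 1
    frac = np.arange(n_pts) * spacing_m / L
    out: list[dict] = []
    for cell in design.cells:
        for t_idx, (start, end) in enumerate(cell.transect_endpoints(), start=1):
            xs = start[0] + frac * (end[0] - start[0])
            ys = start[1] + frac * (end[1] - start[1])
            for i in range(n_pts):
                out.append(
                    {
                        "plot_id": cell.plot_id,
                        "cell_id": cell.cell_id,
                        "transect_index": t_idx,
                        "position_m": float(i * spacing_m),
                        "x": float(xs[i]),
                        "y": float(ys[i]),
                    }
                )
    return out
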
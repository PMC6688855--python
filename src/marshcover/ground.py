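"""Simulated field crew: step-point transects read off the true class map.

The field protocol records the dominant cover underfoot roughly every metre
along both diagonals of each 50 x 50 m cell; species-level records are
grouped into barren / non-shrub / shrub before any computation, so the
simulator emits the grouped class directly.  An optional uniform-confusion
observer error stands in for recorder mistakes (default off).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import SurveyDesign, transect_sample_points
from .raster import CLASS_IDS, ClassRaster, pixel_index


@dataclass(frozen=True)
class StepPointRecord:
    plot_id: int
    cell_id: int
    transect_index: int
    position_m: float
    grouped_class: int


def walk_transects(
    truth: ClassRaster,
    design: SurveyDesign,
    spacing_m: float = 1.0,
    misclass_rate: float = 0.0,
    seed: int = 0,
) -> list[StepPointRecord]:
    """Sample the truth raster at every step point of every transect.

    With probability ``misclass_rate`` a record's label is replaced by one
    of the other two classes uniformly at random (observer error).
    Deterministic given ``seed``.
    """
    if not (0 <= misclass_rate < 1):
        raise ValueError("misclass_rate must be in [0, 1)")
    pts = transect_sample_points(design, spacing_m)
    coords = np.array([[p["x"], p["y"]] for p in pts])
    rows, cols = pixel_index(coords, truth)
    labels = truth.data[rows, cols].astype(np.int64)
    if misclass_rate > 0:
        rng = np.random.default_rng(seed)
        flip = rng.random(labels.size) < misclass_rate
        # uniform over the two other classes
        offset = rng.integers(1, 3, size=labels.size)
        labels[flip] = (labels[flip] + offset[flip]) % 3
    return [
        StepPointRecord(p["plot_id"], p["cell_id"], p["transect_index"], p["position_m"], int(lab))
        for p, lab in zip(pts, labels)
    ]


def cell_proportions_from_points(
    records: list[StepPointRecord], method: str = "ground", altitude_m: float | None = None
) -> pd.DataFrame:
    """Per-cell class proportions from step-point records.

    Returns long-form rows (plot_id, cell_id, method, altitude_m, class,
    proportion, n) where n is the total points in the cell; the three
    proportions of a cell sum to exactly 1.
    """
    if not records:
        raise ValueError("no records")
    df = pd.DataFrame(
        {
            "plot_id": [r.plot_id for r in records],
            "cell_id": [r.cell_id for r in records],
            "grouped_class": [r.grouped_class for r in records],
        }
    )
    out_rows = []
    for (plot_id, cell_id), grp in df.groupby(["plot_id", "cell_id"], sort=True):
        n = len(grp)
        counts = np.bincount(grp["grouped_class"], minlength=3)[:3]
        for c in CLASS_IDS:
            out_rows.append(
                {
                    "plot_id": int(plot_id),
                    "cell_id": int(cell_id),
                    "method": method,
                    "altitude_m": altitude_m,
                    "class": int(c),
                    "proportion": counts[c] / n,
                    "n": n,
                }
            )
    out = pd.DataFrame(out_rows)
    out["altitude_m"] = out["altitude_m"].astype(float)
    return out
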
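"""Thematic-map accuracy: stratified assessment points, confusion matrices,
overall accuracy, Cohen's kappa, omission/commission errors, and the
per-plot summary (mean +/- SD and range across plots).

Assessment points are stratified by mapped class with per-class counts
proportional to class area (largest-remainder apportionment) and drawn
uniformly without replacement within class.  In synthetic mode the truth
raster plays the role of the photointerpreter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Plot
from .raster import CLASS_IDS, NODATA, ClassRaster

logger = logging.getLogger(__name__)


def largest_remainder(shares: np.ndarray, n: int) -> np.ndarray:
    """Apportion n seats proportionally to shares (Hare largest remainder)."""
    shares = np.asarray(shares, dtype=float)
    quotas = shares / shares.sum() * n
    alloc = np.floor(quotas).astype(int)
    rem = n - alloc.sum()
    if rem > 0:
        order = np.argsort(-(quotas - alloc), kind="stable")
        alloc[order[:rem]] += 1
    return alloc


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # rows = mapped class, cols = reference class
    plot_id: int | None = None
    altitude_m: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _plot_pixel_mask(cls: ClassRaster, plot: Plot) -> np.ndarray:
    rows, cols = cls.shape
    x0, y0 = cls.origin
    gsd = cls.gsd_m
    height = rows * gsd
    px = x0 + (np.arange(cols) + 0.5) * gsd
    py = y0 + height - (np.arange(rows) + 0.5) * gsd
    in_x = (px >= plot.x_min) & (px < plot.x_min + plot.width_m)
    in_y = (py >= plot.y_min) & (py < plot.y_min + plot.height_m)
    return in_y[:, None] & in_x[None, :]


def stratified_points(
    cls: ClassRaster, plot: Plot, n_points: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Randomly stratified assessment points within one plot.

    Per-class counts are proportional to the class's mapped area in the
    plot (largest remainder); points are pixel centres drawn uniformly
    without replacement within each class.  Returns (row, col, x, y,
    mapped) rows.  Deterministic given seed.
    """
    mask = _plot_pixel_mask(cls, plot) & (cls.data != NODATA)
    if int(mask.sum()) < n_points:
        raise ValueError("plot has fewer pixels than requested points")
    labels = cls.data
    class_pix = {c: np.flatnonzero(mask.ravel() & (labels.ravel() == c)) for c in CLASS_IDS}
    areas = np.array([len(class_pix[c]) for c in CLASS_IDS], dtype=float)
    alloc = largest_remainder(areas, n_points)
    # reallocate any excess over available pixels to the next class by area
    order = np.argsort(-areas, kind="stable")
    for c in CLASS_IDS:
        excess = alloc[c] - len(class_pix[c])
        if excess > 0:
            logger.warning("class %d allocation exceeds pixels; reallocating %d", c, excess)
            alloc[c] -= excess
            for o in order:
                room = len(class_pix[o]) - alloc[o]
                take = min(room, excess)
                alloc[o] += take
                excess -= take
                if excess == 0:
                    break
    rng = np.random.default_rng(seed)
    rows_out = []
    ncols = cls.shape[1]
    height = cls.shape[0] * cls.gsd_m
    for c in CLASS_IDS:
        if alloc[c] == 0:
            continue
        chosen = rng.choice(class_pix[c], size=alloc[c], replace=False)
        r, col = np.divmod(chosen, ncols)
        for ri, ci in zip(r, col):
            rows_out.append(
                {
                    "row": int(ri),
                    "col": int(ci),
                    "x": cls.origin[0] + (ci + 0.5) * cls.gsd_m,
                    "y": cls.origin[1] + height - (ri + 0.5) * cls.gsd_m,
                    "mapped": int(c),
                }
            )
    return pd.DataFrame(rows_out)


def confusion_matrix(
    points: pd.DataFrame,
    mapped: ClassRaster,
    reference: ClassRaster,
    plot_id: int | None = None,
    altitude_m: float | None = None,
) -> ConfusionMatrix:
    """Count (mapped, reference) label pairs at the assessment points.

    Points falling on nodata in either raster are excluded with a warning.
    """
    if mapped.shape != reference.shape or mapped.gsd_m != reference.gsd_m:
        raise ValueError("mapped and reference rasters not aligned")
    r = points["row"].to_numpy()
    c = points["col"].to_numpy()
    m = mapped.data[r, c].astype(np.int64)
    ref = reference.data[r, c].astype(np.int64)
    keep = (m != NODATA) & (ref != NODATA)
    if not keep.all():
        logger.warning("%d assessment points on nodata excluded", int((~keep).sum()))
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (m[keep], ref[keep]), 1)
    return ConfusionMatrix(counts=counts, plot_id=plot_id, altitude_m=altitude_m)


def accuracy_metrics(cm: ConfusionMatrix) -> dict:
    """Overall accuracy, Cohen's kappa, and per-class omission/commission.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the matrix marginals;
    degenerate single-class matrices (p_e = 1) report kappa 0 with a
    warning.  Omission_c = 1 - diag_c / column_c (reference missed);
    commission_c = 1 - diag_c / row_c (mapped wrongly); classes absent
    from a margin report NaN.
    """
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(counts) / total
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    p_e = float(np.sum(row * col)) / total**2
    if abs(1.0 - p_e) < 1e-12:
        logger.warning("degenerate single-class matrix; kappa defined as 0")
        kappa = 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    diag = np.diag(counts).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        omission = 1.0 - np.where(col > 0, diag / col, np.nan)
        commission = 1.0 - np.where(row > 0, diag / row, np.nan)
    return {
        "overall_accuracy": float(p_o),
        "kappa": float(kappa),
        "omission": omission,
        "commission": commission,
        "n": total,
    }


def summarize_accuracy(per_plot: list[dict]) -> pd.DataFrame:
    """Table-style summary of per-plot OA and kappa: mean, sample SD (n-1),
    min, max; SD is 0 (flagged) for a single plot."""
    if not per_plot:
        raise ValueError("no plot metrics")
    out = []
    for key in ("overall_accuracy", "kappa"):
        vals = np.array([m[key] for m in per_plot], dtype=float)
        single = len(vals) == 1
        out.append(
            {
                "metric": key,
                "mean": float(vals.mean()),
                "sd": 0.0 if single else float(vals.std(ddof=1)),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "n_plots": len(vals),
                "sd_undefined": single,
            }
        )
    return pd.DataFrame(out)
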
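"""Salt-and-pepper clean-up of classified rasters.

High-resolution classifications leave isolated misclassified pixels; the
standard remedy chain is (1) a majority filter, (2) an expand/shrink
"boundary clean" smoothing of class edges, and (3) removal of patches below
a minimum mapping unit (MMU, default 0.25 m^2) with sub-MMU pixels
re-labelled to the class of the nearest surviving pixel.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .raster import CLASS_IDS, NODATA, ClassRaster

logger = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


def _kernel(kind: str) -> np.ndarray:
    if kind == "8-neighbour":
        return _STRUCT8
    if kind == "4-neighbour":
        return _STRUCT4.copy()
    raise ValueError("kernel must be '4-neighbour' or '8-neighbour'")


def majority_filter(cls: ClassRaster, kernel: str = "8-neighbour") -> ClassRaster:
    """Replace each pixel by the strict-majority class of its neighbourhood.

    The neighbourhood includes the centre (9 or 5 pixels; fewer at raster
    edges and around nodata, which is ignored in the counts).  A pixel is
    only changed when one class holds a *strict* majority of the valid
    neighbourhood; otherwise it is left as is.
    """
    k = _kernel(kernel).astype(np.int32)
    data = cls.data
    valid = data != NODATA
    counts = np.stack(
        [ndimage.convolve(((data == c) & valid).astype(np.int32), k, mode="constant", cval=0) for c in CLASS_IDS]
    )
    total = ndimage.convolve(valid.astype(np.int32), k, mode="constant", cval=0)
    winner = np.argmax(counts, axis=0).astype(np.uint8)
    wins = np.take_along_axis(counts, winner[None].astype(np.int64), axis=0)[0]
    out = data.copy()
    strict = (2 * wins > total) & valid
    out[strict] = winner[strict]
    return ClassRaster(data=out, gsd_m=cls.gsd_m, origin=cls.origin)


def boundary_clean(
    cls: ClassRaster,
    priority: tuple[int, ...] | None = None,
    iterations: int = 2,
) -> ClassRaster:
    """Expand/shrink smoothing of class boundaries.

    For each class, a one-pixel morphological dilation followed by erosion
    (a 3x3 closing) is applied to its mask; the closed masks are composited
    so that classes earlier in ``priority`` win contested pixels.  By
    default priority is descending class area.  Every pixel keeps a label
    (each class's closing contains its own mask), so the raster stays
    fully labelled.  Repeated ``iterations`` times (default 2).
    """
    data = cls.data.copy()
    if priority is None:
        areas = np.bincount(data[data != NODATA], minlength=3)[:3]
        priority = tuple(int(c) for c in np.argsort(-areas, kind="stable"))
    if sorted(priority) != sorted(CLASS_IDS):
        raise ValueError("priority must be a permutation of the three classes")
    nodata = data == NODATA
    for _ in range(iterations):
        out = data.copy()
        # apply lowest priority first so highest priority overwrites last
        for c in reversed(priority):
            mask = data == c
            if not mask.any():
                continue
            closed = ndimage.binary_erosion(
                ndimage.binary_dilation(mask, structure=_STRUCT8),
                structure=_STRUCT8, border_value=1,
            )
            out[closed] = c
        out[nodata] = NODATA
        data = out
    return ClassRaster(data=data, gsd_m=cls.gsd_m, origin=cls.origin)


def patch_label(cls: ClassRaster, connectivity: int = 8) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Connected-component labelling of same-class patches.

    Returns (labels, patch_class, patch_area_px): ``labels`` assigns a
    unique positive id to every patch (0 = nodata), ``patch_class[i]`` and
    ``patch_area_px[i]`` describe patch id i+1.
    """
    struct = _STRUCT8 if connectivity == 8 else _STRUCT4
    labels = np.zeros(cls.shape, dtype=np.int64)
    patch_class: list[int] = []
    patch_area: list[int] = []
    offset = 0
    for c in CLASS_IDS:
        mask = cls.data == c
        lab, n = ndimage.label(mask, structure=struct)
        if n == 0:
            continue
        labels[mask] = lab[mask] + offset
        areas = np.bincount(lab[mask])[1:]
        patch_class.extend([c] * n)
        patch_area.extend(areas.tolist())
        offset += n
    return labels, np.array(patch_class, dtype=np.uint8), np.array(patch_area, dtype=np.int64)


def mmu_sieve(
    cls: ClassRaster,
    min_area_m2: float = 0.25,
    connectivity: int = 8,
    max_passes: int = 10,
) -> ClassRaster:
    """Dissolve patches smaller than the minimum mapping unit.

    Per pass, every connected component with area (pixels * gsd^2) below
    ``min_area_m2`` is removed simultaneously; each removed pixel takes the
    class of the nearest pixel (Euclidean distance between pixel centres)
    belonging to a pre-pass surviving patch, ties broken toward the lowest
    class id.  Passes repeat until no sub-MMU patch remains or
    ``max_passes`` is hit (logged if not converged).
    """
    px_area = cls.gsd_m**2
    data = cls.data.copy()
    for _ in range(max_passes):
        work = ClassRaster(data=data, gsd_m=cls.gsd_m, origin=cls.origin)
        labels, patch_class, patch_area = patch_label(work, connectivity)
        small = patch_area * px_area < min_area_m2
        if not small.any():
            return work
        survive_patch = np.concatenate([[False], ~small])  # label 0 = nodata
        survivor_mask = survive_patch[labels]
        if not survivor_mask.any():
            raise ValueError("all patches below MMU; no surviving donor")
        removed = ~survivor_mask & (data != NODATA)
        # per-class distance to nearest surviving pixel; scanning classes in
        # ascending id with strict < gives the lowest-class tie-break
        best_d = np.full(int(removed.sum()), np.inf)
        best_c = np.zeros(best_d.shape, dtype=np.uint8)
        for c in CLASS_IDS:
            donor = survivor_mask & (data == c)
            if not donor.any():
                continue
            d = ndimage.distance_transform_edt(~donor, sampling=cls.gsd_m)[removed]
            better = d < best_d
            best_d[better] = d[better]
            best_c[better] = c
        data[removed] = best_c
    work = ClassRaster(data=data, gsd_m=cls.gsd_m, origin=cls.origin)
    _, _, areas = patch_label(work, connectivity)
    if np.any(areas * px_area < min_area_m2):
        logger.warning("mmu_sieve did not converge within %d passes", max_passes)
    return work


def postprocess_chain(
    cls: ClassRaster,
    kernel: str = "8-neighbour",
    priority: tuple[int, ...] | None = None,
    bc_iterations: int = 2,
    min_area_m2: float = 0.25,
    connectivity: int = 8,
) -> ClassRaster:
    """Majority filter -> boundary clean -> MMU sieve."""
    out = majority_filter(cls, kernel=kernel)
    out = boundary_clean(out, priority=priority, iterations=bc_iterations)
    return mmu_sieve(out, min_area_m2=min_area_m2, connectivity=connectivity)
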
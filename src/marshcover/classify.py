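"""Unsupervised spectral classification of the RGB mosaic.

The mosaic is clustered into K=30 spectral classes by Lloyd's k-means with
k-means++ seeding in raw RGB space (no texture, no position), then the
clusters are reclassified into the three grouped land-cover categories.  In
synthetic mode the analyst's manual reclassification is replaced by a
plurality vote of each cluster's pixels against the reference truth raster;
real-data users supply a manual cluster -> class mapping instead.

Lloyd runs on the table of *unique* colours weighted by their pixel counts,
which is algebraically identical to running on every pixel (same centroids,
same objective) but far faster on 8-bit imagery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .raster import BARREN, CLASS_IDS, NODATA, NONSHRUB, SHRUB, ClassRaster, RGBRaster

logger = logging.getLogger(__name__)

#: tie-break priority for plurality reclassification
TIE_PRIORITY = (BARREN, SHRUB, NONSHRUB)


@dataclass
class ClusterModel:
    centroids: np.ndarray  # (K, 3) float
    seed: int
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    initial_centroids: np.ndarray | None = None  # k-means++ seeds, kept for audit

    @property
    def K(self) -> int:
        return self.centroids.shape[0]

    def predict(self, rgb: RGBRaster, chunk: int = 4_000_000) -> np.ndarray:
        """Nearest-centroid (Euclidean) cluster id per pixel."""
        flat = rgb.data.reshape(-1, 3).astype(np.float64)
        out = np.empty(flat.shape[0], dtype=np.int32)
        for i in range(0, flat.shape[0], chunk):
            d = _sq_dists(flat[i : i + chunk], self.centroids)
            out[i : i + chunk] = np.argmin(d, axis=1)
        return out.reshape(rgb.shape)


def _sq_dists(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    # |x-c|^2 = |x|^2 - 2 x.c + |c|^2 ; exact enough on 0-255 data
    return (
        np.einsum("ij,ij->i", x, x)[:, None]
        - 2.0 * x @ c.T
        + np.einsum("ij,ij->i", c, c)[None, :]
    )


def _kmeanspp_init(points: np.ndarray, weights: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    n = points.shape[0]
    centroids = np.empty((K, points.shape[1]))
    probs = weights / weights.sum()
    centroids[0] = points[rng.choice(n, p=probs)]
    d2 = _sq_dists(points, centroids[:1]).ravel()
    for k in range(1, K):
        p = weights * d2
        s = p.sum()
        if s <= 0:  # all points coincide with chosen centroids
            centroids[k:] = centroids[0]
            return centroids
        centroids[k] = points[rng.choice(n, p=p / s)]
        d2 = np.minimum(d2, _sq_dists(points, centroids[k : k + 1]).ravel())
    return centroids


def fit_clusters(
    rgb: RGBRaster,
    K: int = 30,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
    sample_size: int | None = None,
) -> ClusterModel:
    """Lloyd k-means on RGB values with k-means++ seeding.

    ``tol`` is the relative change in the within-cluster sum of squares at
    which iteration stops.  If ``sample_size`` is given, the model is fit
    on a seeded uniform pixel subsample (centroids then apply to the full
    raster via :meth:`ClusterModel.predict`); by default all pixels are
    used.  If K exceeds the number of distinct colours it is reduced with
    a warning.  Deterministic given ``seed``.
    """
    if rgb.data.size == 0:
        raise ValueError("empty raster")
    if not 1 <= K <= 255:
        raise ValueError("K must be in [1, 255]")
    rng = np.random.default_rng(seed)
    flat = rgb.data.reshape(-1, 3)
    if sample_size is not None and sample_size < flat.shape[0]:
        idx = rng.choice(flat.shape[0], size=sample_size, replace=False)
        flat = flat[idx]
    colors, counts = np.unique(flat, axis=0, return_counts=True)
    points = colors.astype(np.float64)
    weights = counts.astype(np.float64)
    if K > points.shape[0]:
        logger.warning("K=%d exceeds %d distinct colours; reducing", K, points.shape[0])
        K = points.shape[0]
    centroids = _kmeanspp_init(points, weights, K, rng)
    init = centroids.copy()
    trace: list[float] = []
    prev_obj = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = _sq_dists(points, centroids)
        assign = np.argmin(d2, axis=1)
        obj = float(np.sum(weights * d2[np.arange(points.shape[0]), assign]))
        trace.append(obj)
        # weighted mean update; empty clusters keep their centroid
        wsum = np.bincount(assign, weights=weights, minlength=K)
        for dim in range(3):
            num = np.bincount(assign, weights=weights * points[:, dim], minlength=K)
            nz = wsum > 0
            centroids[nz, dim] = num[nz] / wsum[nz]
        if prev_obj < np.inf and (prev_obj - obj) <= tol * max(prev_obj, 1e-300):
            break
        prev_obj = obj
    return ClusterModel(centroids=centroids, seed=seed, objective_trace=trace, n_iter=n_iter, initial_centroids=init)


@dataclass
class ReclassMap:
    mapping: dict[int, int]  # cluster_id -> grouped class

    def __post_init__(self) -> None:
        bad = {v for v in self.mapping.values()} - set(CLASS_IDS)
        if bad:
            raise ValueError(f"invalid grouped classes {sorted(bad)}")

    def apply(self, cluster_ids: np.ndarray) -> np.ndarray:
        lut = np.full(max(self.mapping) + 1, NODATA, dtype=np.uint8)
        for k, v in self.mapping.items():
            lut[k] = v
        return lut[cluster_ids]


def plurality_reclass_map(
    model: ClusterModel, cluster_ids: np.ndarray, reference: ClassRaster
) -> ReclassMap:
    """Map each cluster to the grouped class holding the plurality of its
    reference pixels; ties break by fixed priority barren > shrub >
    non-shrub; empty clusters map to barren with a warning."""
    if cluster_ids.shape != reference.shape:
        raise ValueError("reference not aligned with clustered raster")
    ref = reference.data.ravel()
    cid = cluster_ids.ravel()
    valid = ref != NODATA
    counts = np.zeros((model.K, 3), dtype=np.int64)
    np.add.at(counts, (cid[valid], ref[valid].astype(np.int64)), 1)
    mapping: dict[int, int] = {}
    for k in range(model.K):
        if counts[k].sum() == 0:
            logger.warning("cluster %d has no members; mapped to barren", k)
            mapping[k] = BARREN
            continue
        best = max(TIE_PRIORITY, key=lambda c: (counts[k, c], -TIE_PRIORITY.index(c)))
        mapping[k] = int(best)
    return ReclassMap(mapping)


def reclassify_clusters(
    model: ClusterModel,
    rgb: RGBRaster,
    reference: ClassRaster | None = None,
    manual_map: ReclassMap | None = None,
) -> ClassRaster:
    """Produce the 3-class map from a cluster model.

    Automatic mode (``reference`` given) stands in for the analyst's
    manual inspection: plurality vote against the reference.  Manual mode
    applies a user ``ReclassMap`` verbatim.
    """
    if (reference is None) == (manual_map is None):
        raise ValueError("provide exactly one of reference or manual_map")
    cluster_ids = model.predict(rgb)
    rmap = manual_map if manual_map is not None else plurality_reclass_map(model, cluster_ids, reference)
    return ClassRaster(data=rmap.apply(cluster_ids), gsd_m=rgb.gsd_m, origin=rgb.origin)
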
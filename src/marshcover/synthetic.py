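"""Seeded synthetic salt-marsh scenes: true class maps plus RGB renderings.

The generator is a statistical stand-in for the degraded supratidal marsh:
a patchy landscape that is mostly barren sediment (~75%), with dwarf-shrub
patches (~21%) and sparse graminoid/forb mats (~3.5%).  Truth maps come from
thresholding a Gaussian-smoothed white-noise field at empirical quantiles,
which gives tunable patch size and near-exact class proportions.  The RGB
renderer reproduces the two error mechanisms that make real RGB mosaics
hard to classify:

* ``confusability`` pulls the non-shrub (graminoid mat) spectrum toward a
  dark-soil sub-spectrum of the barren class, so dark vegetation and dark
  sediment overlap spectrally;
* ``shadow_fraction`` darkens a strip of pixels on a fixed bearing beside
  shrub patches, emulating canopy shadows that classifiers confuse with
  shrub cover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .geometry import GsdModel, SurveyDesign
from .raster import BARREN, NONSHRUB, SHRUB, ClassRaster, RGBRaster

#: intensity multiplier applied inside the shadow mask
SHADOW_FACTOR = 0.45

DEFAULT_SPECTRA = {
    BARREN: np.array([150.0, 135.0, 115.0]),  # light dry sediment
    NONSHRUB: np.array([112.0, 124.0, 78.0]),  # graminoid/forb mat
    SHRUB: np.array([55.0, 88.0, 52.0]),  # dwarf willow/birch canopy
}
DARK_SOIL_MEAN = np.array([78.0, 70.0, 60.0])  # wet/organic sediment


#: default per-channel spectral SD; broad enough that dark graminoid mats,
#: dark soils and shadowed pixels genuinely overlap, as in field mosaics
DEFAULT_NOISE_SD = 18.0


def _default_cov() -> dict[int, np.ndarray]:
    return {c: np.eye(3) * DEFAULT_NOISE_SD**2 for c in DEFAULT_SPECTRA}


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    ``target_props`` is (barren, non-shrub, shrub) and must sum to 1.
    ``spatial_corr_length_m`` sets the Gaussian smoothing kernel of the
    latent field, i.e. the typical patch scale.  ``confusability`` in [0,1]
    moves the non-shrub mean toward the dark-soil spectrum (1 = coincident).
    """

    seed: int = 0
    gsd_m: float = 0.12
    target_props: tuple[float, float, float] = (0.755, 0.035, 0.210)
    spatial_corr_length_m: float = 6.0
    class_means: dict[int, np.ndarray] = field(default_factory=lambda: {k: v.copy() for k, v in DEFAULT_SPECTRA.items()})
    class_covs: dict[int, np.ndarray] = field(default_factory=_default_cov)
    dark_soil_mean: np.ndarray = field(default_factory=lambda: DARK_SOIL_MEAN.copy())
    shadow_fraction: float = 0.15
    confusability: float = 0.5
    dark_soil_fraction: float = 0.25  # share of barren drawn from the dark-soil sub-spectrum
    noise_sd: float | None = None  # overrides class_covs with iso noise if set

    def __post_init__(self) -> None:
        props = np.asarray(self.target_props, dtype=float)
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("target_props must sum to 1")
        if np.any(props < 0):
            raise ValueError("target_props must be nonnegative")
        if not self.gsd_m > 0:
            raise ValueError("gsd_m must be positive")
        if not (0 <= self.shadow_fraction < 1):
            raise ValueError("shadow_fraction must be in [0, 1)")
        if not (0 <= self.confusability <= 1):
            raise ValueError("confusability must be in [0, 1]")
        if self.noise_sd is not None:
            if self.noise_sd < 0:
                raise ValueError("noise_sd must be nonnegative")
            self.class_covs = {c: np.eye(3) * self.noise_sd**2 for c in self.class_means}
        for c, cov in self.class_covs.items():
            if np.any(np.linalg.eigvalsh(np.asarray(cov)) < -1e-9):
                raise ValueError(f"class {c} covariance not PSD")

    def effective_means(self) -> dict[int, np.ndarray]:
        """Class means after the confusability shift of the non-shrub spectrum."""
        means = {c: np.asarray(m, dtype=float).copy() for c, m in self.class_means.items()}
        c = self.confusability
        means[NONSHRUB] = (1.0 - c) * means[NONSHRUB] + c * np.asarray(self.dark_soil_mean, dtype=float)
        return means


@dataclass
class SyntheticScene:
    rgb: RGBRaster
    truth: ClassRaster
    spec: SceneSpec
    altitude_m: float | None = None

    def __post_init__(self) -> None:
        if self.rgb.shape != self.truth.shape or self.rgb.gsd_m != self.truth.gsd_m:
            raise ValueError("rgb and truth must share dimensions and gsd")


def generate_truth_map(spec: SceneSpec, extent_m: tuple[float, float]) -> ClassRaster:
    """Threshold a smoothed Gaussian field into a 3-class truth raster.

    The latent field is white noise smoothed with a Gaussian kernel of
    ``spatial_corr_length_m``; class labels are assigned by splitting the
    field at its empirical quantiles (low values -> shrub, middle ->
    non-shrub, high -> barren), so realized proportions track the targets
    to well within +/-0.02.  Deterministic given ``spec.seed``.
    """
    width, height = extent_m
    # ceil so the raster always covers the full design extent
    cols = int(np.ceil(width / spec.gsd_m - 1e-9))
    rows = int(np.ceil(height / spec.gsd_m - 1e-9))
    if rows <= 0 or cols <= 0:
        raise ValueError("degenerate extent: zero pixels")
    if spec.spatial_corr_length_m < 2 * spec.gsd_m:
        raise ValueError("spatial_corr_length_m must be >= 2 * gsd_m")
    rng = np.random.default_rng(spec.seed)
    fld = rng.standard_normal((rows, cols))
    sigma_px = spec.spatial_corr_length_m / spec.gsd_m
    fld = ndimage.gaussian_filter(fld, sigma=sigma_px, mode="reflect")
    p_barren, p_nonshrub, p_shrub = spec.target_props
    # low tail -> shrub, middle band -> non-shrub, rest -> barren
    q_shrub = np.quantile(fld, p_shrub) if p_shrub > 0 else -np.inf
    q_nonshrub = np.quantile(fld, p_shrub + p_nonshrub) if p_nonshrub > 0 else q_shrub
    labels = np.full((rows, cols), BARREN, dtype=np.uint8)
    labels[fld < q_nonshrub] = NONSHRUB
    labels[fld < q_shrub] = SHRUB
    if p_barren == 0:
        labels[labels == BARREN] = NONSHRUB if p_nonshrub > 0 else SHRUB
    return ClassRaster(data=labels, gsd_m=spec.gsd_m, origin=(0.0, 0.0))


def shadow_mask(truth: ClassRaster, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of shadowed pixels beside shrub patches.

    Shrub-adjacent zone = pixels one step along the fixed bearing (here:
    due north of a shrub pixel, i.e. shifted one row up) that are not shrub
    themselves; each zone pixel is shadowed independently with probability
    ``shadow_fraction``.
    """
    shrub = truth.data == SHRUB
    adjacent = np.zeros_like(shrub)
    adjacent[:-1, :] = shrub[1:, :]
    adjacent &= ~shrub
    mask = np.zeros_like(shrub)
    if spec.shadow_fraction > 0 and adjacent.any():
        mask[adjacent] = rng.random(int(adjacent.sum())) < spec.shadow_fraction
    return mask


def render_rgb(truth: ClassRaster, spec: SceneSpec, seed: int | None = None) -> RGBRaster:
    """Draw each pixel's RGB from its class's spectral distribution.

    A seeded share of barren pixels uses the dark-soil sub-spectrum; the
    non-shrub mean is shifted toward dark soil by ``confusability``; shadow
    pixels are multiplied by ``SHADOW_FACTOR``.  Values clip to [0, 255].
    """
    if truth.data.size == 0:
        raise ValueError("truth raster is empty")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows, cols = truth.shape
    means = spec.effective_means()
    out = np.empty((rows, cols, 3), dtype=np.float32)
    labels = truth.data
    for c in (BARREN, NONSHRUB, SHRUB):
        m = labels == c
        n = int(m.sum())
        if n == 0:
            continue
        cov = np.asarray(spec.class_covs[c], dtype=float)
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(3))
        vals = means[c][None, :] + rng.standard_normal((n, 3)) @ L.T
        if c == BARREN and spec.dark_soil_fraction > 0:
            dark = rng.random(n) < spec.dark_soil_fraction
            vals[dark] += (np.asarray(spec.dark_soil_mean) - means[BARREN])[None, :]
        out[m] = vals.astype(np.float32)
    sh = shadow_mask(truth, spec, rng)
    out[sh] *= SHADOW_FACTOR
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return RGBRaster(data=out, gsd_m=truth.gsd_m, origin=truth.origin)


def resample_nearest(truth: ClassRaster, new_gsd_m: float) -> ClassRaster:
    """Nearest-neighbour resample of a class raster to a new GSD.

    Output pixel centres are mapped into the source grid by the half-open
    rule; the output covers the same metric extent (rounded to whole
    pixels).  Identity when the GSD is unchanged.
    """
    if new_gsd_m == truth.gsd_m:
        return ClassRaster(truth.data.copy(), truth.gsd_m, truth.origin)
    width, height = truth.extent_m
    new_cols = int(np.ceil(width / new_gsd_m - 1e-9))
    new_rows = int(np.ceil(height / new_gsd_m - 1e-9))
    src_rows, src_cols = truth.shape
    col_src = np.minimum(((np.arange(new_cols) + 0.5) * new_gsd_m / truth.gsd_m).astype(np.int64), src_cols - 1)
    row_src = np.minimum(((np.arange(new_rows) + 0.5) * new_gsd_m / truth.gsd_m).astype(np.int64), src_rows - 1)
    data = truth.data[np.ix_(row_src, col_src)]
    return ClassRaster(data=data, gsd_m=new_gsd_m, origin=truth.origin)


def simulate_study(
    spec: SceneSpec,
    design: SurveyDesign,
    altitudes_m: list[float],
    gsd_model: GsdModel | None = None,
) -> dict[float, SyntheticScene]:
    """One scene per flight altitude over the survey design's extent.

    A single truth map is generated at the spec's native GSD, then
    nearest-neighbour resampled to each altitude's GSD (from the GSD
    model); RGB is rendered per altitude with a seed derived from the scene
    seed and the altitude index, so the underlying landscape is identical
    across altitudes while sensor noise differs.
    """
    if any(a <= 0 for a in altitudes_m):
        raise ValueError("altitudes must be positive")
    if gsd_model is None:
        gsd_model = GsdModel(k=0.0016)
    native = generate_truth_map(spec, design.extent_m)
    scenes: dict[float, SyntheticScene] = {}
    for i, alt in enumerate(altitudes_m):
        gsd = gsd_model.gsd_m(alt)
        truth_a = resample_nearest(native, gsd)
        spec_a = replace(spec, gsd_m=gsd)
        rgb = render_rgb(truth_a, spec_a, seed=spec.seed + 1000 * (i + 1))
        scenes[alt] = SyntheticScene(rgb=rgb, truth=truth_a, spec=spec_a, altitude_m=alt)
    return scenes
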
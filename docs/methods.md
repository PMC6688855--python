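# Methods

## The assessment being emulated

A degraded supratidal salt marsh is surveyed two ways over the same grid of
92 adjacent 50×50 m cells (23 ha, five rectangular plots): a field crew
walks both diagonals of every cell recording the dominant cover underfoot
every metre (step-point method; 71 points per 70.71 m diagonal, 142 per
cell, 184 transects), and a fixed-wing drone images the plots at 75, 100
and 120 m AGL with a simple RGB camera. Cover is collapsed to three
classes — barren (0), non-shrub (1), shrub (2) — and the question is
whether the drone route reproduces the ground route's per-cell proportions.

Everything downstream of data collection is implemented here exactly as a
practitioner would run it; data collection itself is replaced by a seeded
synthetic landscape with known truth, so every stage is testable without
any imagery download.

## Survey geometry

Coordinates are planar metres, origin at the study SW corner. The default
design packs the five plots side by side as column blocks of a 23×4 cell
grid (widths 6/5/5/4/3 cells → 24/20/20/16/12 cells per plot), giving a
single 1150×200 m rectangle with no dead space. The real plots vary in
shape; only the totals (92 cells, 23 ha) enter any downstream computation,
and the partition is configurable.

The camera model is linear through the origin: gsd = k·altitude. The
surveyed camera corresponds to k = 0.00032 (2.4/3.2/3.8 cm at 75/100/120 m,
with half-away-from-zero rounding to one decimal); `GsdModel.paper_calibrated()`
reproduces it. The synthetic default uses k = 0.0016 (12/16/19.2 cm), which
keeps the three-altitude study at ≈31 Mpx total — desk scale — while
preserving the geometry of the comparison. Transect sample points sit at
arc length 0, s, 2s, … from the start corner ("approximately every meter"
is made exactly 1.000 m for determinism); the far corner is included only
when the diagonal length is an exact multiple of s, so 1 m spacing gives 71
points (0–70 m).

Pixel membership is stated once and reused everywhere: a point falls in
pixel ⌊u/gsd⌋ (half-open, left/top edge inclusive), a pixel belongs to the
cell containing its centre. This removes double counting on shared cell
edges. Points landing exactly on the raster's far edge are clamped onto the
last pixel so cell corners coincident with the raster boundary remain
sampleable.

## Synthetic landscape generator

**Truth.** White noise is smoothed with a Gaussian kernel of width
`spatial_corr_length_m` (default 6 m — patch scale of a mottled degraded
marsh) and split at its empirical quantiles so realized class proportions
match the targets (default 0.755/0.035/0.210 barren/non-shrub/shrub)
essentially exactly; the generator contract asserted in tests is ±0.02 per
class. Low field values become shrub, the middle band non-shrub, the rest
barren, which places non-shrub at shrub-patch margins — where graminoid
mats actually sit. One truth field is generated at the native (finest) GSD
and nearest-neighbour resampled to each altitude, so all altitudes image
the same landscape.

**RGB rendering.** Each pixel draws from its class's spectral distribution
(means: light sediment 150/135/115, graminoid mat 112/124/78, shrub canopy
55/88/52; default isotropic SD 18 per channel). Two calibrated error
mechanisms reproduce the failure modes documented for real mosaics:

* a `dark_soil_fraction` (0.25) of barren pixels renders from a dark
  sub-spectrum (78/70/60), and `confusability` c ∈ [0,1] moves the
  non-shrub mean toward that dark-soil spectrum by fraction c (c = 1 makes
  them coincide);
* a `shadow_fraction` (0.15) of pixels immediately north of shrub patches
  (fixed bearing, one-sided) is darkened by ×0.45.

Defaults (SD 18, c = 0.5) were calibrated so the default study lands in the
difficulty regime reported for real RGB mosaics of this system — overall
accuracy ≈ 0.9–0.96, κ ≈ 0.75–0.9, non-shrub nearly absent from the
classified maps and weakly correlated with ground — instead of a trivially
separable cartoon. What the generator does **not** emulate: radiometric
texture within patches, sun-angle/BRDF physics, mosaic seams and
structure-from-motion artifacts, species-level spectra, GPS error. Passing
tests therefore demonstrate the pipeline's statistical machinery and its
qualitative error structure, not radiometric realism.

## Classification

Lloyd's k-means (K = 30) with k-means++ seeding clusters raw RGB vectors —
no texture or position features. The implementation runs on the table of
unique colours weighted by pixel counts, which is algebraically identical
to per-pixel Lloyd (same seeding distribution, same centroid updates) and
is verified in tests against a naive per-pixel Lloyd from the same seeds.
Iteration stops at a 1e-4 relative drop in the within-cluster sum of
squares or 100 iterations. Plots are classified separately (light
conditions vary between real mosaics); the full pipeline fits each plot's
model on a seeded 200k-pixel subsample and predicts all pixels, as
sampling-based unsupervised classifiers do. If K exceeds the number of
distinct colours it is reduced with a warning.

The analyst's manual cluster inspection is replaced, openly, by a plurality
vote: each cluster maps to the class holding the most truth pixels among
its members (ties: barren > shrub > non-shrub; empty clusters → barren with
a warning). Real-data users supply a manual cluster→class map instead.

## Post-processing

1. **Majority filter** — each pixel takes the strict-majority class of its
   3×3 (or von Neumann) neighbourhood, centre included; no strict majority
   → unchanged; nodata ignored.
2. **Boundary clean** — per class, a 3×3 closing (dilate then erode) of the
   class mask; closed masks composited so classes earlier in the priority
   (default: descending area) win contested pixels; two iterations. This is
   a documented reimplementation of the proprietary expand/shrink tool's
   published behaviour, not a bit-parity clone.
3. **MMU sieve** — connected components (8-connected) smaller than 0.25 m²
   are dissolved; each removed pixel takes the class of the nearest
   surviving pixel (Euclidean distance between centres, per-class distance
   transforms, ties to the lowest class id). All sub-MMU patches in a pass
   are removed simultaneously against pre-pass survivors, making the result
   order-independent; passes repeat (≤10) until converged.

## Cover estimators

Per cell: `drone_pixels` divides class pixel counts by the cell's pixel
count n; `drone_transects` reads the classified raster at the same 142
step points the ground crew would use ("approximately the same transects"
is made exactly the design transects, which is what makes the comparison
testable). Ground simulation reads the truth raster at those points, with
an optional uniform-confusion observer error (default 0). All three emit
one long-form table (cell × method × altitude × class, proportion, n);
proportions sum to 1 per group by construction. A transect is a line
sample: as spacing → 0 it converges to the line-integral class fractions
along the diagonals, which differ from the cell-area proportions by a
sampling-design gap (typically < 0.05 mean absolute per-cell difference on
the default landscape) — tests assert the convergence and bound the gap.

## Accuracy assessment

Per plot, 100 assessment points stratified by mapped class with counts
proportional to class area (largest-remainder apportionment — "proportional"
is not otherwise pinned down), drawn uniformly without replacement within
class; 500 points per altitude. The synthetic truth raster stands in for
the photointerpreter. From the 3×3 confusion matrix (rows mapped, columns
reference): OA = trace/total, κ = (p_o − p_e)/(1 − p_e) with p_e from the
marginals (degenerate single-class matrices report κ = 0 with a warning),
omission_c = 1 − diag_c/col_c, commission_c = 1 − diag_c/row_c. Per-plot
metrics are summarised as mean, sample SD (n−1), min, max; a single plot
reports SD 0 with a flag.

## Beta GLMM

Responses are Smithson–Verkuilen transformed per cell with that row's own
n (142 for transect methods, the cell pixel count for `drone_pixels`), then
modelled as Beta(μ, φ) in mean–precision form with logit link, one
treatment-coded categorical fixed factor (altitude, baseline 75 m; or
method, baseline ground) and a Gaussian random cell intercept. φ is common
across observations (single-scale model).

Fitting is maximum marginal likelihood: per cell the random effect is
integrated out by adaptive Gauss–Hermite quadrature (15 nodes; the
integrand is re-centred at the cell's conditional mode, found by a
safeguarded vectorised Newton iteration with analytic first and second
derivatives, and rescaled by its curvature). Doubling the nodes moves β̂ by
< 1e-4 (asserted). The outer optimizer is L-BFGS-B on (β, log σ², log φ)
from the fixed start β = 0, σ² = 0.5, φ = 10, with bounds keeping the
likelihood finite; non-finite evaluations return a large penalty so the
line search backtracks. Standard errors come from the inverse
finite-difference observed information (σ² and φ by delta method from the
log scale); a σ² estimate at its lower bound is flagged but returned.

The Wald F for the fixed factor is (Lβ̂)'(LV̂L')⁻¹(Lβ̂)/rank(L) with a
containment-style denominator df N − n_cells − (p−1), which is 182 for 276
observations on 92 cells with a 3-level factor — matching the table
structure this reproduces. The dispersion diagnostic is conditional Pearson
χ² (residuals at the empirical-Bayes modes, Var(y|b) = μ(1−μ)/(1+φ))
divided by N − p − n_cells; with ~one df absorbed per cell this sits near 1
for well-specified fits. Exact numeric parity with other engines is a soft
goal: cross-engine agreement with glmmTMB on identical data is asserted at
5e-3 on β and 5% on σ² and φ.

Calibration, computed fresh by both the test suite and the acceptance
script over 200 simulated 92-cell studies (β = (0.5, 0.3, −0.4), σ² = 0.7,
φ = 40): fixed-effect bias within 3 Monte-Carlo SE, 95% Wald(t₁₈₂)
interval coverage in [0.90, 0.99], and type-I error of the Wald F at
nominal 0.05 within [0.03, 0.08] under a null simulation.

## Problem sizes and determinism

The default study runs at 12/16/19.2 cm GSD (≈16 + 9 + 6 Mpx), chosen as
the package's desk-scale default; the k-means subsample is 200k pixels per
plot. Tests use reduced designs (e.g. two plots × 4 cells at 25–50 cm GSD)
wherever the property under test does not need the full grid; the
noiseless-separable end-to-end check runs at 15–24 cm pixels because the
0.25 m² MMU sieve presumes pixel area ≪ MMU — at ~0.5 m pixels the sieve
would dissolve true single-pixel patches and the check would measure the
scale mismatch, not the classifier. All
randomness fans out from one master seed through named SHA-256 substreams
(`stage_seed`), so stages re-run identically in isolation and two full runs
produce hash-identical manifests.

## Known limitations

* The unsupervised clusterer is k-means, a stand-in from the same family
  as the ISO-cluster tool used in GIS packages; iteration counts and
  sample fractions of the original tool are unpublished, so no parity is
  claimed.
* Plurality reclassification against truth is an optimistic analyst: it
  cannot mislabel a cluster whose membership is dominated by one class,
  whereas a human can. Accuracy numbers are therefore upper-bound-ish for
  a given spectral difficulty, which is why difficulty itself is calibrated.
* The deposited per-cell table carries no per-cell n; `read_s1_data`
  defaults n to the design value 142, so exact reproduction of published
  model tables from that file is not guaranteed for the pixel-count method.
* Proportions near 0 make the beta GLMM's non-shrub dispersion exceed 1 on
  the default scene (the class is mapped almost constant-zero); this is a
  property of the degenerate data, reported, not corrected.
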
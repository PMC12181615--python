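# Methods

This note documents the models, parameter choices and numerical details
behind `cmhq`, and what the synthetic validation does and does not show
about real histology.

## The measurement problem

A whole mouse brain is paraffin-sectioned at 8 µm with a 2-of-5
retain/discard scheme (mean axial spacing 8 × 5/2 = 20 µm), stained with
hematoxylin (blue, tissue) and DAB (dark brown, extravasated red blood
cells), scanned in brightfield and downscaled for analysis. The target
quantities per brain are: microbleed count, bleed area as a percentage of
tissue cross-section area, and bleed density per mm² of tissue. The
difficulty is scale (hundreds of sections per brain) and the failure
modes of simple thresholding: dust and debris are as dark as DAB, tissue
staining intensity varies section to section, and each section lands on
its slide with its own small rotation and shift.

## Staining model and color transforms

Beer–Lambert absorption: `I_c = I0_c · 10^(−Σ_s conc_s V[s,c])` with
unit-norm stain OD vectors as rows of `V`. Defaults: Ruifrok–Johnston
HDAB — hematoxylin ≈ (0.650, 0.704, 0.286), DAB ≈ (0.269, 0.568, 0.778),
residual = normalized cross product of the two. The rows are *not*
orthogonal; the residual row only completes the basis, and its
"concentration" is diagnostic. `I0` defaults to (255, 255, 255) with a
99th-percentile per-slide estimate available. Intensities are clipped to
≥ 1 DN before the log, so saturated black maps to finite OD.

Quantization: with 8-bit images the rounding error perturbs OD by about
`0.217/I` per channel, which the unmixing amplifies by the inverse-matrix
norm. The round trip `deconvolve(rgb_to_od(reconstruct_rgb(C)))` is exact
to machine precision without quantization and good to ~0.02 in
concentration for physical two-stain fields up to concentration 1.0; at
total OD ≳ 2 (intensities of a few DN) no useful bound exists. Tests and
the acceptance script check both regimes accordingly.

YIQ uses the classic NTSC matrix; the transform is linear and exact in
floats. On the signed I axis (orange ↔ blue chrominance), DAB is strictly
positive (≈ +30 to +50 for typical concentrations), hematoxylin negative
(≈ −10 to −18), neutral gray/black ≈ 0. This is the entire basis of the
YIQ method's artifact robustness.

## Classic segmentation

Both classic methods share: Otsu threshold (256 equal bins over
[min, max], between-class variance `w0·w1·(µ0−µ1)²`, ties to the lowest
threshold, bin-edge return convention, foreground = value > threshold),
hole filling, and particle analysis (connected components at 8- or
4-connectivity, area = pixels × pixel_size², default minimum object size
10 µm² to drop single-pixel noise — a documented addition, as classical
interactive workflows state no size cut).

* **hdab**: DAB concentration channel → difference-of-Gaussians bandpass
  with σ = size/2 for sizes (50, 2) px — a testable stand-in for
  interactive FFT bandpass filters, whose kernels have no published
  closed form — → Otsu → fill holes. The bandpass hollows out large
  objects into rings; hole filling restores them to disks. Neutral dark
  debris unmixes with DAB coefficient ≈ 0.84 per unit OD, so this method
  *over-counts* on dirty slides; on bleed-free noisy sections Otsu
  fragments the noise floor into many spurious objects. Both behaviors
  are deliberate properties of the method being studied, not bugs.
* **yiq**: I channel → Otsu with two guards. (1) The operating threshold
  is clipped to an achromatic margin (+5, a few sensor-noise standard
  deviations on I): DAB chroma is strictly positive, so a threshold below
  zero chrominance can only admit noise. (2) The mask is intersected with
  a tissue mask estimated from the image (any channel < 240): a global
  Otsu on the three-population histogram (tissue < background < bleeds)
  may split tissue-vs-background instead of bleeds-vs-rest, and the
  intersection yields the bleed population in either case. With these
  guards the method is exact on synthetic material and near-immune to
  neutral debris.

A blank slide yields an empty mask from `segment_hdab` and a
degenerate-input error from `segment_yiq` (an achromatic image has no
chrominance contrast to threshold).

## Random-forest pixel classification

Features per RGB channel: identity, Gaussian blur σ ∈ {1, 2, 4, 8},
gradient magnitude (σ 1), Laplacian (σ 1), min/max/variance in a
radius-2 box — 30 features. Forest: 100 trees, unlimited depth, √p
features per split, seed 42; these stand in for an interactive trainable-
segmentation tool whose exact settings are unpublished. Annotations are
sparse point sets per class; training keeps every bleed pixel and caps
background/tissue at 5× the bleed count, operationalizing the small-bleed
bias (the rare class is never swamped). The serialized model embeds a
hash of its feature descriptor and refuses to load against a different
extractor. Inference is deterministic.

## Registration

Rigid transforms (rotation about canvas center + translation) are
estimated by minimizing mean squared intensity difference over a 3-level
pyramid (block-mean ×4, ×2, ×1) with Powell's method, after Gaussian
pre-smoothing (σ 1.5) so label maps present a smooth cost surface.
Translation is initialized from foreground centroids and rotation from a
±12° coarse scan at the lowest resolution — without this, silhouettes
with weak rotational texture can trap MSE in local minima. Measured
recovery on synthetic pairs: ≲ 0.5 px, ≲ 0.3°.

Stacks are aligned sequentially (each section to its aligned
predecessor) in batches of 10 new sections plus 2 frozen carried
references — the reference carry-over scheme that keeps long stacks
consistent without re-transforming previous batches; a trailing short
remainder merges with the references. A reverse pass re-aligns the
reversed stack to relax monotone drift and is kept only if it improves
the mean consecutive-centroid-drift metric (on an already-converged
stack it would only add resampling jitter). Label maps always warp with
nearest-neighbour interpolation; class codes never blend.

Known limitation: when consecutive sections differ strongly in silhouette
(coarse stacks sampling the whole brain in a handful of sections, ≳ 10%
outline change per step), the rotation component becomes ill-posed for
an MSE criterion and individual pairs can misregister. At the realistic
sampling the pipeline targets (tens of sections, small inter-section
change) stack drift after alignment is ~0.1–0.2 px.

## 3D assembly and quantification

Majority-vote ×5 downscaling with ties resolved toward the higher code,
so small bleeds survive reduction. The brain envelope is the largest 3D
connected component of the Gaussian-smoothed (σ 2 voxels) tissue
occupancy field thresholded at 0.5 — a surface-segmentation stand-in
with the same contract (closed smooth envelope, excludes extratissular
specks); commercial tools' parameters for this step are unpublished.
The voxelwise minimum overlay zeroes codes outside the envelope and can
only reduce class counts. Volume assembly is an exact restack (class
counts conserved identically); z-spacing defaults to 20 µm.

Quantification: tissue area per section = (tissue + bleed) pixels ×
(pixel/1000)² mm²; area fraction = 100 × bleed/tissue area; density =
2D object count / tissue mm². Density deliberately counts per-section 2D
objects — the unit a histologist counts — with a separate 3D-merged
component count available (`count_objects_3d`); aggregates are summed,
i.e. tissue-area-weighted means. The area-fraction denominator is tissue
area (not whole-image area), consistent with density being normalized to
tissue.

## Statistics

Method comparison: per-section method/reference ratios (both-zero
sections count as ratio 1; reference-zero/method-positive sections are
excluded from means and reported — exclusion avoids infinite ratios
skewing means). One-way ANOVA across methods with Dunnett's many-to-one
test against the reference (scipy's multivariate-t implementation);
Shapiro–Wilk and Brown–Forsythe (median-centered Levene) diagnostics.

Group comparison: Kruskal–Wallis with an exact permutation p-value when
total N ≤ 12 — at 3 groups of 3 the χ² approximation cannot fall below
p ≈ 0.039 even under complete separation, so small-sample designs need
the exact distribution (1 680 assignments, enumerated from precomputed
rank sums). Follow-up is Dunn's rank-based z against the control with
Holm correction; this is the rank analogue of a Dunnett-style contrast
set (a parametric Dunnett test does not apply to ranks, although some
published workflows use that name after a Kruskal–Wallis omnibus).

A hard limit worth knowing: with 3 brains per group no two-sided
nonparametric pairwise test can reach p < 0.05 (minimum exact p = 0.1),
and even the exact omnibus detects a 10× burden difference only ~half
the time when two of the three groups are equal. Per-brain sample sizes
of that order support estimation, not confident hypothesis testing.

## Synthetic study conditions

The generator's defaults define the validation conditions: 256 × 320 px
sections at 1.725 µm/px (a 0.345 µm/px 40× scan downscaled to 20%; the
native scanner resolution is an assumption and is configurable), 40
sections sharing one 3D silhouette (harmonically perturbed ellipse with
a ventricle hole, axial scale profile), 30 planted bleeds — 20 small
(< 50 µm) and 10 large (> 100 µm), the 2:1 training mix, stratified with
2.5 µm guard bands and large bleeds spread round-robin over sections —
hematoxylin concentration 0.35 with 15% smooth spatial texture and 10%
CV per-section jitter, DAB concentration 1.0, one neutral-density
boundary speck per section on average (OD 1.2–2.2, radius 2–4 px),
misalignment bounded by ±10 px / ±5°, Gaussian sensor noise σ 2 DN added
after staining. Ground truth (masks, object table, true transforms) is
exact and pre-noise; geometry is rasterized in the misaligned frame by
evaluating shape functions at inverse-transformed coordinates, so no
resampling error enters the truth. Identical configs are byte-identical.

Problem sizes used in tests and the acceptance script (40-section
brains, 5 seeds for recovery runs, 12-section artifact-rich stacks,
1 000 null simulations) were chosen as the smallest sizes at which each
property is meaningfully exercised.

**What passing does and does not show.** The synthetic bleeds are
hard-edged, uniformly stained ellipses on a clean white background, and
the color model is exactly the one the deconvolution inverts. Passing
therefore demonstrates internal correctness (exact algebra, oracle-equal
primitives, geometric recovery, calibrated statistics) and the
*mechanisms* of the method differences — neutral debris inflating the
DAB channel but not the I channel. It does not demonstrate performance
on real slides, where stain vectors drift, bleed edges are diffuse and
the classifier's area estimates are known to degrade: on real material
the random forest under-estimates bleed area, a behaviour the clean
synthetic conditions do not reproduce (here its area ratio is ≈ 1.01).
Scanner shading, focus artifacts and vascular structures are likewise
not modelled.
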
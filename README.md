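# cmhq — cerebral microhemorrhage quantification in stained brain sections

`cmhq` is a scriptable pipeline for detecting, counting and 3D-mapping
**cerebral microhemorrhages (CMHs)** — small focal brain bleeds from
ruptured microvessels — in serial coronal brain sections stained with
hematoxylin (blue tissue counterstain) and DAB (dark-brown precipitate
marking red-blood-cell peroxidases). It is aimed at preclinical
neurovascular labs that section whole mouse brains (~8 µm sections,
2-of-5 sampling), scan them in brightfield, and need per-brain microbleed
burden — count, area fraction, and density per mm² of tissue — without
weeks of manual counting.

Because no public dataset of such slides exists, the package ships a
first-class **synthetic slide generator** that renders stained sections
through an exact Beer–Lambert staining model with pixel-perfect ground
truth, so every pipeline stage is verifiable end to end at desk scale.

## Methods at a glance

**Stain separation.** Under Beer–Lambert absorption, transmitted
intensity is `I_c = I0_c · 10^(−Σ_s conc_s · V[s,c])` for unit-norm stain
OD vectors `V` (hematoxylin, DAB, residual). Taking the optical density
`OD_c = −log10(I_c / I0_c)` makes stains additive, and concentrations are
recovered by linear unmixing `conc = OD · V⁻¹` (color deconvolution,
Ruifrok–Johnston HDAB vectors by default). Alternatively, the NTSC YIQ
transform maps RGB to luma and two chrominance axes; the **I channel**
(orange ↔ blue) is positive for brown DAB and negative for blue
hematoxylin, so one scalar channel isolates bleeds.

**Segmentation.** Three interchangeable methods produce binary bleed
masks that feed a shared particle analysis (connected components, area
calibration in µm², size filter):

* `hdab` — deconvolution → DAB channel → difference-of-Gaussians
  bandpass (50/2 px) → Otsu threshold → fill holes. Sensitive but
  artifact-prone: neutral dark debris unmixes with a spurious DAB
  component and inflates counts.
* `yiq` — YIQ → I channel → Otsu (clipped to the achromatic point) →
  tissue restriction → fill holes. Robust to neutral debris.
* `ml` — a LABKIT-style random-forest pixel classifier (three classes:
  0 background / 1 tissue / 2 bleed) trained from sparse annotations on
  a multi-scale filter bank, with class-balanced sampling biased toward
  the rare bleed class.

**Alignment and 3D burden.** Label maps are centered on a common canvas,
rigidly aligned section-to-section (MSE minimization over a 3-level
pyramid) in batches of 10 with 2 carried reference sections, majority-
vote downscaled (×5, ties favor bleeds), cleaned through a smooth 3D
brain-surface mask (voxelwise minimum), refined by a reverse alignment
pass, and stacked into an anisotropic volume (default z-spacing 20 µm =
8 µm × 5/2 sampling). Quantification reports per-section and aggregate
tissue area (mm²), bleed area fraction (%), and density (objects/mm²).

**Method comparison.** Per-section count/area ratios to a reference
counting, one-way ANOVA with Dunnett many-to-one comparisons,
Shapiro–Wilk and Brown–Forsythe diagnostics; group burden comparisons use
Kruskal–Wallis (exact permutation enumeration for very small samples)
with a rank-based many-to-one follow-up.

## Worked example

```bash
cmhq generate --out data --seed 11 --n-sections 8 --n-bleeds 8
cmhq segment  --data data --out seg --method yiq
cmhq align    --labels data --out recon
```

The generate step writes 8 stained sections (`sec_0000.tif` …) with
ground-truth masks and an object table; segment writes one mask and
particle table per section; align reports

```
INFO cmhq: drift 10.38 px -> 0.20 px; aggregate: {'section': 'aggregate',
  'tissue_area_mm2': 0.738, 'bleed_area_um2': 46270.97, 'bleed_count': 8,
  'area_fraction_pct': 6.269, 'density_per_mm2': 10.839}
```

i.e. the planted ±10 px / ±5° section misalignments were reduced to
0.20 px mean centroid drift, all 8 planted bleeds were recovered, and the
brain carries 10.8 microbleeds per mm² of tissue occupying 6.3% of the
cross-sectional area. The tail of `recon/quantification.csv`:

```
  section  tissue_area_mm2  bleed_area_um2  bleed_count  area_fraction_pct  density_per_mm2
        7         0.077069    15547.640625            1          20.173745        12.975438
aggregate         0.738104    46270.968750            8           6.268897        10.838584
```

## Layout

| module | role |
| --- | --- |
| `cmhq.synthetic_slides` | synthetic stained serial stacks + ground truth |
| `cmhq.stain_models` | OD color deconvolution, Beer–Lambert forward model, YIQ |
| `cmhq.segmentation_classic` | hdab/yiq pipelines, Otsu, particle analysis |
| `cmhq.segmentation_ml` | random-forest pixel classifier, batch segmentation |
| `cmhq.registration` | canvas standardization, batched rigid alignment |
| `cmhq.volume3d` | downscale, brain mask, volume assembly, quantification |
| `cmhq.compare` | ratio-to-reference harness, statistics, timing |
| `cmhq.cli` | `cmhq generate/train/segment/align/quantify/compare` |

See `docs/methods.md` for the full model description, parameter defaults
and known limitations.
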
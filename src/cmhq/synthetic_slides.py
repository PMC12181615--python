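"""Synthetic serial stacks of hematoxylin/DAB-stained coronal sections.

Real material for this problem is a serial stack of brightfield images of
8-um coronal mouse brain sections: pale blue hematoxylin-counterstained
tissue on a white background, with microhemorrhages appearing as compact
dark-brown DAB blobs from below 50 um to above 100 um in diameter, plus
the usual nuisances — ventricles (holes inside the tissue), section-to-
section staining intensity variation, dark dust/debris specks near tissue
edges, and a random rigid misalignment of every section on its slide.

This module emulates all of that with exact per-pixel ground truth:

* One smooth 3-D tissue silhouette is shared by the whole stack and
  sampled along the rostro-caudal axis (a low-order harmonic perturbation
  of an ellipse, with an interior ventricle hole). No anatomical atlas
  fidelity is attempted.
* Bleeds are planted as near-circular ellipses (area-preserving axis
  jitter), stratified into a small (<50 um) and a large (>100 um) diameter
  class; the default 2:1 small:large mix mirrors the composition used to
  train the pixel classifier (about 20 small and 10 large bleeds).
* Staining is rendered through the exact Beer-Lambert forward model of
  :mod:`cmhq.stain_models`, so OD deconvolution is algebraically invertible
  on noise-free output.
* Artifacts are neutral-density (gray/black) specks near the tissue
  boundary: they carry high total OD but no genuine DAB chromaticity, so
  they fool stain-agnostic intensity thresholds (and leak into the DAB
  channel of a linear unmixing) while remaining invisible to
  chrominance-based segmentation — reproducing the over-counting failure
  mode of raw color deconvolution.
* Every section is perturbed by a bounded random rigid transform; geometry
  is evaluated at inverse-transformed pixel coordinates, so masks are
  rasterized exactly in the final frame (no resampling error) and the true
  transform is recorded.

Gaussian sensor noise (default sigma 2 DN) is added after staining
synthesis; ground truth is pre-noise. Identical configs (including seeds)
produce byte-identical stacks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage

from .errors import ConfigurationError
from .registration import RigidTransform
from .stain_models import StainMatrix

__all__ = [
    "SlideSimConfig",
    "SectionTruth",
    "StackTruth",
    "generate_section",
    "generate_stack",
    "write_stack",
]

# Diameter class boundaries used for the stratified small/large bleed mix.
SMALL_BLEED_UM = 50.0
LARGE_BLEED_UM = 100.0


@dataclass(frozen=True)
class SlideSimConfig:
    """Study conditions for one synthetic serial stack.

    ``pixel_size_um`` defaults to 1.725 um/px: a 0.345 um/px 40x scan
    downscaled to 20% (the scanner resolution itself is an assumption; the
    acquisition protocol states the objective and the downscale factor but
    not the native um/px — configurable).
    """

    image_size_px: tuple = (256, 320)
    pixel_size_um: float = 1.725
    n_sections: int = 40
    tissue_shape_seed: int = 0
    n_bleeds_total: int = 30
    bleed_diameter_range_um: tuple = (20.0, 150.0)
    small_large_mix: float = 2.0 / 3.0  # fraction of bleeds below 50 um
    artifact_rate: float = 1.0          # expected artifact specks per section
    stain_intensity_jitter: float = 0.1  # CV of per-section stain scaling
    misalignment_translation_px: float = 10.0  # max |shift| per axis
    misalignment_rotation_deg: float = 5.0     # max |angle|
    rng_seed: int = 0
    noise_sigma: float = 2.0            # Gaussian sensor noise, DN
    hematoxylin_conc: float = 0.35
    dab_conc: float = 1.0
    section_thickness_um: float = 8.0
    sections_retained: int = 2          # 2-of-5 sampling scheme
    sections_discarded: int = 3

    def validate(self) -> None:
        rows, cols = self.image_size_px
        if rows < 64 or cols < 64:
            raise ConfigurationError("image_size_px: canvas must be >= 64x64")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be > 0")
        if self.n_sections < 1:
            raise ConfigurationError("n_sections must be >= 1")
        if self.n_bleeds_total < 0:
            raise ConfigurationError("n_bleeds_total must be >= 0")
        lo, hi = self.bleed_diameter_range_um
        if lo <= 0 or hi <= lo:
            raise ConfigurationError(
                "bleed_diameter_range_um must satisfy 0 < min < max")
        if not 0.0 <= self.small_large_mix <= 1.0:
            raise ConfigurationError("small_large_mix must lie in [0, 1]")
        n_small = round(self.n_bleeds_total * self.small_large_mix)
        if n_small > 0 and lo >= SMALL_BLEED_UM:
            raise ConfigurationError(
                "bleed_diameter_range_um min must be < 50 um to allow the "
                "small bleed class")
        if self.n_bleeds_total - n_small > 0 and hi <= LARGE_BLEED_UM:
            raise ConfigurationError(
                "bleed_diameter_range_um max must be > 100 um to allow the "
                "large bleed class")
        if self.artifact_rate < 0:
            raise ConfigurationError("artifact_rate must be >= 0")
        if self.stain_intensity_jitter < 0:
            raise ConfigurationError("stain_intensity_jitter must be >= 0")
        if self.misalignment_translation_px < 0:
            raise ConfigurationError("misalignment_translation_px must be >= 0")
        if self.misalignment_rotation_deg < 0:
            raise ConfigurationError("misalignment_rotation_deg must be >= 0")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")

    @property
    def z_spacing_um(self) -> float:
        """Mean axial spacing implied by the retain/discard sampling scheme."""
        cycle = self.sections_retained + self.sections_discarded
        return self.section_thickness_um * cycle / self.sections_retained

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "SlideSimConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        for key in ("image_size_px", "bleed_diameter_range_um"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class SectionTruth:
    """Pixel-exact ground truth for one generated section."""

    section_index: int
    tissue_mask: np.ndarray      # bool; includes bleed pixels
    bleed_labels: np.ndarray     # uint16; 0 = none, else global object id
    transform: RigidTransform    # true planted misalignment
    objects: pd.DataFrame        # id, section, x_px, y_px, diameter_um, area_um2

    @property
    def label_map(self) -> np.ndarray:
        """Class-code view: 0 = background, 1 = tissue, 2 = bleed."""
        out = np.zeros(self.tissue_mask.shape, dtype=np.uint8)
        out[self.tissue_mask] = 1
        out[self.bleed_labels > 0] = 2
        return out


@dataclass
class StackTruth:
    sections: list

    @property
    def objects(self) -> pd.DataFrame:
        frames = [s.objects for s in self.sections if len(s.objects)]
        if not frames:
            return _empty_objects()
        return pd.concat(frames, ignore_index=True)

    @property
    def transforms(self):
        return [s.transform for s in self.sections]

    def label_stack(self):
        return [s.label_map for s in self.sections]


def _empty_objects() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["id", "section", "x_px", "y_px", "diameter_um", "area_um2"]
    ).astype({"id": int, "section": int})


# ---------------------------------------------------------------------------
# geometry


def _shape_params(config: SlideSimConfig) -> dict:
    rng = np.random.default_rng(
        np.random.SeedSequence([config.tissue_shape_seed, 7001]))
    ks = np.arange(2, 6)
    return {
        "amps": rng.uniform(-0.05, 0.05, size=ks.size),
        "ks": ks,
        "phases": rng.uniform(0, 2 * np.pi, size=ks.size),
        # ventricle: interior hole, offset above center, scales with section
        "hole_cy": -0.30, "hole_cx": 0.0,   # in units of semi-axes
        "hole_ry": 0.20, "hole_rx": 0.12,   # in units of semi-axes
    }


def _section_scale(i: int, n: int) -> float:
    if n == 1:
        return 1.0
    return 0.78 + 0.22 * float(np.sin(np.pi * (i + 0.5) / n))


def _semi_axes(config: SlideSimConfig):
    rows, cols = config.image_size_px
    return 0.38 * rows, 0.40 * cols  # (b rows, a cols)


def _tissue_indicator(y, x, config, shape, scale):
    """Evaluate the tissue silhouette at centered (row, col) offsets."""
    b, a = _semi_axes(config)
    u, v = y / b, x / a
    rho = np.hypot(u, v)
    theta = np.arctan2(u, v)
    boundary = scale * (1.0 + sum(
        amp * np.cos(k * theta + ph)
        for amp, k, ph in zip(shape["amps"], shape["ks"], shape["phases"])))
    inside = rho <= boundary
    hy = (y - shape["hole_cy"] * b * scale) / (shape["hole_ry"] * b * scale)
    hx = (x - shape["hole_cx"] * a * scale) / (shape["hole_rx"] * a * scale)
    hole = hy * hy + hx * hx <= 1.0
    return inside & ~hole


def _plan_bleeds(config: SlideSimConfig) -> pd.DataFrame:
    """Deterministic global plan: object id, host section, planted diameter.

    Diameters are stratified: round(mix * total) objects from the small
    class (uniform on [min, 47.5] um) and the rest from the large class
    (uniform on [102.5, max] um); the 2.5 um guard bands keep realized
    equivalent diameters clearly inside their class after rasterization.
    Large bleeds are spread round-robin over distinct sections so that a
    single section never has to pack several >100 um objects.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 901]))
    total = config.n_bleeds_total
    n_small = round(total * config.small_large_mix)
    n_large = total - n_small
    lo, hi = config.bleed_diameter_range_um
    d_small = rng.uniform(lo, min(SMALL_BLEED_UM - 2.5, hi), size=n_small)
    d_large = rng.uniform(max(LARGE_BLEED_UM + 2.5, lo), hi, size=n_large)
    sections_large = [
        int(s) for s in rng.permutation(config.n_sections)[
            np.arange(n_large) % config.n_sections]
    ] if n_large else []
    sections_small = rng.integers(0, config.n_sections, size=n_small)
    rows = []
    for i, (sec, d) in enumerate(zip(sections_large, d_large)):
        rows.append({"id": i + 1, "section": sec, "diameter_um": float(d)})
    for i, (sec, d) in enumerate(zip(sections_small, d_small)):
        rows.append({"id": n_large + i + 1, "section": int(sec),
                     "diameter_um": float(d)})
    plan = pd.DataFrame(rows, columns=["id", "section", "diameter_um"])
    return plan.astype({"id": int, "section": int}) if len(plan) else plan


def _sample_rigid(config: SlideSimConfig, rng) -> RigidTransform:
    t = config.misalignment_translation_px
    r = config.misalignment_rotation_deg
    return RigidTransform(
        angle_deg=float(rng.uniform(-r, r)) if r > 0 else 0.0,
        drow=float(rng.uniform(-t, t)) if t > 0 else 0.0,
        dcol=float(rng.uniform(-t, t)) if t > 0 else 0.0,
    )


def _smooth_field(rng, shape, sigma=10.0) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    peak = np.max(np.abs(f))
    return f / peak if peak > 0 else f


def generate_section(config: SlideSimConfig, section_index: int,
                     stains: StainMatrix | None = None):
    """Generate one section image and its pixel-exact ground truth.

    Returns ``(image, SectionTruth)`` where ``image`` is 8-bit RGB.
    """
    config.validate()
    if not 0 <= section_index < config.n_sections:
        raise ConfigurationError(
            "section_index must satisfy 0 <= index < n_sections")
    stains = stains or StainMatrix.hdab()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed, 1000 + section_index]))
    rows, cols = config.image_size_px
    shape = _shape_params(config)
    scale = _section_scale(section_index, config.n_sections)
    ctr = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])

    # --- canonical-frame rasterization, used only to sample placements
    yy, xx = np.mgrid[0:rows, 0:cols]
    y0, x0 = yy - ctr[0], xx - ctr[1]
    tissue_canon = _tissue_indicator(y0, x0, config, shape, scale)
    dist_in = ndimage.distance_transform_edt(tissue_canon)
    dist_out = ndimage.distance_transform_edt(~tissue_canon)

    # --- plant bleeds assigned to this section (large first)
    plan = _plan_bleeds(config)
    mine = plan[plan["section"] == section_index] if len(plan) else plan
    mine = mine.sort_values("diameter_um", ascending=False) if len(mine) else mine
    bleeds = []  # (id, cy, cx, ax_r, ax_c, angle, diameter_um)
    for _, rec in mine.iterrows():
        r_px = 0.5 * rec["diameter_um"] / config.pixel_size_um
        ok = dist_in > (r_px + 3.0)
        for prev in bleeds:
            ok &= (np.hypot(yy - prev[1], xx - prev[2])
                   > r_px + max(prev[3], prev[4]) + 4.0)
        cand = np.flatnonzero(ok)
        if cand.size == 0:
            raise ConfigurationError(
                "could not place a %.0f um bleed in section %d; the tissue "
                "cross-section is too small for the configured bleed load"
                % (rec["diameter_um"], section_index))
        pick = int(rng.choice(cand))
        cy = yy.flat[pick] + rng.uniform(-0.5, 0.5)
        cx = xx.flat[pick] + rng.uniform(-0.5, 0.5)
        ecc = rng.uniform(0.92, 1.08)  # area-preserving axis jitter
        bleeds.append((int(rec["id"]), cy, cx, r_px * ecc, r_px / ecc,
                       rng.uniform(0, np.pi), float(rec["diameter_um"])))

    # --- artifacts: neutral-density specks hugging the tissue boundary
    n_art = int(rng.poisson(config.artifact_rate))
    artifacts = []  # (cy, cx, radius, od_amplitude)
    near_edge = ((dist_out > 0) & (dist_out < 12)) | \
                ((dist_in > 0) & (dist_in < 5))
    for _ in range(n_art):
        ok = near_edge.copy()
        for b in bleeds:
            ok &= np.hypot(yy - b[1], xx - b[2]) > max(b[3], b[4]) + 9.0
        cand = np.flatnonzero(ok)
        if cand.size == 0:
            break
        pick = int(rng.choice(cand))
        artifacts.append((float(yy.flat[pick]), float(xx.flat[pick]),
                          float(rng.uniform(2.0, 4.0)),
                          float(rng.uniform(1.2, 2.2))))

    # --- planted misalignment; evaluate geometry at inverse-mapped coords
    tf = _sample_rigid(config, rng)
    minv = np.linalg.inv(tf.matrix((rows, cols)))
    q = np.stack([yy, xx, np.ones_like(yy)], axis=-1) @ minv.T
    qy, qx = q[..., 0] - ctr[0], q[..., 1] - ctr[1]

    tissue = _tissue_indicator(qy, qx, config, shape, scale)
    bleed_labels = np.zeros((rows, cols), dtype=np.uint16)
    for oid, cy, cx, ar, ac, ang, _d in bleeds:
        dy = (qy + ctr[0]) - cy
        dx = (qx + ctr[1]) - cx
        ca, sa = np.cos(ang), np.sin(ang)
        e1 = (dy * ca + dx * sa) / ar
        e2 = (-dy * sa + dx * ca) / ac
        inside = (e1 * e1 + e2 * e2 <= 1.0) & tissue  # containment exact
        bleed_labels[inside] = oid

    artifact_od = np.zeros((rows, cols), dtype=float)
    for cy, cx, rad, amp in artifacts:
        dy = (qy + ctr[0]) - cy
        dx = (qx + ctr[1]) - cx
        artifact_od[dy * dy + dx * dx <= rad * rad] = amp

    # --- staining synthesis (Beer-Lambert forward model)
    jit = config.stain_intensity_jitter
    j_h = float(np.exp(rng.normal(0.0, jit))) if jit > 0 else 1.0
    j_d = float(np.exp(rng.normal(0.0, jit))) if jit > 0 else 1.0
    texture = _smooth_field(rng, (rows, cols))
    hema = np.where(tissue,
                    config.hematoxylin_conc * j_h * (1.0 + 0.15 * texture),
                    0.0)
    # bleeds retain a reduced hematoxylin floor (tissue beneath the deposit)
    hema = np.where(bleed_labels > 0, 0.25 * config.hematoxylin_conc * j_h,
                    hema)
    dab = np.where(bleed_labels > 0, config.dab_conc * j_d, 0.0)

    od = (hema[..., None] * stains.matrix[0]
          + dab[..., None] * stains.matrix[1]
          + artifact_od[..., None])
    img = 255.0 * np.power(10.0, -od)
    if config.noise_sigma > 0:
        img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    # --- per-object records measured on the final rasterized labels
    recs = []
    px_area = config.pixel_size_um ** 2
    for oid, cy, cx, _ar, _ac, _ang, d_um in bleeds:
        pix = bleed_labels == oid
        n_pix = int(pix.sum())
        center = tf.matrix((rows, cols)) @ np.array([cy, cx, 1.0])
        recs.append({"id": oid, "section": section_index,
                     "x_px": float(center[1]), "y_px": float(center[0]),
                     "diameter_um": d_um, "area_um2": n_pix * px_area})
    objects = pd.DataFrame(recs, columns=_empty_objects().columns) \
        if recs else _empty_objects()

    truth = SectionTruth(section_index, tissue, bleed_labels, tf, objects)
    return image, truth


def generate_stack(config: SlideSimConfig, stains: StainMatrix | None = None):
    """Generate the full serial stack. Returns ``(images, StackTruth)``."""
    config.validate()
    images, sections = [], []
    for i in range(config.n_sections):
        img, truth = generate_section(config, i, stains=stains)
        images.append(img)
        sections.append(truth)
    return images, StackTruth(sections)


def write_stack(out_dir, images, truth: StackTruth,
                config: SlideSimConfig) -> None:
    """Write a generated stack to disk.

    Sections as 8-bit RGB TIFF ``sec_{index:04d}.tif``; ground truth as
    16-bit bleed-id label TIFFs and 8-bit tissue masks; the object table as
    CSV; the config as YAML.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, (img, sec) in enumerate(zip(images, truth.sections)):
        tifffile.imwrite(out / f"sec_{i:04d}.tif", img)
        tifffile.imwrite(out / f"gt_bleeds_{i:04d}.tif", sec.bleed_labels)
        tifffile.imwrite(out / f"gt_tissue_{i:04d}.tif",
                         sec.tissue_mask.astype(np.uint8))
    truth.objects.to_csv(out / "ground_truth_objects.csv", index=False)
    pd.DataFrame(
        [{"section": i, "angle_deg": t.angle_deg, "drow": t.drow,
          "dcol": t.dcol} for i, t in enumerate(truth.transforms)]
    ).to_csv(out / "ground_truth_transforms.csv", index=False)
    config.to_yaml(out / "config.yaml")
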
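"""Canvas standardization and batched rigid serial-section alignment.

Serial coronal sections are mounted and scanned independently, so each
section carries a small random rigid offset (translation + rotation) with
respect to its neighbours. Alignment proceeds the way high-throughput
slide pipelines do it:

1. every image is centered on a common black canvas sized to the largest
   section;
2. sections are aligned sequentially, each to its already-aligned
   predecessor, in batches: the first batch is aligned on its own and the
   last ``n_refs`` aligned images of each batch are carried over as frozen
   references for the next batch (reference carry-over prevents inter-batch
   drift without holding the whole stack in memory);
3. an optional reverse pass re-runs the alignment on the reversed stack to
   relax any residual monotone drift.

The pairwise registration itself is intensity-based: it minimizes the mean
squared difference over a 3-level image pyramid with a derivative-free
(Powell) local search at each level. Label maps are warped with
nearest-neighbour interpolation so class codes never blend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize

from .errors import ConfigurationError, DataError, DegenerateInputError

__all__ = [
    "RigidTransform",
    "SectionStack",
    "apply_transform",
    "register_pair",
    "plan_batches",
    "align_batched",
    "reverse_pass_align",
    "centroid_drift",
    "standardize_canvas",
]


def _center(shape) -> np.ndarray:
    return np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])


@dataclass(frozen=True)
class RigidTransform:
    """Rotation about the canvas center followed by a translation.

    The transform moves image *content* forward: a positive ``drow`` shifts
    content down, a positive ``angle_deg`` rotates it counter-clockwise in
    (row, col) index space. Identity is ``(0, (0, 0))``.
    """

    angle_deg: float = 0.0
    drow: float = 0.0
    dcol: float = 0.0

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(0.0, 0.0, 0.0)

    def matrix(self, shape) -> np.ndarray:
        """Homogeneous 3x3 matrix mapping input (row, col) to output."""
        th = math.radians(self.angle_deg)
        c, s = math.cos(th), math.sin(th)
        rot = np.array([[c, -s], [s, c]])
        ctr = _center(shape)
        m = np.eye(3)
        m[:2, :2] = rot
        m[:2, 2] = ctr - rot @ ctr + np.array([self.drow, self.dcol])
        return m

    @classmethod
    def from_matrix(cls, m, shape) -> "RigidTransform":
        angle = math.degrees(math.atan2(m[1, 0], m[0, 0]))
        th = math.radians(angle)
        rot = np.array([[math.cos(th), -math.sin(th)],
                        [math.sin(th), math.cos(th)]])
        ctr = _center(shape)
        t = m[:2, 2] - (ctr - rot @ ctr)
        return cls(angle, float(t[0]), float(t[1]))

    def compose(self, other: "RigidTransform", shape) -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform.from_matrix(
            self.matrix(shape) @ other.matrix(shape), shape
        )

    def inverse(self, shape) -> "RigidTransform":
        return RigidTransform.from_matrix(
            np.linalg.inv(self.matrix(shape)), shape
        )


def apply_transform(image, transform: RigidTransform,
                    interpolation: str = "linear", cval=0) -> np.ndarray:
    """Warp an image by a rigid transform (rotation about center, then shift).

    Label masks (integer dtype) must use nearest-neighbour interpolation:
    class codes are categorical and must never blend. Out-of-canvas regions
    are filled with ``cval`` (0 = background code).
    """
    img = np.asarray(image)
    if interpolation not in ("linear", "nearest"):
        raise ConfigurationError("interpolation must be 'linear' or 'nearest'")
    if interpolation == "linear" and img.dtype.kind in "iub":
        raise ConfigurationError(
            "linear interpolation is not allowed for integer label masks; "
            "use interpolation='nearest'"
        )
    order = 0 if interpolation == "nearest" else 1
    minv = np.linalg.inv(transform.matrix(img.shape[:2]))

    def _warp(plane):
        return ndimage.affine_transform(
            plane, minv[:2, :2], offset=minv[:2, 2], order=order,
            mode="constant", cval=cval, prefilter=False,
        )

    if img.ndim == 2:
        return _warp(img)
    if img.ndim == 3:
        return np.stack([_warp(img[..., k]) for k in range(img.shape[-1])], axis=-1)
    raise DataError("apply_transform expects a 2-D image or 2-D + channels")


def _block_mean(img: np.ndarray, f: int) -> np.ndarray:
    if f == 1:
        return img
    h, w = (img.shape[0] // f) * f, (img.shape[1] // f) * f
    return img[:h, :w].reshape(h // f, f, w // f, f).mean(axis=(1, 3))


def register_pair(moving, reference, *, levels=(4, 2, 1),
                  smooth_sigma: float = 1.5, angle_scan_deg: float = 12.0,
                  xtol: float = 1e-4) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` onto ``reference``.

    Minimizes the mean squared intensity difference over a multi-resolution
    pyramid (coarse-to-fine), with Powell's derivative-free method at each
    level. Both images are lightly Gaussian-smoothed first so that piecewise
    constant label maps present a smooth cost surface. To avoid local
    minima, the translation is initialized from the foreground centroid
    offset and the rotation from a coarse angle scan (+-``angle_scan_deg``
    in 2 degree steps) at the coarsest level. Deterministic for fixed
    inputs.
    """
    mov = np.asarray(moving, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mov.shape != ref.shape:
        raise DataError("moving and reference images must share a shape")
    if mov.ndim == 3:
        mov, ref = mov.mean(axis=-1), ref.mean(axis=-1)
    if np.ptp(mov) == 0 or np.ptp(ref) == 0:
        raise DegenerateInputError("cannot register a constant image")
    mov = ndimage.gaussian_filter(mov / max(np.ptp(mov), 1e-12), smooth_sigma)
    ref = ndimage.gaussian_filter(ref / max(np.ptp(ref), 1e-12), smooth_sigma)

    c_mov = np.array(ndimage.center_of_mass(mov))
    c_ref = np.array(ndimage.center_of_mass(ref))
    shift0 = c_ref - c_mov

    params = np.array([0.0, shift0[0] / levels[0], shift0[1] / levels[0]])
    prev_f = None
    for li, f in enumerate(levels):
        mov_l, ref_l = _block_mean(mov, f), _block_mean(ref, f)
        if prev_f is not None:
            params[1:] *= prev_f / f
        shape_l = mov_l.shape

        def cost(p):
            warped = ndimage.affine_transform(
                mov_l,
                *_inv_parts(p, shape_l),
                order=1, mode="constant", cval=0.0, prefilter=False,
            )
            return float(np.mean((warped - ref_l) ** 2))

        if li == 0 and angle_scan_deg > 0:
            angles = np.arange(-angle_scan_deg, angle_scan_deg + 1e-9, 2.0)
            costs = [cost([a, params[1], params[2]]) for a in angles]
            params[0] = float(angles[int(np.argmin(costs))])

        res = optimize.minimize(
            cost, params, method="Powell",
            options={"xtol": xtol if f == levels[-1] else 1e-3,
                     "ftol": 1e-9, "maxiter": 200},
        )
        params = res.x
        prev_f = f
    return RigidTransform(float(params[0]), float(params[1]),
                          float(params[2]))


def _inv_parts(p, shape):
    tf = RigidTransform(float(p[0]), float(p[1]), float(p[2]))
    minv = np.linalg.inv(tf.matrix(shape))
    return minv[:2, :2], minv[:2, 2]


@dataclass
class SectionStack:
    """Ordered series of same-sized section images plus applied transforms."""

    images: list
    transforms: list = field(default_factory=list)
    pixel_size_um: float = 1.0
    kind: str = "label"  # "label" (categorical codes) or "intensity"

    def __post_init__(self):
        if not self.images:
            raise DataError("SectionStack requires at least one image")
        shapes = {im.shape[:2] for im in self.images}
        if len(shapes) != 1:
            raise DataError("SectionStack images must share canvas dimensions")
        if not self.transforms:
            self.transforms = [RigidTransform.identity()
                               for _ in self.images]
        if len(self.transforms) != len(self.images):
            raise DataError("transform list length must equal section count")

    @property
    def canvas_shape(self):
        return self.images[0].shape[:2]

    def __len__(self):
        return len(self.images)

    def copy(self) -> "SectionStack":
        return SectionStack([im.copy() for im in self.images],
                            list(self.transforms), self.pixel_size_um, self.kind)


def standardize_canvas(images, pixel_size_um: float = 1.0,
                       kind: str = "label") -> SectionStack:
    """Center every image on a shared black canvas sized to the largest one.

    Offsets are ``floor((canvas - size) / 2)`` per axis; the padding value 0
    is the background code, so foreground pixel counts are untouched.
    """
    imgs = [np.asarray(im) for im in images]
    if not imgs:
        raise DataError("standardize_canvas requires at least one image")
    kinds = {im.dtype.kind for im in imgs}
    if len({k in "iub" for k in kinds}) != 1:
        raise DataError("cannot mix integer label and float intensity images")
    hh = max(im.shape[0] for im in imgs)
    ww = max(im.shape[1] for im in imgs)
    out = []
    for im in imgs:
        pad_r = (hh - im.shape[0]) // 2
        pad_c = (ww - im.shape[1]) // 2
        canvas_shape = (hh, ww) + im.shape[2:]
        canvas = np.zeros(canvas_shape, dtype=im.dtype)
        canvas[pad_r:pad_r + im.shape[0], pad_c:pad_c + im.shape[1]] = im
        out.append(canvas)
    return SectionStack(out, pixel_size_um=pixel_size_um, kind=kind)


def plan_batches(n_sections: int, batch_size: int = 10, n_refs: int = 2):
    """Reference carry-over batching plan.

    The first group holds ``batch_size`` sections aligned independently;
    each later group prepends the last ``n_refs`` already-aligned sections
    as frozen references to the next ``batch_size`` new sections (a trailing
    short remainder is merged with the references as-is).

    Returns a list of ``(reference_indices, new_indices)`` pairs (0-based).
    """
    if batch_size <= n_refs or n_refs < 1:
        raise ConfigurationError("batch_size must exceed n_refs >= 1")
    if n_sections < 1:
        raise ConfigurationError("n_sections must be >= 1")
    groups = [([], list(range(min(batch_size, n_sections))))]
    pos = batch_size
    while pos < n_sections:
        refs = list(range(pos - n_refs, pos))
        new = list(range(pos, min(pos + batch_size, n_sections)))
        groups.append((refs, new))
        pos += batch_size
    return groups


def align_batched(stack: SectionStack, batch_size: int = 10, n_refs: int = 2,
                  **register_kwargs) -> SectionStack:
    """Align a stack sequentially in reference carry-over batches.

    Each new section is registered to its already-aligned predecessor;
    carried references are never re-transformed. Cumulative transforms are
    recorded per section (composed with any transform already on the stack).
    """
    groups = plan_batches(len(stack), batch_size, n_refs)
    interp = "nearest" if stack.kind == "label" else "linear"
    aligned = [np.asarray(stack.images[0])]
    tfs = [stack.transforms[0]]
    for refs, new in groups:
        for j in new:
            if j == 0:
                continue
            tf = register_pair(stack.images[j], aligned[j - 1],
                               **register_kwargs)
            aligned.append(apply_transform(stack.images[j], tf, interp))
            tfs.append(tf.compose(stack.transforms[j], stack.canvas_shape))
    return SectionStack(aligned, tfs, stack.pixel_size_um, stack.kind)


def reverse_pass_align(stack: SectionStack, batch_size: int = 10,
                       n_refs: int = 2, **register_kwargs) -> SectionStack:
    """Re-run batched alignment on the reversed stack, then restore order.

    A forward pass anchored on the first section can accumulate a monotone
    drift toward the far end; aligning the reversed stack relaxes it from
    the other side. Section order (and metadata order) is restored on
    return, so the operation is an involution on ordering. On a stack that
    is already well aligned the pass would only add resampling jitter, so
    the input is returned unchanged whenever it does not improve the
    centroid-drift metric — the pass never increases residual drift.
    """
    rev = SectionStack(list(stack.images[::-1]), list(stack.transforms[::-1]),
                       stack.pixel_size_um, stack.kind)
    out = align_batched(rev, batch_size, n_refs, **register_kwargs)
    out = SectionStack(list(out.images[::-1]), list(out.transforms[::-1]),
                       stack.pixel_size_um, stack.kind)
    if centroid_drift(out) <= centroid_drift(stack):
        return out
    return stack.copy()


def centroid_drift(stack: SectionStack) -> float:
    """Mean displacement of foreground centroids between consecutive sections.

    The metric used to judge alignment quality: on a perfectly aligned
    serial stack the tissue centroid moves only as much as anatomy changes
    between neighbouring sections.
    """
    cents = []
    for im in stack.images:
        fg = np.asarray(im) > 0
        if fg.ndim == 3:
            fg = fg.any(axis=-1)
        if not fg.any():
            cents.append(None)
            continue
        cents.append(np.array(ndimage.center_of_mass(fg)))
    pairs = [
        float(np.linalg.norm(a - b))
        for a, b in zip(cents[:-1], cents[1:])
        if a is not None and b is not None
    ]
    if not pairs:
        raise DegenerateInputError("no foreground to measure drift on")
    return float(np.mean(pairs))
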
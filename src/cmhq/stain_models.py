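"""Color-domain transforms for hematoxylin/DAB brightfield histology.

Two independent color representations are used to isolate the brown DAB
precipitate that marks extravasated red blood cells (microhemorrhages) from
the blue hematoxylin counterstain:

* **Optical-density (OD) color deconvolution.** Under the Beer-Lambert law,
  transmitted intensity is ``I_c = I0_c * 10**(-sum_s conc_s * V[s, c])``
  for stain OD vectors ``V`` (rows = stains, columns = RGB). Taking
  ``OD_c = -log10(I_c / I0_c)`` makes stain contributions additive, so the
  per-pixel stain concentrations are recovered by a linear unmixing
  ``conc = OD @ inv(V)``.

* **YIQ chrominance.** The NTSC YIQ transform maps RGB to luma (Y) and two
  chrominance axes; the I axis spans orange <-> blue, which is exactly the
  DAB-vs-hematoxylin contrast, so a single scalar channel separates the two
  stains without any matrix inversion.

The default HDAB stain vectors follow the Ruifrok-Johnston values that
ship with common deconvolution implementations; they are configurable
because scanners and staining protocols shift the effective vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigurationError, DataError

__all__ = [
    "StainMatrix",
    "NTSC_YIQ_MATRIX",
    "rgb_to_od",
    "deconvolve",
    "reconstruct_rgb",
    "rgb_to_yiq",
    "estimate_background",
]

#: NTSC RGB -> YIQ matrix (the classic "Color Transformer" convention).
NTSC_YIQ_MATRIX = np.array(
    [
        [0.299, 0.587, 0.114],
        [0.596, -0.274, -0.322],
        [0.211, -0.523, 0.312],
    ]
)

# Ruifrok-Johnston HDAB optical-density vectors (per RGB channel).
_HDAB_H = (0.650, 0.704, 0.286)
_HDAB_DAB = (0.269, 0.568, 0.778)


@dataclass(frozen=True)
class StainMatrix:
    """3x3 matrix of unit-norm stain OD vectors.

    Rows are stains in the fixed order (hematoxylin, DAB, residual); columns
    are RGB channels. The residual row completes the basis and is by default
    the normalized cross product of the first two rows — the stain vectors
    are *not* orthogonal, so the residual merely spans the remaining
    dimension and its concentrations are diagnostic only.
    """

    matrix: np.ndarray
    names: tuple[str, str, str] = ("hematoxylin", "dab", "residual")

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ConfigurationError("StainMatrix.matrix must be 3x3")
        norms = np.linalg.norm(m, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ConfigurationError(
                "StainMatrix rows must be unit-norm (got norms %s)" % norms
            )
        if not np.isfinite(np.linalg.cond(m)) or abs(np.linalg.det(m)) < 1e-12:
            raise ConfigurationError("StainMatrix is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_rows(cls, hematoxylin, dab, residual=None) -> "StainMatrix":
        """Build from two (or three) stain vectors, normalizing each row.

        With ``residual=None`` the third row is the normalized cross product
        of the first two, guaranteeing an invertible basis.
        """
        h = np.asarray(hematoxylin, float)
        d = np.asarray(dab, float)
        h = h / np.linalg.norm(h)
        d = d / np.linalg.norm(d)
        if residual is None:
            r = np.cross(h, d)
        else:
            r = np.asarray(residual, float)
        nr = np.linalg.norm(r)
        if nr == 0:
            raise ConfigurationError("residual stain vector has zero norm")
        r = r / nr
        return cls(np.vstack([h, d, r]))

    @classmethod
    def hdab(cls) -> "StainMatrix":
        """The default Ruifrok-Johnston hematoxylin + DAB stain basis."""
        return cls.from_rows(_HDAB_H, _HDAB_DAB)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def to_yaml(self, path) -> None:
        payload = {"names": list(self.names), "matrix": self.matrix.tolist()}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "StainMatrix":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(np.asarray(payload["matrix"], float), tuple(payload["names"]))


def _as_i0(i0) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(i0, dtype=float), (3,)).copy()
    if np.any(arr <= 0) or np.any(arr > 255):
        raise ConfigurationError("i0 reference intensities must lie in (0, 255]")
    return arr


def rgb_to_od(image, i0=(255.0, 255.0, 255.0)) -> np.ndarray:
    """Convert an RGB image to per-channel optical density.

    ``OD_c = -log10(max(I_c, 1) / I0_c)``. Intensities are clipped to >= 1
    before the log so fully black pixels map to a large finite OD rather
    than infinity (matching common deconvolution implementations).
    """
    i0 = _as_i0(i0)
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise DataError("expected an RGB image with a trailing channel axis")
    return -np.log10(np.maximum(img, 1.0) / i0)


def deconvolve(od, stains: StainMatrix | None = None) -> np.ndarray:
    """Unmix an OD image into (hematoxylin, DAB, residual) concentrations.

    Negative concentrations are preserved: they flag pixels outside the
    stain model (useful for diagnosing artifacts) and clipping them would
    silently bias area measurements.
    """
    stains = stains or StainMatrix.hdab()
    od = np.asarray(od, dtype=float)
    return od @ stains.inverse


def reconstruct_rgb(concentrations, stains: StainMatrix | None = None,
                    i0=(255.0, 255.0, 255.0), quantize: bool = True) -> np.ndarray:
    """Forward Beer-Lambert rendering of stain concentration fields.

    ``I_c = I0_c * 10**(-(conc @ V)_c)``, optionally rounded to 8-bit. Large
    concentrations floor near 0 (no wrap-around). The synthetic slide
    generator uses this exact forward model, which makes the deconvolution
    round-trip an algebraic identity in the noise-free limit.
    """
    i0 = _as_i0(i0)
    stains = stains or StainMatrix.hdab()
    conc = np.asarray(concentrations, dtype=float)
    od = conc @ stains.matrix
    img = i0 * np.power(10.0, -od)
    if quantize:
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img


def rgb_to_yiq(image, matrix: np.ndarray | None = None) -> np.ndarray:
    """NTSC YIQ transform of an RGB image (float output, no quantization).

    The I channel (in-phase chrominance, orange <-> blue axis) is positive
    for brown DAB precipitate and negative for blue hematoxylin, which is
    the contrast the YIQ segmentation method thresholds.
    """
    m = NTSC_YIQ_MATRIX if matrix is None else np.asarray(matrix, float)
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise DataError("expected an RGB image with a trailing channel axis")
    return img @ m.T


def estimate_background(image, percentile: float = 99.0) -> np.ndarray:
    """Per-channel background intensity estimate (bright-percentile pixel).

    Optional alternative to the fixed white reference for slides whose
    illumination is not perfectly white.
    """
    img = np.asarray(image, dtype=float)
    i0 = np.percentile(img.reshape(-1, img.shape[-1]), percentile, axis=0)
    return np.clip(i0, 1.0, 255.0)
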
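"""Random-forest pixel classification of stained sections.

A trainable-segmentation workflow in the ilastik/LABKIT style: the user
sparsely annotates pixels of three classes — 0 background (white slide),
1 brain tissue (hematoxylin), 2 microbleed (DAB) — a per-pixel feature
stack is computed (intensity, multi-scale Gaussian blurs, gradient
magnitude, Laplacian, local min/max/variance, per RGB channel), and a
random forest is fitted on the annotated pixels only. Inference assigns
every pixel the argmax class, yielding the 0/1/2 label maps consumed by
the registration and 3D-quantification stages.

Training honours a small-bleed bias: all annotated bleed pixels are kept
while background and tissue annotations are subsampled to at most
``max_class_ratio`` times the bleed count, so the rarest class (and the
smallest bleeds with it) is never swamped during fitting.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .errors import ConfigurationError, DataError

__all__ = [
    "CLASS_NAMES",
    "DEFAULT_FEATURES",
    "TrainingAnnotation",
    "PixelClassifierModel",
    "extract_features",
    "annotations_from_masks",
    "train_classifier",
    "predict_labels",
    "labels_to_bleed_mask",
    "batch_segment",
    "save_model",
    "load_model",
]

CLASS_NAMES = {0: "background", 1: "tissue", 2: "bleed"}

#: Default per-channel feature stack (order is fixed and recorded).
DEFAULT_FEATURES = (
    "identity",
    "gaussian:1", "gaussian:2", "gaussian:4", "gaussian:8",
    "gradient:1",
    "laplacian:1",
    "min:2", "max:2", "variance:2",
)


def _descriptor_hash(descriptor) -> str:
    return hashlib.sha256(
        json.dumps(list(descriptor)).encode()).hexdigest()[:16]


def _apply_filter(plane: np.ndarray, name: str) -> np.ndarray:
    if name == "identity":
        return plane
    kind, _, arg = name.partition(":")
    if kind == "gaussian":
        return ndimage.gaussian_filter(plane, float(arg))
    if kind == "gradient":
        return ndimage.gaussian_gradient_magnitude(plane, float(arg))
    if kind == "laplacian":
        return ndimage.gaussian_laplace(plane, float(arg))
    if kind in ("min", "max", "variance"):
        size = 2 * int(arg) + 1  # radius -> box width
        if kind == "min":
            return ndimage.minimum_filter(plane, size=size)
        if kind == "max":
            return ndimage.maximum_filter(plane, size=size)
        mean = ndimage.uniform_filter(plane, size=size)
        mean_sq = ndimage.uniform_filter(plane * plane, size=size)
        return np.maximum(mean_sq - mean * mean, 0.0)
    raise ConfigurationError(f"unknown feature filter: {name!r}")


def extract_features(image, descriptor=DEFAULT_FEATURES) -> np.ndarray:
    """Per-pixel feature stack, shape (rows, cols, n_channels * n_filters)."""
    if len(descriptor) < 1:
        raise ConfigurationError("feature descriptor must list >= 1 filter")
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 2:
        img = img[..., None]
    planes = []
    for ch in range(img.shape[-1]):
        plane = img[..., ch]
        for name in descriptor:
            planes.append(_apply_filter(plane, name).astype(np.float32))
    return np.stack(planes, axis=-1)


@dataclass
class TrainingAnnotation:
    """Sparse pixel annotations on one image: class -> (N, 2) (row, col)."""

    image: np.ndarray
    coords: dict  # {class_code: int array of shape (N, 2)}

    def __post_init__(self):
        shape = np.asarray(self.image).shape[:2]
        for cls, pts in self.coords.items():
            if cls not in CLASS_NAMES:
                raise DataError(f"unknown class code {cls}")
            pts = np.asarray(pts, dtype=int)
            if pts.size and (
                pts.min() < 0
                or pts[:, 0].max() >= shape[0]
                or pts[:, 1].max() >= shape[1]
            ):
                raise DataError(
                    f"annotation coordinates out of bounds for class {cls}")
            self.coords[cls] = pts.reshape(-1, 2)


def annotations_from_masks(image, tissue_mask, bleed_mask, n_per_class=400,
                           rng=None) -> TrainingAnnotation:
    """Sample sparse point annotations from reference masks.

    Stands in for interactive scribbling: draws up to ``n_per_class``
    random pixels from each of background, tissue (excluding bleeds) and
    bleed regions. Bleed pixels are sampled from all bleeds, so small
    objects contribute annotations in proportion to their area.
    """
    rng = np.random.default_rng(rng)
    tissue = np.asarray(tissue_mask, bool)
    bleed = np.asarray(bleed_mask, bool)
    regions = {0: ~tissue & ~bleed, 1: tissue & ~bleed, 2: bleed}
    coords = {}
    for cls, region in regions.items():
        idx = np.argwhere(region)
        if len(idx) == 0:
            coords[cls] = np.empty((0, 2), int)
            continue
        take = min(n_per_class, len(idx))
        coords[cls] = idx[rng.choice(len(idx), size=take, replace=False)]
    return TrainingAnnotation(np.asarray(image), coords)


@dataclass
class PixelClassifierModel:
    """A fitted forest plus everything needed to reproduce its predictions."""

    forest: RandomForestClassifier
    descriptor: tuple
    classes: tuple = (0, 1, 2)
    metadata: dict = field(default_factory=dict)

    @property
    def descriptor_hash(self) -> str:
        return _descriptor_hash(self.descriptor)


def train_classifier(annotations, hyperparams=None) -> PixelClassifierModel:
    """Fit a random-forest pixel classifier on sparse annotations.

    ``hyperparams`` keys (with defaults): ``n_trees`` 100, ``max_depth``
    None, ``seed`` 42, ``max_class_ratio`` 5 (cap on background/tissue
    pixels per bleed pixel — the small-bleed bias), ``descriptor``
    (feature stack). All three classes must be represented somewhere in
    the annotation set.
    """
    hp = {"n_trees": 100, "max_depth": None, "seed": 42,
          "max_class_ratio": 5, "descriptor": DEFAULT_FEATURES}
    hp.update(hyperparams or {})
    descriptor = tuple(hp["descriptor"])

    xs, ys = [], []
    for ann in annotations:
        feats = extract_features(ann.image, descriptor)
        for cls, pts in ann.coords.items():
            if len(pts) == 0:
                continue
            xs.append(feats[pts[:, 0], pts[:, 1]])
            ys.append(np.full(len(pts), cls))
    if not xs:
        raise DataError("no annotated pixels provided")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    present = set(np.unique(y).tolist())
    missing = [CLASS_NAMES[c] for c in CLASS_NAMES if c not in present]
    if missing:
        raise DataError(
            "training annotations missing class(es): " + ", ".join(missing))

    # small-bleed bias: keep every bleed pixel, cap the majority classes
    rng = np.random.default_rng(hp["seed"])
    n_bleed = int((y == 2).sum())
    cap = max(hp["max_class_ratio"] * n_bleed, 1)
    keep = np.zeros(len(y), bool)
    keep[y == 2] = True
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        keep[idx] = True
    x, y = x[keep], y[keep]

    forest = RandomForestClassifier(
        n_estimators=hp["n_trees"], max_depth=hp["max_depth"],
        max_features="sqrt", random_state=hp["seed"], n_jobs=1)
    forest.fit(x, y)
    metadata = {
        "n_trees": hp["n_trees"], "max_depth": hp["max_depth"],
        "seed": hp["seed"], "max_class_ratio": hp["max_class_ratio"],
        "n_training_pixels": int(len(y)),
        "n_images": len(annotations),
        "training_accuracy": float(forest.score(x, y)),
        "descriptor_hash": _descriptor_hash(descriptor),
    }
    return PixelClassifierModel(forest, descriptor, (0, 1, 2), metadata)


def predict_labels(model: PixelClassifierModel, image) -> np.ndarray:
    """Per-pixel argmax class; uint8 label map with codes {0, 1, 2}."""
    feats = extract_features(image, model.descriptor)
    n_feat_expected = getattr(model.forest, "n_features_in_", feats.shape[-1])
    if feats.shape[-1] != n_feat_expected:
        raise DataError(
            "image/feature mismatch: model expects %d features, got %d"
            % (n_feat_expected, feats.shape[-1]))
    flat = feats.reshape(-1, feats.shape[-1])
    pred = model.forest.predict(flat)
    return pred.reshape(feats.shape[:2]).astype(np.uint8)


def labels_to_bleed_mask(labels) -> np.ndarray:
    """Boolean mask of the bleed class (code 2)."""
    arr = np.asarray(labels)
    bad = np.setdiff1d(np.unique(arr), [0, 1, 2])
    if bad.size:
        raise DataError(f"label map contains invalid codes {bad.tolist()}")
    return arr == 2


def save_model(model: PixelClassifierModel, path) -> None:
    """Serialize the model to a single portable archive file."""
    joblib.dump(
        {"format_version": 1, "forest": model.forest,
         "descriptor": list(model.descriptor),
         "descriptor_hash": model.descriptor_hash,
         "classes": list(model.classes), "metadata": model.metadata},
        path)


def load_model(path) -> PixelClassifierModel:
    """Load a serialized model, refusing on a feature-descriptor mismatch."""
    payload = joblib.load(path)
    descriptor = tuple(payload["descriptor"])
    if _descriptor_hash(descriptor) != payload["descriptor_hash"]:
        raise ConfigurationError(
            "model feature descriptor hash mismatch; refusing to run with an "
            "incompatible feature extractor")
    return PixelClassifierModel(payload["forest"], descriptor,
                                tuple(payload["classes"]),
                                dict(payload["metadata"]))


_INDEX_RE = re.compile(r"(\d+)")


def _extract_index(stem: str):
    m = _INDEX_RE.search(stem)
    return int(m.group(1)) if m else None


def batch_segment(model: PixelClassifierModel, input_dir, output_dir):
    """Discover, canonically rename and segment a directory of sections.

    TIF/PNG images are sorted by the first integer in their filename,
    renamed to ``sec_{index:04d}`` (index = rank in sorted order), and
    segmented; label maps are written as 8-bit TIFF with codes {0, 1, 2}.
    A ``manifest.csv`` maps original to canonical names. Unreadable files
    are skipped and reported; duplicate numeric identifiers are a hard
    error.
    """
    in_dir, out_dir = Path(input_dir), Path(output_dir)
    candidates = sorted(
        p for p in in_dir.iterdir()
        if p.suffix.lower() in (".tif", ".tiff", ".png"))
    indexed = [(p, _extract_index(p.stem)) for p in candidates]
    indexed = [(p, i) for p, i in indexed if i is not None]
    if not indexed:
        raise DataError(f"no input images found in {in_dir}")
    seen = {}
    for p, i in indexed:
        if i in seen:
            raise DataError(
                f"duplicate numeric identifier {i}: {seen[i].name} and {p.name}")
        seen[i] = p
    indexed.sort(key=lambda pi: pi[1])

    out_dir.mkdir(parents=True, exist_ok=True)
    manifest, written, skipped = [], [], []
    for rank, (path, idx) in enumerate(indexed):
        try:
            image = tifffile.imread(path) if path.suffix.lower() != ".png" \
                else np.asarray(__import__("imageio.v3", fromlist=["imread"])
                                .imread(path))
        except Exception as exc:  # unreadable file: log and continue
            skipped.append((path.name, str(exc)))
            continue
        labels = predict_labels(model, image)
        out_name = f"sec_{rank:04d}.tif"
        tifffile.imwrite(out_dir / out_name, labels)
        manifest.append({"original": path.name, "canonical": out_name,
                         "numeric_id": idx})
        written.append(out_dir / out_name)
    pd.DataFrame(manifest).to_csv(out_dir / "manifest.csv", index=False)
    return {"written": written, "skipped": skipped,
            "manifest": out_dir / "manifest.csv"}
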
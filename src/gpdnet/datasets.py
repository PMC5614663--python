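"""Labeled image sets: a synthetic gastric-lesion texture generator plus the
crop/translate augmentation and per-class random test split protocol.

Real gastroscopy images are private, so the generator procedurally emulates
the three lesion classes on a mucosa-like pink-red background:

* ``erosion`` — scattered small irregular reddish patches,
* ``polyp``   — a bright circular protrusion with a radial luminance
  gradient and a specular highlight,
* ``ulcer``   — a dark annulus (crater rim) around a pale center.

The ``difficulty`` presets control additive pixel noise, geometric jitter
and lesion contrast so classifier accuracy is tunable from near-ceiling
(``easy``) down to a deliberately noisy regime (``hard``); the ``medium``
preset is calibrated to leave headroom for iterative fine-tuning to show an
improvement.  Generation is deterministic per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

CLASS_NAMES = ("erosion", "polyp", "ulcer")


@dataclass
class LabeledImageSet:
    """Images (N, H, W, 3) in [0, 1] with integer class labels."""

    images: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels length mismatch")
        if len(self.labels) and not (0 <= self.labels.min()
                                     and self.labels.max() < len(self.class_names)):
            raise ValueError("labels out of range")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def num_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.num_classes)

    def subset(self, index: np.ndarray) -> "LabeledImageSet":
        return LabeledImageSet(self.images[index], self.labels[index], self.class_names)

    def concat(self, other: "LabeledImageSet") -> "LabeledImageSet":
        return LabeledImageSet(np.concatenate([self.images, other.images]),
                               np.concatenate([self.labels, other.labels]),
                               self.class_names)

    # -- on-disk layouts ------------------------------------------------------

    def save_png_dir(self, root: str | Path) -> Path:
        """Write ``root/<class_name>/<index>.png`` (8-bit RGB)."""
        root = Path(root)
        for ci, cname in enumerate(self.class_names):
            (root / cname).mkdir(parents=True, exist_ok=True)
        counters = [0] * self.num_classes
        for img, label in zip(self.images, self.labels):
            arr = np.clip(np.rint(img * 255), 0, 255).astype(np.uint8)
            Image.fromarray(arr).save(
                root / self.class_names[label] / f"{counters[label]:05d}.png")
            counters[label] += 1
        return root

    @classmethod
    def load_png_dir(cls, root: str | Path,
                     class_names: tuple[str, ...] | None = None) -> "LabeledImageSet":
        root = Path(root)
        if class_names is None:
            class_names = tuple(sorted(p.name for p in root.iterdir() if p.is_dir()))
        images, labels = [], []
        for ci, cname in enumerate(class_names):
            for path in sorted((root / cname).glob("*.png")):
                images.append(np.asarray(Image.open(path).convert("RGB"),
                                         dtype=np.float32) / 255.0)
            labels.extend([ci] * (len(images) - len(labels)))
        return cls(np.stack(images), np.asarray(labels), class_names)

    def save_archive(self, path: str | Path) -> Path:
        """Single packed file: image array + label vector + JSON manifest."""
        path = Path(path)
        np.savez(path, images=self.images, labels=self.labels)
        path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
        path.with_suffix(".json").write_text(json.dumps(
            {"class_names": list(self.class_names),
             "n": len(self), "shape": list(self.images.shape)}))
        return path

    @classmethod
    def load_archive(cls, path: str | Path) -> "LabeledImageSet":
        path = Path(path)
        with np.load(path) as npz:
            images, labels = npz["images"], npz["labels"]
        sidecar = path.with_suffix(".json")
        names = (tuple(json.loads(sidecar.read_text())["class_names"])
                 if sidecar.exists() else CLASS_NAMES)
        return cls(images, labels, names)


# difficulty -> (noise sigma, center jitter px per 32, lesion contrast scale)
_DIFFICULTY = {
    "easy": (0.04, 2.0, 1.0),
    "medium": (0.22, 5.0, 0.45),
    "hard": (0.34, 7.0, 0.28),
}


@dataclass
class SynthConfig:
    """Synthetic lesion-texture generator settings.

    ``n_per_class`` defaults to 1,000 to mirror the scale of the augmented
    clinical set (about 1.2k per class); ``image_size`` can exceed 32 to
    produce sources for crop augmentation.
    """

    n_per_class: int = 1000
    seed: int = 0
    difficulty: str = "medium"
    image_size: int = 32

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.difficulty not in _DIFFICULTY:
            raise ValueError(f"difficulty must be one of {sorted(_DIFFICULTY)}")


def _mucosa_background(rng: np.random.Generator, s: int) -> np.ndarray:
    base = np.array([0.78, 0.47, 0.45]) + rng.normal(0, 0.03, 3)
    img = np.broadcast_to(base, (s, s, 3)).astype(np.float64).copy()
    field = gaussian_filter(rng.normal(0, 1, (s, s)), sigma=s / 6.0)
    img += 0.10 * field[:, :, None] * np.array([1.0, 0.7, 0.6])
    return img


def _render_one(rng: np.random.Generator, label: int, s: int,
                jitter: float, contrast: float) -> np.ndarray:
    img = _mucosa_background(rng, s)
    scale = s / 32.0
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    cx = s / 2 + rng.normal(0, jitter * scale)
    cy = s / 2 + rng.normal(0, jitter * scale)
    r = np.hypot(yy - cy, xx - cx)

    if label == 1:  # polyp: bright shaded protrusion
        radius = scale * (7.0 + 3.0 * rng.random())
        bump = np.exp(-(r / radius) ** 2)
        img += contrast * bump[:, :, None] * np.array([0.30, 0.22, 0.06])
        hx, hy = cx - radius / 3, cy - radius / 3
        hl = np.exp(-((yy - hy) ** 2 + (xx - hx) ** 2) / (radius / 2.5) ** 2)
        img += contrast * 0.30 * hl[:, :, None]
    elif label == 0:  # erosion: scattered irregular reddish patches
        for _ in range(rng.integers(7, 13)):
            pcx, pcy = rng.uniform(0.12 * s, 0.88 * s, 2)
            a = scale * rng.uniform(1.8, 4.0)
            b = scale * rng.uniform(1.8, 4.0)
            th = rng.uniform(0, np.pi)
            u = (xx - pcx) * np.cos(th) + (yy - pcy) * np.sin(th)
            v = -(xx - pcx) * np.sin(th) + (yy - pcy) * np.cos(th)
            blob = np.exp(-((u / a) ** 2 + (v / b) ** 2))
            img -= contrast * blob[:, :, None] * np.array([0.08, 0.34, 0.30])
    else:  # ulcer: dark crater rim around a pale center
        r0 = scale * (7.5 + 2.0 * rng.random())
        width = scale * (1.8 + 1.0 * rng.random())
        ring = np.exp(-((r - r0) / width) ** 2)
        img -= contrast * ring[:, :, None] * np.array([0.36, 0.34, 0.26])
        core = np.exp(-(r / (0.55 * r0)) ** 2)
        img += contrast * core[:, :, None] * np.array([0.22, 0.28, 0.10])
    return img


def generate_synthetic_gpd(config: SynthConfig) -> LabeledImageSet:
    """Three-class synthetic lesion textures, deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    noise, jitter, contrast = _DIFFICULTY[config.difficulty]
    s = config.image_size
    images, labels = [], []
    for label in range(len(CLASS_NAMES)):
        for _ in range(config.n_per_class):
            img = _render_one(rng, label, s, jitter, contrast)
            img += rng.normal(0, noise, img.shape)
            images.append(np.clip(img, 0, 1))
            labels.append(label)
    return LabeledImageSet(np.stack(images).astype(np.float32), np.asarray(labels))


@dataclass
class AugmentConfig:
    """Random crop + translation augmentation emitting fixed-size outputs.

    ``crop_sizes`` are candidate square ROI edge lengths (clinical-scale
    defaults; pass sizes <= your source size).  Either ``multiplier`` (same
    factor for every class) or ``per_class_counts`` (exact output totals per
    class) controls how many derived images each class yields.
    """

    crop_sizes: tuple[int, ...] = (475, 400, 320)
    max_translation: int = 10
    output_size: int = 32
    multiplier: int = 3
    per_class_counts: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.crop_sizes or min(self.crop_sizes) < 1:
            raise ValueError("crop_sizes must be positive")
        if self.output_size != 32:
            raise ValueError("output size is fixed at 32")
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")


def resize_to_input(image: np.ndarray, target: int = 32) -> np.ndarray:
    """Bilinear resize to ``target`` square, clamped to [0, 1]."""
    from skimage.transform import resize

    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if image.shape[:2] == (target, target):
        return np.clip(image, 0, 1).astype(np.float32)
    out = resize(image, (target, target), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0, 1).astype(np.float32)


def augment(dataset: LabeledImageSet, config: AugmentConfig,
            seed: int = 0) -> LabeledImageSet:
    """Derive >= 1 randomly cropped + translated 32x32 images per source.

    Per class, output counts follow ``config.per_class_counts`` when given
    (extra derivations are spread round-robin over the earliest sources),
    otherwise ``multiplier`` copies of every source.  Labels are preserved.
    """
    h, w = dataset.images.shape[1:3]
    src = min(h, w)
    usable = [c for c in config.crop_sizes if c <= src]
    if not usable:
        raise ValueError(f"all crop sizes {config.crop_sizes} exceed source size {src}")
    rng = np.random.default_rng(seed)
    out_images, out_labels = [], []
    for ci in range(dataset.num_classes):
        idx = np.flatnonzero(dataset.labels == ci)
        if len(idx) == 0:
            continue
        if config.per_class_counts is not None:
            target = config.per_class_counts[ci]
            if target < len(idx):
                raise ValueError("per-class target below source count (each source yields >= 1)")
            per = np.full(len(idx), target // len(idx))
            per[: target % len(idx)] += 1
        else:
            per = np.full(len(idx), config.multiplier)
        for i, n_crops in zip(idx, per):
            image = dataset.images[i]
            for _ in range(n_crops):
                crop = usable[rng.integers(len(usable))]
                ty0 = (h - crop) // 2
                tx0 = (w - crop) // 2
                dy = int(rng.integers(-config.max_translation, config.max_translation + 1))
                dx = int(rng.integers(-config.max_translation, config.max_translation + 1))
                y0 = int(np.clip(ty0 + dy, 0, h - crop))
                x0 = int(np.clip(tx0 + dx, 0, w - crop))
                roi = image[y0:y0 + crop, x0:x0 + crop]
                out_images.append(resize_to_input(roi, config.output_size))
                out_labels.append(ci)
    return LabeledImageSet(np.stack(out_images), np.asarray(out_labels),
                           dataset.class_names)


def split_train_test(dataset: LabeledImageSet, per_class_test: int = 300,
                     seed: int = 0) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Per class: shuffle, hold out ``per_class_test`` images for testing.

    The split is an exact partition — every image lands in exactly one
    side.  Raises if any class is not strictly larger than the holdout.
    """
    if per_class_test < 0:
        raise ValueError("per_class_test must be >= 0")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for ci in range(dataset.num_classes):
        idx = np.flatnonzero(dataset.labels == ci)
        if per_class_test and len(idx) <= per_class_test:
            raise ValueError(f"class {dataset.class_names[ci]} has {len(idx)} images, "
                             f"needs more than {per_class_test}")
        perm = rng.permutation(idx)
        test_idx.append(perm[:per_class_test])
        train_idx.append(perm[per_class_test:])
    return (dataset.subset(np.concatenate(train_idx)),
            dataset.subset(np.concatenate(test_idx)))
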
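"""Deterministic toy lesion-image generator.

Emulates the structure of small medical-image classification sets — a few
hundred grayscale-like images, 2-4 classes, small localized "lesion"
structures on noisy low-frequency backgrounds — the scale of public breast
ultrasound (780 images / 3 classes), chest CT (746 / 2) and colon-slide
(6160 / 4, imbalanced) collections.  Every image is a smooth random
background plus pixel noise, and, for lesion-bearing classes, an elliptical
inclusion with class-conditional size, contrast and internal texture.  The
"normal" class of a preset carries no lesion.  Output is 3-channel (the
model's stem expects RGB) with pixel values in [0, 1], fully reproducible
from (spec, seed).

This is deliberately not a physical simulation of ultrasound or CT; see the
methods note for what conclusions it does and does not support.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage


@dataclass(frozen=True)
class LesionDescriptor:
    """Class-conditional recipe for the elliptical inclusion.

    ``axis_range`` bounds the semi-axes as fractions of the image edge;
    ``contrast`` is the additive intensity of the inclusion (negative for
    hypo-intense lesions); ``texture_freq`` modulates the inclusion with a
    sinusoidal texture (cycles per image edge, 0 for none); ``present=False``
    marks a lesion-free ("normal") class.
    """

    axis_range: tuple[float, float] = (0.08, 0.18)
    contrast: float = 0.35
    texture_freq: float = 0.0
    present: bool = True

    def __post_init__(self) -> None:
        if self.present and (self.axis_range[0] <= 0 or self.axis_range[1] <= 0):
            raise ValueError(f"degenerate lesion axes {self.axis_range}")


@dataclass
class SyntheticSpec:
    """Recipe for a labelled toy dataset.

    ``class_lesions`` maps class name -> descriptor; classes must have
    pairwise distinct descriptors so the task is well-posed.  ``samples``
    maps class name -> count (imbalance supported).
    """

    class_lesions: dict[str, LesionDescriptor]
    samples: dict[str, int]
    image_size: int = 224
    background_noise: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.class_lesions) != set(self.samples):
            raise ValueError("class_lesions and samples must share class names")
        if not 2 <= len(self.class_lesions) <= 4:
            raise ValueError("2-4 classes supported")
        if min(self.samples.values()) < 1:
            raise ValueError("samples per class must be >= 1")
        descs = list(self.class_lesions.values())
        if len(set(descs)) != len(descs):
            raise ValueError("distinct classes need distinct lesion descriptors")

    @property
    def class_names(self) -> list[str]:
        return list(self.class_lesions)


def two_class_spec(n_per_class: int = 40, image_size: int = 64,
                   contrast: float = 0.5, seed: int = 0) -> SyntheticSpec:
    """Strong-contrast two-class preset (lesion vs normal) for fast tests."""
    return SyntheticSpec(
        class_lesions={
            "normal": LesionDescriptor(present=False),
            "lesion": LesionDescriptor(axis_range=(0.12, 0.25), contrast=contrast),
        },
        samples={"normal": n_per_class, "lesion": n_per_class},
        image_size=image_size,
        seed=seed,
    )


def three_class_spec(n_per_class: int = 30, image_size: int = 64,
                     seed: int = 0) -> SyntheticSpec:
    """Normal / benign-like / malignant-like (breast-ultrasound scale shape)."""
    return SyntheticSpec(
        class_lesions={
            "normal": LesionDescriptor(present=False),
            "benign": LesionDescriptor(axis_range=(0.10, 0.18), contrast=-0.35,
                                       texture_freq=0.0),
            "malignant": LesionDescriptor(axis_range=(0.15, 0.3), contrast=0.4,
                                          texture_freq=12.0),
        },
        samples={k: n_per_class for k in ("normal", "benign", "malignant")},
        image_size=image_size,
        seed=seed,
    )


def imbalanced_four_class_spec(scale: int = 1, image_size: int = 64,
                               seed: int = 0) -> SyntheticSpec:
    """Four classes with colon-slide-like imbalance (ratios ~ 18:14:23:11)."""
    base = {"normal": 18, "serrated": 14, "carcinoma": 23, "adenoma": 11}
    return SyntheticSpec(
        class_lesions={
            "normal": LesionDescriptor(present=False),
            "serrated": LesionDescriptor(axis_range=(0.08, 0.15), contrast=0.3,
                                         texture_freq=20.0),
            "carcinoma": LesionDescriptor(axis_range=(0.15, 0.3), contrast=0.45,
                                          texture_freq=6.0),
            "adenoma": LesionDescriptor(axis_range=(0.1, 0.2), contrast=-0.4),
        },
        samples={k: v * scale for k, v in base.items()},
        image_size=image_size,
        seed=seed,
    )


def _background(rng: np.random.Generator, size: int, noise: float) -> np.ndarray:
    coarse = rng.normal(0.0, 1.0, (8, 8))
    field_ = ndimage.zoom(coarse, size / 8, order=3)[:size, :size]
    field_ = 0.45 + 0.12 * field_ / max(np.abs(field_).max(), 1e-9)
    return field_ + rng.normal(0.0, noise, (size, size))


def _lesion(rng: np.random.Generator, size: int, d: LesionDescriptor) -> np.ndarray:
    a = rng.uniform(*d.axis_range) * size
    b = rng.uniform(*d.axis_range) * size
    theta = rng.uniform(0, np.pi)
    margin = 0.25 * size
    cy = rng.uniform(margin, size - margin)
    cx = rng.uniform(margin, size - margin)
    yy, xx = np.mgrid[0:size, 0:size]
    y, x = yy - cy, xx - cx
    u = x * np.cos(theta) + y * np.sin(theta)
    v = -x * np.sin(theta) + y * np.cos(theta)
    r2 = (u / a) ** 2 + (v / b) ** 2
    mask = np.exp(-3.0 * r2) * (r2 < 2.0)  # soft-edged ellipse
    tex = 1.0
    if d.texture_freq > 0:
        phase = rng.uniform(0, 2 * np.pi)
        tex = 0.7 + 0.3 * np.sin(2 * np.pi * d.texture_freq * u / size + phase)
    return d.contrast * mask * tex


def generate_dataset(spec: SyntheticSpec
                     ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Render the dataset.

    Returns ``(images, labels, class_names)`` with ``images`` of shape
    ``(n, 3, size, size)`` in [0, 1] and integer ``labels`` indexing
    ``class_names``.  Identical (spec, seed) give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    names = spec.class_names
    images, labels = [], []
    for ci, name in enumerate(names):
        d = spec.class_lesions[name]
        for _ in range(spec.samples[name]):
            img = _background(rng, spec.image_size, spec.background_noise)
            if d.present:
                img = img + _lesion(rng, spec.image_size, d)
            img = np.clip(img, 0.0, 1.0)
            images.append(np.repeat(img[None], 3, axis=0))
            labels.append(ci)
    return np.asarray(images), np.asarray(labels, dtype=np.int64), names


def write_imagefolder(images: np.ndarray, labels: np.ndarray,
                      class_names: list[str], path) -> Path:
    """Write PNGs under one subdirectory per class, plus a manifest CSV."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    counters = {name: 0 for name in class_names}
    for img, lab in zip(images, labels):
        name = class_names[int(lab)]
        cdir = root / name
        cdir.mkdir(exist_ok=True)
        idx = counters[name]
        counters[name] += 1
        fname = f"{name}_{idx:04d}.png"
        arr = np.clip(img * 255.0 + 0.5, 0, 255).astype(np.uint8)
        Image.fromarray(arr.transpose(1, 2, 0)).save(cdir / fname)
        rows.append((f"{name}/{fname}", name))
    with open(root / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "label"])
        w.writerows(rows)
    return root
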
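"""Directory-per-class image datasets and in-memory array datasets."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image


class ImageFolderDataset:
    """Images arranged as ``root/<class>/<file>.png|jpg``, labels from dirs.

    Class names are the sorted subdirectory names; ``__getitem__`` returns
    ``(image, label)`` with the image as a float64 ``(3, H, W)`` array in
    [0, 1].
    """

    EXTENSIONS = {".png", ".jpg", ".jpeg"}

    def __init__(self, root) -> None:
        self.root = Path(root)
        if not self.root.is_dir():
            raise FileNotFoundError(f"dataset directory not found: {self.root}")
        self.class_names = sorted(
            d.name for d in self.root.iterdir() if d.is_dir()
        )
        self.samples: list[tuple[Path, int]] = []
        for ci, name in enumerate(self.class_names):
            for f in sorted((self.root / name).iterdir()):
                if f.suffix.lower() in self.EXTENSIONS:
                    self.samples.append((f, ci))
        if not self.samples:
            raise ValueError(f"no class-labelled images found under {self.root}")

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, i: int) -> tuple[np.ndarray, int]:
        path, label = self.samples[i]
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
        return arr.transpose(2, 0, 1), label

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([l for _, l in self.samples], dtype=np.int64)


class ArrayDataset:
    """In-memory ``(images, labels)`` pair with the same item protocol."""

    def __init__(self, images: np.ndarray, labels: np.ndarray,
                 class_names: list[str] | None = None) -> None:
        if len(images) != len(labels):
            raise ValueError("images and labels differ in length")
        self.images = np.asarray(images, dtype=np.float64)
        self.labels = np.asarray(labels, dtype=np.int64)
        self.class_names = class_names or [
            str(c) for c in sorted(set(self.labels.tolist()))
        ]

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, i: int) -> tuple[np.ndarray, int]:
        return self.images[i], int(self.labels[i])


def stratified_split(dataset, test_fraction: float = 0.2, seed: int = 0
                     ) -> tuple[list[int], list[int]]:
    """Per-class random index split (default 8:2 train/test)."""
    labels = (
        dataset.labels if hasattr(dataset, "labels")
        else np.asarray([dataset[i][1] for i in range(len(dataset))])
    )
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n_test = max(1, int(round(test_fraction * len(idx)))) if len(idx) > 1 else 0
        test_idx.extend(idx[:n_test].tolist())
        train_idx.extend(idx[n_test:].tolist())
    return sorted(train_idx), sorted(test_idx)


class Subset:
    def __init__(self, dataset, indices) -> None:
        self.dataset = dataset
        self.indices = list(indices)
        self.class_names = getattr(dataset, "class_names", None)

    def __len__(self) -> int:
        return len(self.indices)

    def __getitem__(self, i: int):
        return self.dataset[self.indices[i]]
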
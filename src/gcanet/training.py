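"""Loss, schedule, preprocessing and the train/evaluate loops.

Defaults follow the published recipe for this architecture: 224 x 224
inputs, batch size 32, Adam at learning rate 1e-4 with weight decay 0.1,
cosine annealing of the learning rate to zero over 300 epochs, and only
random cropping, random horizontal flipping and per-channel normalization as
augmentation.  Weight decay is applied decoupled from the adaptive gradient
step (AdamW-style) and only to convolution/linear weights; at a decay
coefficient of 0.1 the classic L2-in-gradient reading would dominate the
loss gradient entirely.

The loss is categorical cross-entropy, mean over the batch of
``-log q(true class)`` with ``q`` the softmax of the logits.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import metrics as metrics_mod
from . import nn
from .model import Model

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])


@dataclass
class TrainConfig:
    batch_size: int = 32
    epochs: int = 300
    learning_rate: float = 1e-4
    weight_decay: float = 0.1
    input_size: int = 224
    seed: int = 0
    random_crop: bool = True
    horizontal_flip: bool = True
    crop_scale: tuple[float, float] = (0.7, 1.0)
    normalization: str = "dataset"   # "dataset" | "imagenet" | "none"
    max_steps: int | None = None     # optional cap on optimizer steps
    mean: tuple[float, float, float] | None = None
    std: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.normalization not in ("dataset", "imagenet", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


# ---------------------------------------------------------------------------
# Loss and schedule


def cross_entropy(predictions: np.ndarray, labels: np.ndarray,
                  from_logits: bool = True) -> float:
    """Mean categorical cross-entropy, -log q(true class) averaged over the batch."""
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels)
    n, c = predictions.shape
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError(
            f"label outside class range [0, {c}): {labels.min()}..{labels.max()}"
        )
    q = nn.softmax(predictions) if from_logits else predictions
    return float(-np.log(np.clip(q[np.arange(n), labels], 1e-300, None)).mean())


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray
                       ) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the logits (softmax - one-hot)/n."""
    n, c = logits.shape
    q = nn.softmax(logits)
    loss = float(-np.log(np.clip(q[np.arange(n), labels], 1e-300, None)).mean())
    grad = q.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def cosine_lr(step: int, total: int, lr0: float) -> float:
    """Cosine annealing to zero: ``lr0 * (1 + cos(pi * t / T)) / 2``."""
    if not 0 <= step <= total:
        raise ValueError(f"step {step} outside [0, {total}]")
    return lr0 * (1.0 + math.cos(math.pi * step / total)) / 2.0


# ---------------------------------------------------------------------------
# Preprocessing


def _resize(img: np.ndarray, size: int) -> np.ndarray:
    c, h, w = img.shape
    if h == size and w == size:
        return img
    return np.stack([
        ndimage.zoom(ch, (size / h, size / w), order=1, grid_mode=True,
                     mode="nearest")
        for ch in img
    ])


def _random_resized_crop(img: np.ndarray, size: int, scale: tuple[float, float],
                         rng: np.random.Generator) -> np.ndarray:
    c, h, w = img.shape
    area = h * w
    for _ in range(10):
        target = rng.uniform(*scale) * area
        aspect = math.exp(rng.uniform(math.log(3 / 4), math.log(4 / 3)))
        cw = int(round(math.sqrt(target * aspect)))
        ch_ = int(round(math.sqrt(target / aspect)))
        if cw <= w and ch_ <= h:
            top = rng.integers(0, h - ch_ + 1)
            left = rng.integers(0, w - cw + 1)
            return _resize(img[:, top : top + ch_, left : left + cw], size)
    return _resize(img, size)


def preprocess(img: np.ndarray, training: bool, cfg: TrainConfig,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """One image (3, H, W) in [0,1] -> normalized (3, size, size).

    Training: random resized crop, then horizontal flip with probability 1/2,
    then per-channel standardization.  Evaluation: deterministic resize then
    standardization.
    """
    img = np.asarray(img, dtype=np.float64)
    if training:
        rng = rng or np.random.default_rng(cfg.seed)
        if cfg.random_crop:
            img = _random_resized_crop(img, cfg.input_size, cfg.crop_scale, rng)
        else:
            img = _resize(img, cfg.input_size)
        if cfg.horizontal_flip and rng.random() < 0.5:
            img = img[:, :, ::-1].copy()
    else:
        img = _resize(img, cfg.input_size)
    if cfg.normalization == "imagenet":
        mean, std = IMAGENET_MEAN, IMAGENET_STD
    elif cfg.mean is not None:
        mean, std = np.asarray(cfg.mean), np.asarray(cfg.std)
    else:
        return img
    return (img - mean[:, None, None]) / std[:, None, None]


def fit_normalization(dataset, cfg: TrainConfig, max_samples: int = 200) -> None:
    """Fill ``cfg.mean``/``cfg.std`` with dataset channel statistics."""
    if cfg.normalization != "dataset" or cfg.mean is not None:
        return
    idx = np.linspace(0, len(dataset) - 1, min(len(dataset), max_samples)).astype(int)
    acc = np.zeros(3)
    acc2 = np.zeros(3)
    n = 0
    for i in idx:
        img, _ = dataset[int(i)]
        acc += img.mean(axis=(1, 2))
        acc2 += (img ** 2).mean(axis=(1, 2))
        n += 1
    mean = acc / n
    std = np.sqrt(np.maximum(acc2 / n - mean ** 2, 1e-8))
    cfg.mean = tuple(mean.tolist())
    cfg.std = tuple(std.tolist())


# ---------------------------------------------------------------------------
# Optimizer


class AdamW:
    """Adam with decoupled weight decay on decay-flagged parameters."""

    def __init__(self, params, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = list(params)
        self.weight_decay = weight_decay
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float) -> None:
        b1, b2 = self.betas
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
            if p.decay and self.weight_decay:
                p.data -= lr * self.weight_decay * p.data


# ---------------------------------------------------------------------------
# Loops


def _make_batch(dataset, indices, training: bool, cfg: TrainConfig,
                rng: np.random.Generator | None) -> tuple[np.ndarray, np.ndarray]:
    imgs, labs = [], []
    for i in indices:
        img, lab = dataset[int(i)]
        imgs.append(preprocess(img, training, cfg, rng))
        labs.append(lab)
    return np.stack(imgs), np.asarray(labs, dtype=np.int64)


def train(model: Model, dataset, cfg: TrainConfig, val_dataset=None
          ) -> list[dict]:
    """Optimize ``model`` on ``dataset``; returns the per-epoch history.

    History rows carry epoch index, learning rate, training loss/accuracy
    and (when a validation set is given) validation loss/accuracy.  All
    randomness (shuffling, augmentation) derives from ``cfg.seed``, so two
    runs with the same seed produce identical first-epoch losses.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    n_classes = model.cfg.num_classes
    labels = np.asarray([dataset[i][1] for i in range(len(dataset))])
    if labels.max() >= n_classes:
        raise ValueError(
            f"dataset has label {labels.max()} but the model head has "
            f"{n_classes} classes"
        )
    fit_normalization(dataset, cfg)
    rng = np.random.default_rng(cfg.seed)
    optimizer = AdamW(model.parameters(), weight_decay=cfg.weight_decay)
    history: list[dict] = []
    steps_done = 0
    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg.epochs, cfg.learning_rate)
        model.train()
        order = rng.permutation(len(dataset))
        losses, correct, seen = [], 0, 0
        for start in range(0, len(order), cfg.batch_size):
            if cfg.max_steps is not None and steps_done >= cfg.max_steps:
                break
            idx = order[start : start + cfg.batch_size]
            x, y = _make_batch(dataset, idx, True, cfg, rng)
            logits = model(x)
            loss, dlogits = cross_entropy_grad(logits, y)
            model.zero_grad()
            model.backward(dlogits)
            optimizer.step(lr)
            steps_done += 1
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y).sum())
            seen += len(y)
        row = {
            "epoch": epoch,
            "lr": lr,
            "train_loss": float(np.mean(losses)) if losses else float("nan"),
            "train_acc": correct / seen if seen else float("nan"),
        }
        if val_dataset is not None and len(val_dataset):
            val_loss, val_acc = _quick_eval(model, val_dataset, cfg)
            row["val_loss"] = val_loss
            row["val_acc"] = val_acc
        history.append(row)
        if cfg.max_steps is not None and steps_done >= cfg.max_steps:
            break
    return history


def _quick_eval(model: Model, dataset, cfg: TrainConfig) -> tuple[float, float]:
    logits, y = predict_logits(model, dataset, cfg)
    return cross_entropy(logits, y), float((logits.argmax(axis=1) == y).mean())


def predict_logits(model: Model, dataset, cfg: TrainConfig | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Evaluation-mode logits for every dataset item (model left unchanged)."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    cfg = cfg or TrainConfig(input_size=dataset[0][0].shape[-1])
    fit_normalization(dataset, cfg)
    model.eval()
    batch = max(1, cfg.batch_size)
    outs, labs = [], []
    for start in range(0, len(dataset), batch):
        idx = range(start, min(start + batch, len(dataset)))
        x, y = _make_batch(dataset, idx, False, cfg, None)
        outs.append(model(x))
        labs.append(y)
    return np.concatenate(outs), np.concatenate(labs)


def evaluate(model: Model, dataset, cfg: TrainConfig | None = None
             ) -> metrics_mod.MetricsReport:
    """Full metrics report (accuracy, macro P/R/F1, per-class AUC, ROC)."""
    logits, y = predict_logits(model, dataset, cfg)
    proba = nn.softmax(logits)
    labels = list(range(model.cfg.num_classes))
    report = metrics_mod.full_report(proba, y, labels)
    names = getattr(dataset, "class_names", None)
    if names and len(names) == len(labels):
        _relabel(report, names)
    return report


def _relabel(report: metrics_mod.MetricsReport, names: list[str]) -> None:
    remap = lambda d: {names[k]: v for k, v in d.items()}
    report.labels = list(names)
    report.per_class_precision = remap(report.per_class_precision)
    report.per_class_recall = remap(report.per_class_recall)
    report.per_class_f1 = remap(report.per_class_f1)
    if report.per_class_auc is not None:
        report.per_class_auc = remap(report.per_class_auc)
    if report.roc_points is not None:
        report.roc_points = remap(report.roc_points)
    if report.confusion is not None:
        report.confusion.labels = list(names)


# ---------------------------------------------------------------------------
# History serialization


def write_history(history: list[dict], csv_path=None, json_path=None) -> None:
    if csv_path is not None:
        keys = list(history[0].keys())
        with open(csv_path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=keys)
            w.writeheader()
            w.writerows(history)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(history, fh, indent=2)
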
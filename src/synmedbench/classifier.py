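"""Downstream multi-label predictive models and their training protocol.

Per-label sigmoid outputs with binary cross-entropy, a capped number of
images per epoch, plateau-driven learning-rate reduction and early stopping
on the mean validation AUROC. A compact CNN is the default; a densenet-style
architecture (dense blocks, transition layers, global average pooling and a
1024-dimensional penultimate representation) is available without external
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .autodiff import Tensor, concat
from .datasets import DatasetStore
from .nnet import Adam, Conv2d, Dense, Module, avg_pool2x, global_avg_pool, minimize
from .stats import auroc

__all__ = ["ClassifierConfig", "AUCReport", "SmallCNN", "DenseNetStyle",
           "build_model", "train_classifier", "evaluate_mean_auc",
           "penultimate_features", "resize_images"]


@dataclass
class ClassifierConfig:
    architecture: str = "small_cnn"         # small_cnn | densenet121_style
    input_size: int | None = None           # None: native resolution; 224 at paper scale
    batch_size: int = 48
    images_per_epoch: int = 5000
    learning_rate: float = 1e-4
    lr_factor: float = 10.0
    patience_lr: int = 2
    patience_stop: int = 3
    max_epochs: int = 60
    channels: tuple[int, ...] = (8, 16)
    seed: int = 0

    def __post_init__(self):
        if self.patience_stop <= self.patience_lr:
            raise ValueError("patience_stop must exceed patience_lr")
        for name in ("batch_size", "images_per_epoch", "patience_lr",
                     "patience_stop", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class AUCReport:
    """Per-label AUROC plus the mean over non-degenerate labels."""

    per_label: dict[str, float]
    mean_auc: float
    excluded: list[str] = field(default_factory=list)


def resize_images(images: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of (N, H, W) float images."""
    if images.shape[1] == size and images.shape[2] == size:
        return images
    out = np.empty((len(images), size, size))
    for i, img in enumerate(images):
        pil = Image.fromarray(img.astype(np.float32), mode="F")
        out[i] = np.asarray(pil.resize((size, size), Image.BILINEAR), dtype=np.float64)
    return out


class SmallCNN(Module):
    """conv/pool stages followed by global average pooling and a sigmoid head."""

    def __init__(self, resolution: int, n_labels: int, rng: np.random.Generator,
                 channels: Sequence[int] = (8, 16)):
        self.resolution = resolution
        self.n_labels = n_labels
        self.convs = []
        in_ch = 1
        res = resolution
        for ch in channels:
            if res < 4:
                break
            self.convs.append(Conv2d(in_ch, ch, 3, rng, equalized=False))
            in_ch = ch
            res //= 2
        self.feature_dim = in_ch
        self.head = Dense(in_ch, n_labels, rng, equalized=False, gain=1.0)

    def features(self, x: Tensor) -> Tensor:
        for conv in self.convs:
            x = avg_pool2x(conv(x).leaky_relu(0.1))
        return global_avg_pool(x)

    def forward(self, x: Tensor) -> Tensor:
        return self.head(self.features(x))


class DenseNetStyle(Module):
    """Dense blocks with bottlenecks and transition layers; 1024-d features.

    A deliberately shallow stand-in for densenet-121: concatenative feature
    reuse inside blocks, 1x1 + average-pool transitions between them and a
    final projection to a 1024-dimensional globally pooled representation.
    """

    PENULTIMATE_DIM = 1024

    def __init__(self, resolution: int, n_labels: int, rng: np.random.Generator,
                 growth: int = 8, layers_per_block: int = 2, n_blocks: int = 2):
        self.resolution = resolution
        self.n_labels = n_labels
        self.stem = Conv2d(1, 2 * growth, 3, rng, equalized=False)
        ch = 2 * growth
        self.blocks = []
        self.transitions = []
        for b in range(n_blocks):
            block = []
            for _ in range(layers_per_block):
                block.append((Conv2d(ch, 2 * growth, 1, rng, equalized=False),
                              Conv2d(2 * growth, growth, 3, rng, equalized=False)))
                ch += growth
            self.blocks.append(block)
            if b < n_blocks - 1:
                self.transitions.append(Conv2d(ch, ch // 2, 1, rng, equalized=False))
                ch = ch // 2
        self.final = Conv2d(ch, self.PENULTIMATE_DIM, 1, rng, equalized=False)
        self.feature_dim = self.PENULTIMATE_DIM
        self.head = Dense(self.PENULTIMATE_DIM, n_labels, rng, equalized=False, gain=1.0)

    def parameters(self):
        params = self.stem.parameters()
        for block in self.blocks:
            for bottleneck, comp in block:
                params += bottleneck.parameters() + comp.parameters()
        for t in self.transitions:
            params += t.parameters()
        params += self.final.parameters() + self.head.parameters()
        return params

    def features(self, x: Tensor) -> Tensor:
        x = self.stem(x).relu()
        for b, block in enumerate(self.blocks):
            for bottleneck, comp in block:
                y = comp(bottleneck(x).relu()).relu()
                x = concat([x, y], axis=1)
            if b < len(self.transitions):
                x = avg_pool2x(self.transitions[b](x))
        return global_avg_pool(self.final(x))

    def forward(self, x: Tensor) -> Tensor:
        return self.head(self.features(x))


def build_model(config: ClassifierConfig, resolution: int, n_labels: int):
    rng = np.random.default_rng(config.seed)
    if config.architecture == "small_cnn":
        return SmallCNN(resolution, n_labels, rng, config.channels)
    if config.architecture == "densenet121_style":
        return DenseNetStyle(resolution, n_labels, rng)
    raise ValueError(f"unknown architecture {config.architecture!r}")


def _bce_from_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    # max(x,0) - x*y + log(1 + exp(-|x|)): numerically stable BCE
    y = Tensor(targets.astype(np.float64))
    absx = logits * Tensor(np.sign(logits.data))
    return (logits.clip_min(0.0) - logits * y + (1.0 + (-absx).exp()).log()).mean()


def _model_input(images: np.ndarray) -> Tensor:
    return Tensor(images[:, None] * 2.0 - 1.0)  # [0,1] -> [-1,1]


def predict_scores(model, images: np.ndarray, batch: int = 128) -> np.ndarray:
    """Sigmoid label probabilities for (N, H, W) images in [0, 1]."""
    images = resize_images(np.asarray(images, dtype=np.float64), model.resolution)
    out = []
    for start in range(0, len(images), batch):
        logits = model(_model_input(images[start:start + batch]))
        out.append(1.0 / (1.0 + np.exp(-logits.data)))
    return np.concatenate(out, axis=0)


def penultimate_features(model, images: np.ndarray, batch: int = 128) -> np.ndarray:
    """Deterministic penultimate-layer representation per image."""
    images = resize_images(np.asarray(images, dtype=np.float64), model.resolution)
    out = []
    for start in range(0, len(images), batch):
        out.append(model.features(_model_input(images[start:start + batch])).data)
    return np.concatenate(out, axis=0)


def evaluate_mean_auc(model_or_scores, store: DatasetStore) -> AUCReport:
    """Per-label AUROC on a fold; degenerate labels are excluded and reported."""
    if isinstance(model_or_scores, np.ndarray):
        scores = model_or_scores
    else:
        scores = predict_scores(model_or_scores, store.images)
    lm = store.label_matrix()
    per_label, excluded = {}, []
    for j, name in enumerate(store.label_names):
        col = lm[:, j]
        if col.min() == col.max():
            excluded.append(name)
            continue
        per_label[name] = auroc(col, scores[:, j])
    if not per_label:
        raise ValueError("all labels are degenerate in this fold")
    return AUCReport(per_label=per_label,
                     mean_auc=float(np.mean(list(per_label.values()))),
                     excluded=excluded)


def train_classifier(train_store: DatasetStore, val_store: DatasetStore,
                     config: ClassifierConfig) -> tuple[object, pd.DataFrame]:
    """Train with the plateau schedule; returns (best model, per-epoch log).

    Epochs cycle through at most ``images_per_epoch`` images; the mean
    validation AUROC is computed after every epoch. The learning rate is
    divided by ``lr_factor`` after ``patience_lr`` consecutive
    non-improvements and training stops after ``patience_stop``; the
    best-validation weights are restored.
    """
    if len(train_store) == 0 or len(val_store) == 0:
        raise ValueError("train and validation folds must be non-empty")
    val_lm = val_store.label_matrix()
    if all(val_lm[:, j].min() == val_lm[:, j].max() for j in range(val_lm.shape[1])):
        raise ValueError("validation fold is single-class on every label")

    resolution = (config.input_size if config.input_size is not None
                  else train_store.resolution)
    images = resize_images(train_store.images, resolution)
    targets = train_store.label_matrix().astype(np.float64)
    model = build_model(config, resolution, len(train_store.label_names))
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)

    best_auc = -np.inf
    best_state = model.state_arrays()
    fails = 0
    log_rows = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(images))[:config.images_per_epoch]
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model(_model_input(images[idx]))
            loss = _bce_from_logits(logits, targets[idx])
            epoch_loss += minimize(loss, optimizer)
            n_batches += 1
        report = evaluate_mean_auc(model, val_store)
        log_rows.append({"epoch": epoch, "lr": optimizer.lr,
                         "train_loss": epoch_loss / max(n_batches, 1),
                         "val_mean_auc": report.mean_auc})
        if report.mean_auc > best_auc:
            best_auc = report.mean_auc
            best_state = model.state_arrays()
            fails = 0
        else:
            fails += 1
            if fails == config.patience_lr:
                optimizer.lr /= config.lr_factor
            if fails >= config.patience_stop:
                break
    model.load_state_arrays(best_state)
    return model, pd.DataFrame(log_rows)
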
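"""Post-hoc analyses: occlusion feature importance, nearest-neighbour
privacy audit and reader-study statistics."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .classifier import penultimate_features, predict_scores
from .datasets import DatasetStore
from .stats import wilcoxon_signed_rank

__all__ = ["AttributionMap", "NNResult", "ReaderStudyRecord",
           "attribution_map", "occlusion_tiles", "nearest_neighbors",
           "reader_study_stats", "expected_random_accuracy",
           "monte_carlo_random_accuracy"]


# ------------------------------------------------------- feature importance
@dataclass
class AttributionMap:
    """Per-tile occlusion importance; ``normalized`` is min-max scaled to [0, 1]."""

    raw: np.ndarray
    normalized: np.ndarray
    mask_size: int
    baseline_loss: float

    @property
    def n_tiles(self) -> int:
        return self.raw.size


def occlusion_tiles(height: int, width: int, mask_size: int) -> list[tuple[int, int]]:
    """Non-overlapping tile origins (stride = mask size) covering the image."""
    if height % mask_size or width % mask_size:
        raise ValueError("input size must be divisible by the mask size")
    return [(r, c) for r in range(0, height, mask_size)
            for c in range(0, width, mask_size)]


def _bce_sum(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    p = np.clip(scores, 1e-12, 1 - 1e-12)
    y = labels[None, :]
    return -(y * np.log(p) + (1 - y) * np.log(1 - p)).sum(axis=1)


def attribution_map(model, image: np.ndarray, labels: Sequence[int],
                    mask_size: int = 2, fill_value: float = 0.0,
                    batch: int = 256) -> AttributionMap:
    """Occlusion importance: zero each non-overlapping tile (in the model's
    [-1, 1] input space, so ``fill_value=0`` is mid-gray), record the loss
    increase over the unmasked baseline, then min-max normalise.

    ``image`` is (H, W) in [0, 1] at the model's input size; the loss is the
    per-image binary cross-entropy summed over ground-truth labels.
    """
    image = np.asarray(image, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    h, w = image.shape
    tiles = occlusion_tiles(h, w, mask_size)
    baseline = float(_bce_sum(predict_scores(model, image[None]), labels)[0])
    x_input = image * 2.0 - 1.0
    raw = np.empty(len(tiles))
    for start in range(0, len(tiles), batch):
        chunk = tiles[start:start + batch]
        masked = np.repeat(x_input[None], len(chunk), axis=0)
        for i, (r, c) in enumerate(chunk):
            masked[i, r:r + mask_size, c:c + mask_size] = fill_value
        scores = predict_scores(model, (masked + 1.0) / 2.0)
        raw[start:start + len(chunk)] = _bce_sum(scores, labels) - baseline
    grid = raw.reshape(h // mask_size, w // mask_size)
    span = grid.max() - grid.min()
    normalized = (grid - grid.min()) / span if span > 0 else np.zeros_like(grid)
    return AttributionMap(raw=grid, normalized=normalized,
                          mask_size=mask_size, baseline_loss=baseline)


# ----------------------------------------------------------- privacy audit
@dataclass
class NNResult:
    query_id: str
    nearest_real_id: str
    distance: float


def nearest_neighbors(synthetic_images: np.ndarray, real_train: DatasetStore,
                      feature_extractor: Callable[[np.ndarray], np.ndarray] | None = None,
                      model=None, query_ids: Sequence[str] | None = None) -> list[NNResult]:
    """For every synthetic query, the real train image minimising cosine
    distance in a shared feature space (ties -> lowest image id).

    The feature space defaults to the penultimate representation of the
    supplied classifier (the model trained on real data).
    """
    if len(real_train) == 0:
        raise ValueError("real train fold is empty")
    if feature_extractor is None:
        if model is None:
            raise ValueError("provide a feature_extractor or a classifier model")
        feature_extractor = lambda imgs: penultimate_features(model, imgs)  # noqa: E731
    q = np.asarray(feature_extractor(np.asarray(synthetic_images)), dtype=np.float64)
    r = np.asarray(feature_extractor(real_train.images), dtype=np.float64)
    qn = q / np.maximum(np.linalg.norm(q, axis=1, keepdims=True), 1e-12)
    rn = r / np.maximum(np.linalg.norm(r, axis=1, keepdims=True), 1e-12)
    dist = 1.0 - qn @ rn.T                          # in [0, 2]
    real_ids = real_train.labels["image_id"].to_numpy(dtype=object)
    id_order = np.argsort(real_ids, kind="stable")  # tie-break by lowest id
    dist_sorted = dist[:, id_order]
    if query_ids is None:
        query_ids = [f"query{i:05d}" for i in range(len(q))]
    out = []
    for i in range(len(q)):
        j = int(np.argmin(dist_sorted[i]))          # argmin takes first == lowest id
        out.append(NNResult(query_id=str(query_ids[i]),
                            nearest_real_id=str(real_ids[id_order[j]]),
                            distance=float(max(dist_sorted[i, j], 0.0))))
    return out


def nn_results_frame(results: Sequence[NNResult]) -> pd.DataFrame:
    return pd.DataFrame([{"synthetic_id": r.query_id,
                          "nearest_real_id": r.nearest_real_id,
                          "distance": r.distance} for r in results])


# ------------------------------------------------------------- reader study
@dataclass
class ReaderStudyRecord:
    """Confusion counts for one reader labelling a mixed real/synthetic set."""

    TR: int  # real images called real
    FR: int  # synthetic images called real
    TS: int  # synthetic images called synthetic
    FS: int  # real images called synthetic

    def __post_init__(self):
        if min(self.TR, self.FR, self.TS, self.FS) < 0:
            raise ValueError("counts must be non-negative")
        if self.TR + self.TS + self.FR + self.FS == 0:
            raise ValueError("record has zero total")

    @property
    def accuracy(self) -> float:
        return (self.TR + self.TS) / (self.TR + self.TS + self.FR + self.FS)

    @property
    def n_real(self) -> int:
        return self.TR + self.FS

    @property
    def n_synthetic(self) -> int:
        return self.TS + self.FR


def reader_study_stats(records: Sequence[ReaderStudyRecord],
                       null_accuracy: float = 0.5,
                       alternative: str = "greater",
                       min_records_for_test: int = 5) -> dict:
    """Per-reader accuracy, mean +/- sd, and a one-sided Wilcoxon signed-rank
    p-value against the random-labelling null. The test is skipped (p None)
    for panels smaller than ``min_records_for_test``."""
    if len(records) == 0:
        raise ValueError("at least one reader record is required")
    accs = np.array([r.accuracy for r in records])
    out = {"per_reader_accuracy": accs.tolist(),
           "mean_accuracy": float(accs.mean()),
           "sd_accuracy": float(accs.std(ddof=1)) if len(accs) > 1 else float("nan"),
           "null_accuracy": null_accuracy,
           "p_value": None}
    if len(records) >= min_records_for_test:
        _, p = wilcoxon_signed_rank(accs, mu=null_accuracy, alternative=alternative)
        out["p_value"] = float(p)
    return out


def expected_random_accuracy(n_real: int, n_synthetic: int) -> float:
    """Expected accuracy when every image independently receives a fair-coin
    real/synthetic guess: E[(TR + TS)] / n with TR+TS ~ Binomial(n, 1/2)."""
    from scipy.stats import binom
    n = n_real + n_synthetic
    return float(binom.mean(n, 0.5) / n)


def monte_carlo_random_accuracy(n_real: int, n_synthetic: int, draws: int,
                                seed: int = 0) -> float:
    """Monte-Carlo estimate of the same expectation."""
    rng = np.random.default_rng(seed)
    n = n_real + n_synthetic
    correct = rng.binomial(n, 0.5, size=draws)
    return float(correct.mean() / n)
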
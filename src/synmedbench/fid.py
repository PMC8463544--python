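"""Fréchet-distance image-quality metric, the fixed-N sampling protocol with
real-image cycling, and the convergence-based stopping controller.

The feature extractor is a small fixed-seed convolutional encoder (pluggable
at full scale); distances are therefore comparable only within one embedder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["GaussianSummary", "FidProtocol", "EmbeddingModel", "FidController",
           "summarize", "frechet_distance", "assemble_fid_sample",
           "convergence_check", "compute_fid"]


@dataclass(frozen=True)
class GaussianSummary:
    """Sample mean and covariance of a feature cloud."""

    m: np.ndarray
    C: np.ndarray
    n: int

    def __post_init__(self):
        if self.C.shape != (self.m.shape[0], self.m.shape[0]):
            raise ValueError("covariance shape does not match mean")
        if not np.allclose(self.C, self.C.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")


@dataclass(frozen=True)
class FidProtocol:
    """Evaluation sample size, cadence, patience and minimum budget."""

    N: int = 10_000
    eval_cadence: int = 400_000       # real images between evaluations
    patience: int = 2                 # consecutive non-improvements to stop
    min_images: int = 0               # evaluations before this budget are ignored

    def __post_init__(self):
        if self.N <= 0 or self.eval_cadence <= 0 or self.patience <= 0:
            raise ValueError("protocol fields must be positive")


def summarize(features: np.ndarray) -> GaussianSummary:
    """Mean and unbiased (n-1 divisor) covariance of row-vector features."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("need at least 2 feature vectors")
    m = features.mean(axis=0)
    C = np.cov(features, rowvar=False, ddof=1)
    C = np.atleast_2d(C)
    return GaussianSummary(m=m, C=C, n=features.shape[0])


def _psd_eig(C: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
    w, v = np.linalg.eigh(C)
    scale = max(1.0, float(np.abs(w).max()))
    if w.min() < -tol * scale:
        raise ValueError("covariance is not positive semi-definite within tolerance")
    return np.clip(w, 0.0, None), v


def frechet_distance(A: GaussianSummary, B: GaussianSummary, tol: float = 1e-6) -> float:
    """Squared Fréchet distance between two Gaussian summaries.

    d2 = ||m_A - m_B||^2 + Tr(C_A + C_B - 2 (C_A C_B)^{1/2}), with the matrix
    square root taken via an eigendecomposition of C_A^{1/2} C_B C_A^{1/2}
    and negative eigenvalues clipped at zero.
    """
    if A.m.shape != B.m.shape:
        raise ValueError("summaries have different dimensions")
    wa, va = _psd_eig(A.C, tol)
    _psd_eig(B.C, tol)
    a_half = (va * np.sqrt(wa)) @ va.T
    middle = a_half @ B.C @ a_half
    middle = (middle + middle.T) / 2.0
    wm = np.clip(np.linalg.eigvalsh(middle), 0.0, None)
    trace_term = float(np.trace(A.C) + np.trace(B.C) - 2.0 * np.sqrt(wm).sum())
    d2 = float(np.sum((A.m - B.m) ** 2)) + trace_term
    return max(d2, 0.0)


# ----------------------------------------------------------- feature encoder
def _conv_s2(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 convolution, stride 2, zero padding 1; plain numpy forward."""
    n, c, h, width = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    oh, ow = h // 2, width // 2
    oy = np.arange(oh) * 2
    ox = np.arange(ow) * 2
    ky, kx = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
    rows = oy[:, None, None, None] + ky[None, None]
    cols = ox[None, :, None, None] + kx[None, None]
    patches = xp[:, :, rows, cols]                       # (N, C, OH, OW, 3, 3)
    patches = patches.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * 9)
    out = patches @ w.reshape(w.shape[0], -1).T + b
    return out.reshape(n, oh, ow, w.shape[0]).transpose(0, 3, 1, 2)


@dataclass
class EmbeddingModel:
    """Fixed, seeded convolutional feature extractor for FID.

    Deterministic; identical across the real and synthetic evaluation sides.
    Features are per-channel spatial means and standard deviations after the
    final stage.
    """

    weights: list = field(repr=False)
    biases: list = field(repr=False)
    feature_dim: int = 0

    @classmethod
    def default(cls, resolution: int, seed: int = 0,
                channels: Sequence[int] = (16, 32, 48)) -> "EmbeddingModel":
        rng = np.random.default_rng(seed)
        n_stages = max(1, min(len(channels), int(np.log2(resolution)) - 1))
        ws, bs = [], []
        in_ch = 1
        for s in range(n_stages):
            out_ch = channels[s]
            ws.append(rng.standard_normal((out_ch, in_ch, 3, 3)) *
                      np.sqrt(2.0 / (in_ch * 9)))
            bs.append(rng.standard_normal(out_ch) * 0.1)
            in_ch = out_ch
        model = cls(weights=ws, biases=bs, feature_dim=2 * in_ch)
        return model

    def embed(self, images: np.ndarray, batch: int = 256) -> np.ndarray:
        """Map images in [0, 1], shape (N, H, W), to feature vectors."""
        images = np.asarray(images, dtype=np.float64)
        if images.ndim != 3:
            raise ValueError("expected (N, H, W) images")
        feats = []
        for start in range(0, len(images), batch):
            x = images[start:start + batch][:, None] * 2.0 - 1.0
            for w, b in zip(self.weights, self.biases):
                x = _conv_s2(x, w, b)
                x = np.where(x > 0, x, 0.2 * x)
            mean = x.mean(axis=(2, 3))
            std = x.std(axis=(2, 3))
            feats.append(np.concatenate([mean, std], axis=1))
        return np.concatenate(feats, axis=0)


# ------------------------------------------------------------------ sampling
def assemble_fid_sample(real_images: np.ndarray, real_labels: np.ndarray, N: int,
                        generator_handle: Callable[[np.ndarray, np.random.Generator], np.ndarray],
                        seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Draw N real images by cycling the fold and N fresh synthetic images
    conditioned on the (possibly repeated) real labels with fresh noise.

    Per-real-image usage counts differ by at most one: full passes plus a
    seeded partial pass.
    """
    real_images = np.asarray(real_images)
    n = len(real_images)
    if n == 0:
        raise ValueError("real fold is empty")
    rng = np.random.default_rng(seed)
    full, rem = divmod(N, n)
    idx = np.concatenate([np.tile(np.arange(n), full),
                          rng.choice(n, size=rem, replace=False)]).astype(np.int64)
    reals = real_images[idx]
    labels = np.asarray(real_labels)[idx]
    synth = np.asarray(generator_handle(labels, rng), dtype=np.float64)
    if synth.shape != reals.shape:
        raise ValueError("generator returned a mismatched sample")
    return reals, synth


def compute_fid(real_images, synth_images, embedder: EmbeddingModel) -> float:
    return frechet_distance(summarize(embedder.embed(synth_images)),
                            summarize(embedder.embed(real_images)))


# ---------------------------------------------------------------- controller
def convergence_check(trace: Sequence[tuple[float, float]], protocol: FidProtocol) -> str:
    """Return "stop" when, among evaluations at or past the minimum image
    budget, the last ``patience`` each failed to improve on the running best.
    """
    best = np.inf
    fails = 0
    for images_seen, fid_value in trace:
        if images_seen < protocol.min_images:
            continue
        if fid_value < best:
            best = fid_value
            fails = 0
        else:
            fails += 1
        if fails >= protocol.patience:
            return "stop"
    return "continue"


class FidController:
    """Drives FID evaluation cadence and the two-strike stopping rule."""

    def __init__(self, protocol: FidProtocol, embedder: EmbeddingModel,
                 real_images: np.ndarray, real_labels: np.ndarray, seed: int = 0):
        self.protocol = protocol
        self.embedder = embedder
        self.real_images = np.asarray(real_images)
        self.real_labels = np.asarray(real_labels)
        self.seed = seed
        self.trace: list[tuple[float, float]] = []
        self._next_eval = float(protocol.min_images)

    def maybe_evaluate(self, images_seen: float, generator_handle) -> str:
        if images_seen < self._next_eval:
            return "continue"
        self._next_eval = images_seen + self.protocol.eval_cadence
        reals, synth = assemble_fid_sample(
            self.real_images, self.real_labels, self.protocol.N,
            generator_handle, seed=self.seed + len(self.trace))
        self.trace.append((images_seen, compute_fid(reals, synth, self.embedder)))
        return convergence_check(self.trace, self.protocol)
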
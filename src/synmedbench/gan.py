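"""Conditional generative models.

Two architectures:

* ``prog``: a progressive-growing reference model — resolution doubling with
  transition/stabilisation phases, per-resolution 1x1 image-space projection
  layers for smooth interpolation, pixel-wise feature normalisation,
  minibatch-stddev channel, equalized learning rate, WGAN-GP loss with an
  auxiliary classifier conditioning term.
* ``cpd``: no growth; output-skip generator (an image-space head at every
  resolution, upsampled and summed, bounded by tanh), pixel normalisation
  conditioned on a label- and noise-dependent scale/bias, and a
  projection discriminator with residual blocks and global sum pooling.

Desk-scale channel counts are configurable; the full-scale schedule (512
channels up to 32 px, halved per doubling above) is the default shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import Tensor, concat, grad
from .nnet import Adam, Conv2d, Dense, Module, avg_pool2x, backward, global_sum_pool, upsample2x
from .fid import FidController

__all__ = [
    "GanConfig", "TrainState", "ConditionalNormParams",
    "conditional_pixel_norm", "pixel_norm", "projection_score",
    "minibatch_stddev_channel", "gradient_penalty", "losses",
    "progressive_schedule", "train_gan", "generate", "build_models",
    "CpdGenerator", "CpdDiscriminator", "ProgGenerator", "ProgDiscriminator",
    "generator_handle", "save_checkpoint", "load_checkpoint",
]

_EPS = 1e-8


@dataclass
class GanConfig:
    kind: str = "cpd"                  # cpd | prog
    resolution: int = 32
    start_resolution: int = 8          # prog growth entry point; cpd base is 4
    latent_dim: int = 512
    n_labels: int = 1
    max_channels: int = 64             # 512 at paper scale
    n_critic: int = 1
    gp_weight: float = 10.0
    aux_weight: float = 1.0            # prog only
    learning_rate: float = 1e-3
    adam_betas: tuple[float, float] = (0.0, 0.99)
    batch_size: int = 16
    images_per_phase: int = 1_400_000  # prog only
    max_images: int | None = None      # hard cap (safety for desk runs)
    seed: int = 0

    def __post_init__(self):
        for r in (self.resolution, self.start_resolution):
            if r < 4 or (r & (r - 1)) != 0:
                raise ValueError("resolutions must be powers of two >= 4")
        if self.start_resolution > self.resolution:
            raise ValueError("start_resolution must not exceed resolution")
        if self.n_critic < 1:
            raise ValueError("n_critic must be >= 1")
        if self.kind not in ("cpd", "prog"):
            raise ValueError("kind must be 'cpd' or 'prog'")

    def channels(self, res: int) -> int:
        """512-up-to-32px / halved-above schedule, capped at max_channels."""
        if res <= 32:
            return self.max_channels
        return max(self.max_channels >> int(np.log2(res // 32)), 4)


@dataclass
class TrainState:
    images_seen: int = 0
    g_steps: int = 0
    d_steps: int = 0
    phase_index: int = 0
    fid_trace: list = field(default_factory=list)
    stop_reason: str = ""
    seed: int = 0


# ------------------------------------------------------------ normalisation
class ConditionalNormParams(Module):
    """Trainable (W1, b1, W2, b2) producing per-channel scale and bias from
    the concatenated noise/label vector."""

    def __init__(self, cond_dim: int, n_channels: int, rng: np.random.Generator,
                 epsilon: float = _EPS):
        scale = 1.0 / np.sqrt(cond_dim)
        self.W1 = Tensor(rng.standard_normal((cond_dim, n_channels)) * scale,
                         requires_grad=True)
        self.b1 = Tensor(np.ones(n_channels), requires_grad=True)
        self.W2 = Tensor(rng.standard_normal((cond_dim, n_channels)) * scale,
                         requires_grad=True)
        self.b2 = Tensor(np.zeros(n_channels), requires_grad=True)
        self.epsilon = epsilon
        self.n_channels = n_channels

    def gamma_beta(self, zy: Tensor) -> tuple[Tensor, Tensor]:
        return zy @ self.W1 + self.b1, zy @ self.W2 + self.b2


def pixel_norm(a: Tensor, epsilon: float = _EPS) -> Tensor:
    """Plain pixel-wise feature vector normalisation."""
    rms = ((a * a).mean(axis=1, keepdims=True) + epsilon).sqrt()
    return a / rms


def conditional_pixel_norm(a: Tensor, z: Tensor, y: Tensor,
                           params: ConditionalNormParams) -> Tensor:
    """Pixel norm with conditioning: b_i = a_i / rms(a) * gamma_i + beta_i,
    gamma = W1 [z;y] + b1 and beta = W2 [z;y] + b2."""
    if a.shape[1] != params.n_channels:
        raise ValueError("channel count does not match norm parameters")
    zy = concat([z, y], axis=1)
    if zy.shape[1] != params.W1.shape[0]:
        raise ValueError("conditioning dimension does not match norm parameters")
    gamma, beta = params.gamma_beta(zy)
    b, c = a.shape[0], a.shape[1]
    normed = pixel_norm(a, params.epsilon)
    return normed * gamma.reshape(b, c, 1, 1) + beta.reshape(b, c, 1, 1)


def projection_score(features: Tensor, y: Tensor, embedding: Tensor,
                     uncond_head: Dense) -> Tensor:
    """score = unconditional head(features) + <embed(y), features>."""
    if y.shape[1] != embedding.shape[0] or features.shape[1] != embedding.shape[1]:
        raise ValueError("projection dimensions do not match")
    projected = ((y @ embedding) * features).sum(axis=1, keepdims=True)
    return uncond_head(features) + projected


def minibatch_stddev_channel(x: Tensor, epsilon: float = _EPS) -> Tensor:
    """Append one channel carrying the batch stddev statistic (averaged over
    channels and positions, broadcast). A batch of one yields a zero channel."""
    b, c, h, w = x.shape
    if b < 2:
        return concat([x, Tensor(np.zeros((b, 1, h, w)))], axis=1)
    mu = x.mean(axis=0, keepdims=True)
    var = ((x - mu) * (x - mu)).mean(axis=0, keepdims=True)
    stat = (var + epsilon).sqrt().mean()
    channel = stat.reshape(1, 1, 1, 1) * Tensor(np.ones((b, 1, h, w)))
    return concat([x, channel], axis=1)


# ------------------------------------------------------------------- losses
def gradient_penalty(interp_gradients: Tensor, gp_weight: float) -> Tensor:
    """gp_weight * mean((||grad per sample|| - 1)^2)."""
    b = interp_gradients.shape[0]
    flat = interp_gradients.reshape(b, -1)
    norms = ((flat * flat).sum(axis=1) + 1e-12).sqrt()
    return gp_weight * ((norms - 1.0) ** 2.0).mean()


def _softmax_ce(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Softmax cross-entropy against multi-hot targets normalized to a
    distribution (all-zero rows fall back to uniform)."""
    t = np.asarray(targets, dtype=np.float64)
    sums = t.sum(axis=1, keepdims=True)
    q = np.where(sums > 0, t / np.maximum(sums, 1.0), 1.0 / t.shape[1])
    zmax = Tensor(logits.data.max(axis=1, keepdims=True))
    shifted = logits - zmax
    log_probs = shifted - shifted.exp().sum(axis=1, keepdims=True).log()
    return -(Tensor(q) * log_probs).sum(axis=1).mean()


def losses(real_scores: Tensor, fake_scores: Tensor, interp_gradients: Tensor,
           config: GanConfig, labels: np.ndarray | None = None,
           real_logits: Tensor | None = None,
           fake_logits: Tensor | None = None) -> tuple[Tensor, Tensor]:
    """Return (generator loss, discriminator loss) for the configured mode.

    WGAN-GP for both; in prog mode an auxiliary softmax cross-entropy term is
    added to D for real and fake images and to G for fake images only.
    """
    d_loss = fake_scores.mean() - real_scores.mean() + \
        gradient_penalty(interp_gradients, config.gp_weight)
    g_loss = -fake_scores.mean()
    if config.kind == "prog":
        if real_logits is None or fake_logits is None or labels is None:
            raise ValueError("prog mode requires auxiliary classifier logits and labels")
        d_loss = d_loss + config.aux_weight * (_softmax_ce(real_logits, labels) +
                                               _softmax_ce(fake_logits, labels))
        g_loss = g_loss + config.aux_weight * _softmax_ce(fake_logits, labels)
    return g_loss, d_loss


def progressive_schedule(start_res: int, target_res: int,
                         images_per_phase: float) -> list[dict]:
    """Ordered growth phases with cumulative real-image budgets.

    One initial stabilisation at the start resolution, then a (transition,
    stabilisation) pair per resolution doubling.
    """
    for r in (start_res, target_res):
        if r < 1 or (r & (r - 1)) != 0:
            raise ValueError("resolutions must be powers of two")
    if start_res > target_res:
        raise ValueError("start must not exceed target")
    phases = [{"kind": "stabilize", "resolution": start_res}]
    res = start_res
    while res < target_res:
        res *= 2
        phases.append({"kind": "transition", "resolution": res})
        phases.append({"kind": "stabilize", "resolution": res})
    budget = 0.0
    for p in phases:
        budget += images_per_phase
        p["images"] = images_per_phase
        p["cumulative_images"] = budget
    return phases


# ------------------------------------------------------------ architectures
class CpdGenerator(Module):
    """Output-skip generator with conditionally normalised pixel features."""

    BASE_RES = 4

    def __init__(self, config: GanConfig, rng: np.random.Generator):
        self.config = config
        cond_dim = config.latent_dim + config.n_labels
        ch0 = config.channels(self.BASE_RES)
        self.initial = Dense(cond_dim, ch0 * self.BASE_RES ** 2, rng, equalized=True)
        self.levels = []       # list of (conv1, norm1, conv2, norm2, to_image)
        res = self.BASE_RES
        in_ch = ch0
        while True:
            out_ch = config.channels(res)
            conv1 = Conv2d(in_ch, out_ch, 3, rng, equalized=True)
            norm1 = ConditionalNormParams(cond_dim, out_ch, rng)
            conv2 = Conv2d(out_ch, out_ch, 3, rng, equalized=True)
            norm2 = ConditionalNormParams(cond_dim, out_ch, rng)
            to_image = Conv2d(out_ch, 1, 1, rng, equalized=True, gain=1.0)
            self.levels.append((conv1, norm1, conv2, norm2, to_image))
            in_ch = out_ch
            if res == config.resolution:
                break
            res *= 2

    def parameters(self):
        params = self.initial.parameters()
        for level in self.levels:
            for mod in level:
                params += mod.parameters()
        return params

    def forward(self, z: Tensor, y: Tensor) -> Tensor:
        zy = concat([z, y], axis=1)
        b = z.shape[0]
        ch0 = self.config.channels(self.BASE_RES)
        x = self.initial(zy).leaky_relu(0.2).reshape(b, ch0, self.BASE_RES, self.BASE_RES)
        skip = None
        res = self.BASE_RES
        for i, (conv1, norm1, conv2, norm2, to_image) in enumerate(self.levels):
            if i > 0:
                x = upsample2x(x)
                res *= 2
            x = conditional_pixel_norm(conv1(x).leaky_relu(0.2), z, y, norm1)
            x = conditional_pixel_norm(conv2(x).leaky_relu(0.2), z, y, norm2)
            head = to_image(x)
            skip = head if skip is None else upsample2x(skip) + head
        return skip.tanh()


class CpdDiscriminator(Module):
    """Residual discriminator with minibatch stddev, global sum pooling and a
    projection conditioning head."""

    BASE_RES = 4

    def __init__(self, config: GanConfig, rng: np.random.Generator):
        self.config = config
        res = config.resolution
        self.from_image = Conv2d(1, config.channels(res), 1, rng, equalized=True)
        self.blocks = []       # (conv1, conv2, skip_proj) per downsampling step
        while res > self.BASE_RES:
            in_ch = config.channels(res)
            out_ch = config.channels(res // 2)
            conv1 = Conv2d(in_ch, in_ch, 3, rng, equalized=True)
            conv2 = Conv2d(in_ch, out_ch, 3, rng, equalized=True)
            skip = Conv2d(in_ch, out_ch, 1, rng, equalized=True, gain=1.0) \
                if in_ch != out_ch else None
            self.blocks.append((conv1, conv2, skip))
            res //= 2
        final_ch = config.channels(self.BASE_RES)
        self.final_conv = Conv2d(final_ch + 1, final_ch, 3, rng, equalized=True)
        self.uncond_head = Dense(final_ch, 1, rng, equalized=True, gain=1.0)
        self.embedding = Tensor(
            rng.standard_normal((config.n_labels, final_ch)) / np.sqrt(final_ch),
            requires_grad=True)

    def parameters(self):
        params = self.from_image.parameters()
        for conv1, conv2, skip in self.blocks:
            params += conv1.parameters() + conv2.parameters()
            if skip is not None:
                params += skip.parameters()
        params += self.final_conv.parameters() + self.uncond_head.parameters()
        params.append(self.embedding)
        return params

    def pooled_features(self, images: Tensor) -> Tensor:
        x = self.from_image(images).leaky_relu(0.2)
        for conv1, conv2, skip in self.blocks:
            y = conv2(conv1(x).leaky_relu(0.2)).leaky_relu(0.2)
            s = x if skip is None else skip(x)
            x = avg_pool2x((y + s) * (1.0 / np.sqrt(2.0)))
        x = minibatch_stddev_channel(x)
        x = self.final_conv(x).leaky_relu(0.2)
        return global_sum_pool(x)

    def forward(self, images: Tensor, y: Tensor) -> Tensor:
        return projection_score(self.pooled_features(images), y,
                                self.embedding, self.uncond_head)


class ProgGenerator(Module):
    """Progressive-growing generator with per-resolution image projections."""

    def __init__(self, config: GanConfig, rng: np.random.Generator):
        self.config = config
        cond_dim = config.latent_dim + config.n_labels
        self.start_res = config.start_resolution
        ch0 = config.channels(self.start_res)
        self.initial = Dense(cond_dim, ch0 * self.start_res ** 2, rng, equalized=True)
        self.blocks = []       # (conv1, conv2) per resolution level
        self.to_image = []     # 1x1 projection per level
        res = self.start_res
        in_ch = ch0
        while True:
            out_ch = config.channels(res)
            self.blocks.append((Conv2d(in_ch, out_ch, 3, rng, equalized=True),
                                Conv2d(out_ch, out_ch, 3, rng, equalized=True)))
            self.to_image.append(Conv2d(out_ch, 1, 1, rng, equalized=True, gain=1.0))
            in_ch = out_ch
            if res == config.resolution:
                break
            res *= 2

    def parameters(self):
        params = self.initial.parameters()
        for (c1, c2), ti in zip(self.blocks, self.to_image):
            params += c1.parameters() + c2.parameters() + ti.parameters()
        return params

    def forward(self, z: Tensor, y: Tensor, res: int | None = None,
                alpha: float = 1.0) -> Tensor:
        res = res or self.config.resolution
        n_levels = int(np.log2(res // self.start_res)) + 1
        zy = concat([z, y], axis=1)
        b = z.shape[0]
        ch0 = self.config.channels(self.start_res)
        x = pixel_norm(self.initial(zy).leaky_relu(0.2)
                       .reshape(b, ch0, self.start_res, self.start_res))
        prev = None
        for i in range(n_levels):
            if i > 0:
                prev = x
                x = upsample2x(x)
            conv1, conv2 = self.blocks[i]
            x = pixel_norm(conv1(x).leaky_relu(0.2))
            x = pixel_norm(conv2(x).leaky_relu(0.2))
        img = self.to_image[n_levels - 1](x)
        if alpha < 1.0 and n_levels > 1:
            low = upsample2x(self.to_image[n_levels - 2](prev))
            img = alpha * img + (1.0 - alpha) * low
        return img


class ProgDiscriminator(Module):
    """Mirror of the growth schedule with an auxiliary classifier head."""

    def __init__(self, config: GanConfig, rng: np.random.Generator):
        self.config = config
        self.start_res = config.start_resolution
        self.from_image = []   # 1x1 per level, index aligned with generator levels
        self.blocks = []
        res = self.start_res
        levels = []
        while True:
            levels.append(res)
            if res == config.resolution:
                break
            res *= 2
        for r in levels:
            in_ch = config.channels(r)
            self.from_image.append(Conv2d(1, in_ch, 1, rng, equalized=True))
            if r > self.start_res:
                out_ch = config.channels(r // 2)
                self.blocks.append((Conv2d(in_ch, in_ch, 3, rng, equalized=True),
                                    Conv2d(in_ch, out_ch, 3, rng, equalized=True)))
            else:
                self.blocks.append(None)
        final_ch = config.channels(self.start_res)
        self.final_conv = Conv2d(final_ch + 1, final_ch, 3, rng, equalized=True)
        self.score_head = Dense(final_ch, 1, rng, equalized=True, gain=1.0)
        self.aux_head = Dense(final_ch, config.n_labels, rng, equalized=True, gain=1.0)

    def parameters(self):
        params = []
        for fi in self.from_image:
            params += fi.parameters()
        for blk in self.blocks:
            if blk is not None:
                params += blk[0].parameters() + blk[1].parameters()
        params += self.final_conv.parameters() + self.score_head.parameters() \
            + self.aux_head.parameters()
        return params

    def forward(self, images: Tensor, res: int | None = None,
                alpha: float = 1.0) -> tuple[Tensor, Tensor]:
        res = res or self.config.resolution
        level = int(np.log2(res // self.start_res))
        x = self.from_image[level](images).leaky_relu(0.2)
        first = True
        for i in range(level, 0, -1):
            conv1, conv2 = self.blocks[i]
            x = conv2(conv1(x).leaky_relu(0.2)).leaky_relu(0.2)
            x = avg_pool2x(x)
            if first and alpha < 1.0:
                low = self.from_image[i - 1](avg_pool2x(images)).leaky_relu(0.2)
                x = alpha * x + (1.0 - alpha) * low
            first = False
        x = minibatch_stddev_channel(x)
        x = self.final_conv(x).leaky_relu(0.2)
        feats = global_sum_pool(x)
        return self.score_head(feats), self.aux_head(feats)


# ------------------------------------------------------------------ training
def build_models(config: GanConfig) -> tuple[Module, Module]:
    rng = np.random.default_rng(config.seed)
    if config.kind == "cpd":
        return CpdGenerator(config, rng), CpdDiscriminator(config, rng)
    return ProgGenerator(config, rng), ProgDiscriminator(config, rng)


def generate(generator: Module, labels: np.ndarray, seed: int = 0) -> np.ndarray:
    """One image per label vector, output in [-1, 1], deterministic in
    (weights, labels, seed)."""
    labels = np.atleast_2d(np.asarray(labels, dtype=np.float64))
    if labels.shape[1] != generator.config.n_labels:
        raise ValueError("label dimension does not match the generator")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    rng = np.random.default_rng(seed)
    out = []
    batch = max(1, 4096 // generator.config.resolution)
    for start in range(0, len(labels), batch):
        y = labels[start:start + batch]
        z = rng.standard_normal((len(y), generator.config.latent_dim))
        img = generator(Tensor(z), Tensor(y))
        out.append(np.clip(img.data[:, 0], -1.0, 1.0))
    return np.concatenate(out, axis=0)


def generator_handle(generator: Module):
    """Adapt a generator to the dataset-space contract: labels + rng ->
    images in [0, 1]."""
    def handle(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        seed = int(rng.integers(0, 2 ** 31 - 1))
        return (generate(generator, labels, seed) + 1.0) / 2.0
    return handle


def _phase_at(schedule: list[dict], images_seen: float) -> tuple[dict, float]:
    """Current phase and the within-phase interpolation weight alpha."""
    start = 0.0
    for phase in schedule:
        end = phase["cumulative_images"]
        if images_seen < end:
            alpha = 1.0
            if phase["kind"] == "transition":
                alpha = (images_seen - start) / phase["images"]
            return phase, float(np.clip(alpha, 0.0, 1.0))
        start = end
    return schedule[-1], 1.0


def _downsample_to(images: np.ndarray, res: int) -> np.ndarray:
    out = images
    while out.shape[1] > res:
        n, h, w = out.shape
        out = out.reshape(n, h // 2, 2, w // 2, 2).mean(axis=(2, 4))
    return out


def train_gan(train_store, config: GanConfig, controller: FidController | None = None,
              seed: int = 0) -> tuple[Module, TrainState]:
    """Adversarial training with n_critic discriminator updates per generator
    update, WGAN-GP, the prog growth schedule where applicable, and FID-based
    stopping.

    ``controller`` may be None for fixed-budget runs (stops at
    ``config.max_images``).
    """
    if len(train_store) == 0:
        raise ValueError("training fold is empty")
    if train_store.resolution != config.resolution:
        raise ValueError("data resolution does not match the GAN config")
    images = train_store.images * 2.0 - 1.0           # [0,1] -> [-1,1]
    labels = train_store.label_matrix().astype(np.float64)
    if labels.shape[1] != config.n_labels:
        raise ValueError("label dimension does not match the GAN config")

    generator, discriminator = build_models(config)
    g_opt = Adam(generator.parameters(), lr=config.learning_rate, betas=config.adam_betas)
    d_opt = Adam(discriminator.parameters(), lr=config.learning_rate, betas=config.adam_betas)
    rng = np.random.default_rng(seed)
    state = TrainState(seed=seed)

    schedule = None
    if config.kind == "prog":
        schedule = progressive_schedule(config.start_resolution, config.resolution,
                                        config.images_per_phase)

    max_images = config.max_images if config.max_images is not None else float("inf")
    if controller is None and not np.isfinite(max_images):
        raise ValueError("either a FID controller or max_images is required")

    def d_forward(imgs: Tensor, y: Tensor, res: int, alpha: float):
        if config.kind == "prog":
            return discriminator(imgs, res=res, alpha=alpha)
        return discriminator(imgs, y), None

    while state.images_seen < max_images:
        res, alpha = config.resolution, 1.0
        if schedule is not None:
            phase, alpha = _phase_at(schedule, state.images_seen)
            res = phase["resolution"]
            state.phase_index = schedule.index(phase)

        batch_labels = None
        for _ in range(config.n_critic):
            idx = rng.integers(0, len(images), config.batch_size)
            x_real_np = _downsample_to(images[idx], res)
            y_np = labels[idx]
            batch_labels = y_np
            y = Tensor(y_np)
            z = Tensor(rng.standard_normal((config.batch_size, config.latent_dim)))
            if config.kind == "prog":
                fake = generator(z, y, res=res, alpha=alpha).detach()
            else:
                fake = generator(z, y).detach()
            x_real = Tensor(x_real_np)
            eps = rng.random((config.batch_size, 1, 1, 1))
            interp = Tensor(eps * x_real_np[:, None] + (1 - eps) * fake.data,
                            requires_grad=True)
            real_in = Tensor(x_real_np[:, None])
            real_scores, real_logits = d_forward(real_in, y, res, alpha)
            fake_scores, fake_logits = d_forward(Tensor(fake.data), y, res, alpha)
            interp_scores, _ = d_forward(interp, y, res, alpha)
            g_interp, = grad(interp_scores.sum(), [interp], create_graph=True)
            _, d_loss = losses(real_scores, fake_scores, g_interp, config,
                               labels=y_np, real_logits=real_logits,
                               fake_logits=fake_logits)
            d_opt.zero_grad()
            backward(d_loss)
            d_opt.step()
            state.d_steps += 1
            state.images_seen += config.batch_size

        # generator update
        y = Tensor(batch_labels)
        z = Tensor(rng.standard_normal((config.batch_size, config.latent_dim)))
        if config.kind == "prog":
            fake = generator(z, y, res=res, alpha=alpha)
        else:
            fake = generator(z, y)
        fake_scores, fake_logits = d_forward(fake, y, res, alpha)
        g_loss, _ = losses(fake_scores, fake_scores, Tensor(np.ones((1, 1))),
                           config, labels=batch_labels,
                           real_logits=fake_logits, fake_logits=fake_logits)
        g_opt.zero_grad()
        backward(g_loss)
        g_opt.step()
        state.g_steps += 1

        if controller is not None and (schedule is None or
                                       state.images_seen >= schedule[-1]["cumulative_images"]):
            signal = controller.maybe_evaluate(state.images_seen,
                                               generator_handle(generator))
            state.fid_trace = list(controller.trace)
            if signal == "stop":
                state.stop_reason = "fid_converged"
                break
    if not state.stop_reason:
        state.stop_reason = "max_images"
    return generator, state


# --------------------------------------------------------------- checkpoint
def save_checkpoint(path: str | Path, generator: Module, config: GanConfig,
                    state: TrainState) -> None:
    arrays = {f"w{i}": a for i, a in enumerate(generator.state_arrays())}
    meta = {"config": asdict(config), "state": {
        "images_seen": state.images_seen, "g_steps": state.g_steps,
        "d_steps": state.d_steps, "stop_reason": state.stop_reason,
        "fid_trace": state.fid_trace, "seed": state.seed}}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> tuple[Module, GanConfig, dict]:
    archive = np.load(path)
    meta = json.loads(archive["__meta__"].tobytes().decode())
    raw = dict(meta["config"])
    raw["adam_betas"] = tuple(raw["adam_betas"])
    config = GanConfig(**raw)
    generator, _ = build_models(config)
    n = len(generator.state_arrays())
    generator.load_state_arrays([archive[f"w{i}"] for i in range(n)])
    return generator, config, meta["state"]
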
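"""Small neural-network layer library on top of :mod:`synmedbench.autodiff`.

Supports the pieces the generative and predictive models need: dense and
3x3/1x1 convolutional layers with optional runtime He-constant weight scaling
(equalized learning rate), nearest-neighbour upsampling, average pooling and
an Adam optimizer.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, backward, concat, gather_hw, pad_hw

__all__ = [
    "Module", "Dense", "Conv2d", "Upsample2x", "AvgPool2x", "Adam",
    "global_avg_pool", "global_sum_pool", "upsample2x", "avg_pool2x",
]


class Module:
    """Base class: recursive parameter collection and state (de)serialization."""

    def parameters(self) -> list[Tensor]:
        params = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(a, dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_scale(fan_in: int, gain: float = np.sqrt(2.0)) -> float:
    return gain / np.sqrt(fan_in)


class Dense(Module):
    """Fully connected layer; ``equalized`` applies the He constant at runtime."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 equalized: bool = True, gain: float = np.sqrt(2.0), bias: bool = True):
        scale = _he_scale(in_features, gain)
        if equalized:
            self.weight = Tensor(rng.standard_normal((in_features, out_features)),
                                 requires_grad=True)
            self._scale = scale
        else:
            self.weight = Tensor(rng.standard_normal((in_features, out_features)) * scale,
                                 requires_grad=True)
            self._scale = 1.0
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ (self.weight * self._scale)
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    """k x k same-padded convolution via im2col (stride 1)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 equalized: bool = True, gain: float = np.sqrt(2.0)):
        fan_in = in_ch * kernel * kernel
        scale = _he_scale(fan_in, gain)
        shape = (out_ch, in_ch * kernel * kernel)
        if equalized:
            self.weight = Tensor(rng.standard_normal(shape), requires_grad=True)
            self._scale = scale
        else:
            self.weight = Tensor(rng.standard_normal(shape) * scale, requires_grad=True)
            self._scale = 1.0
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)
        self.kernel = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch
        self._idx_cache: dict[tuple, tuple] = {}

    def _indices(self, h: int, w: int) -> tuple:
        key = (h, w)
        if key not in self._idx_cache:
            k = self.kernel
            pad = k // 2
            hp, wp = h + 2 * pad, w + 2 * pad
            oy, ox = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
            ky, kx = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
            rows = (oy.reshape(-1, 1) + ky.reshape(1, -1))  # (H*W, k*k)
            cols = (ox.reshape(-1, 1) + kx.reshape(1, -1))
            self._idx_cache[key] = (rows.T, cols.T, pad, hp, wp)
        return self._idx_cache[key]

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {c}")
        rows, cols, pad, _, _ = self._indices(h, w)
        xp = pad_hw(x, pad)
        patches = gather_hw(xp, rows, cols)            # (B, C, k*k, H*W)
        patches = patches.reshape(b, c * self.kernel ** 2, h * w)
        flat = patches.transpose(1, 0, 2).reshape(c * self.kernel ** 2, b * h * w)
        out = (self.weight * self._scale) @ flat        # (OC, B*H*W)
        out = out.reshape(self.out_ch, b, h, w).transpose(1, 0, 2, 3)
        return out + self.bias.reshape(1, self.out_ch, 1, 1)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour doubling of the spatial axes."""
    b, c, h, w = x.shape
    rows = np.repeat(np.arange(h), 2).reshape(-1, 1) * np.ones((1, 2 * w), dtype=int)
    cols = np.ones((2 * h, 1), dtype=int) * np.repeat(np.arange(w), 2).reshape(1, -1)
    return gather_hw(x, rows, cols)


def avg_pool2x(x: Tensor) -> Tensor:
    b, c, h, w = x.shape
    return (x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5)))


def global_avg_pool(x: Tensor) -> Tensor:
    return x.mean(axis=(2, 3))


def global_sum_pool(x: Tensor) -> Tensor:
    return x.sum(axis=(2, 3))


class Upsample2x(Module):
    def forward(self, x):
        return upsample2x(x)


class AvgPool2x(Module):
    def forward(self, x):
        return avg_pool2x(x)


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def minimize(loss: Tensor, optimizer: Adam) -> float:
    """One optimization step; returns the scalar loss value."""
    optimizer.zero_grad()
    backward(loss)
    optimizer.step()
    return loss.item()
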
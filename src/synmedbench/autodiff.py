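"""Minimal reverse-mode automatic differentiation on numpy arrays.

Backward rules are themselves expressed with :class:`Tensor` operations, so
gradients are graph nodes and higher-order derivatives (needed for the
gradient-penalty term of the adversarial loss) come for free via
``grad(..., create_graph=True)``.

Only the operations required by the model zoo are provided; everything uses
float64 for reproducibility at desk scale.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "grad", "concat", "gather_hw", "scatter_hw", "pad_hw", "slice_hw"]


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    """An n-d array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_grad_fn")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _grad_fn: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self.grad: Tensor | None = None
        self._parents = _parents if self.requires_grad else ()
        self._grad_fn = _grad_fn if self.requires_grad else None

    # ------------------------------------------------------------------ utils
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other),
                     _grad_fn=lambda g: (_unbroadcast(g, self.shape),
                                         _unbroadcast(g, other.shape)))
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _grad_fn=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other),
                     _grad_fn=lambda g: (_unbroadcast(g * other, self.shape),
                                         _unbroadcast(g * self, other.shape)))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * _as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        p = float(p)
        out = Tensor(self.data ** p, _parents=(self,),
                     _grad_fn=lambda g: (g * (p * self ** (p - 1.0)),))
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        if self.ndim != 2 or other.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")
        out = Tensor(self.data @ other.data, _parents=(self, other),
                     _grad_fn=lambda g: (g @ other.T, self.T @ g))
        return out

    # --------------------------------------------------------------- reshapes
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        out = Tensor(self.data.reshape(shape), _parents=(self,),
                     _grad_fn=lambda g: (g.reshape(orig),))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(range(self.ndim))[::-1]
        inv = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(axes), _parents=(self,),
                     _grad_fn=lambda g: (g.transpose(inv),))
        return out

    @property
    def T(self):
        return self.transpose()

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        in_shape = self.shape
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,),
                     _grad_fn=lambda g: (_spread(g, in_shape, axis, keepdims),))
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,),
                     _grad_fn=lambda g: (g * out,))
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,),
                     _grad_fn=lambda g: (g * self ** -1.0,))
        return out

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        out = Tensor(np.tanh(self.data), _parents=(self,),
                     _grad_fn=lambda g: (g * (1.0 - out * out),))
        return out

    def sigmoid(self):
        return (1.0 + (-self).exp()) ** -1.0

    def leaky_relu(self, alpha: float = 0.2):
        # slope mask is a constant w.r.t. differentiation (valid a.e.)
        slope = np.where(self.data > 0, 1.0, alpha)
        return self * Tensor(slope)

    def relu(self):
        return self.leaky_relu(0.0)

    def clip_min(self, lo: float):
        mask = np.where(self.data > lo, 1.0, 0.0)
        return self * Tensor(mask) + lo * (1.0 - mask)


# ---------------------------------------------------------------- helper ops
def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _spread(g: Tensor, in_shape: tuple, axis, keepdims: bool) -> Tensor:
    """Broadcast a summed gradient back over the reduced axes."""
    if axis is not None and not keepdims:
        kshape = list(in_shape)
        for a in np.atleast_1d(axis):
            kshape[a] = 1
        g = g.reshape(tuple(kshape))
    elif axis is None and not keepdims:
        g = g.reshape((1,) * len(in_shape))
    return g * Tensor(np.ones(in_shape))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bwd(g: Tensor):
        return tuple(narrow(g, axis, int(offsets[i]), sizes[i])
                     for i in range(len(tensors)))

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  _parents=tuple(tensors), _grad_fn=_bwd)


def narrow(t: Tensor, axis: int, start: int, length: int) -> Tensor:
    idx = [slice(None)] * t.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    full_shape = t.shape

    def _bwd(g: Tensor):
        pad_before = [0] * t.ndim
        pad_before[axis] = start
        return (_zero_pad(g, full_shape, tuple(pad_before)),)

    return Tensor(t.data[idx], _parents=(t,), _grad_fn=_bwd)


def _zero_pad(g: Tensor, full_shape: tuple, offsets: tuple) -> Tensor:
    """Embed ``g`` into a zero tensor of ``full_shape`` at ``offsets`` (linear op)."""
    idx = tuple(slice(o, o + s) for o, s in zip(offsets, g.shape))

    def _bwd(gg: Tensor):
        return (Tensor(gg.data[idx], _parents=(gg,),
                       _grad_fn=lambda h: (_zero_pad(h, full_shape, offsets),)),)

    data = np.zeros(full_shape)
    data[idx] = g.data
    return Tensor(data, _parents=(g,),
                  _grad_fn=lambda gg: (narrow_nd(gg, idx),))


def narrow_nd(t: Tensor, idx: tuple) -> Tensor:
    shape = t.shape
    offsets = tuple(s.start for s in idx)
    return Tensor(t.data[idx], _parents=(t,),
                  _grad_fn=lambda g: (_zero_pad(g, shape, offsets),))


def pad_hw(t: Tensor, pad: int) -> Tensor:
    """Zero-pad the trailing two (spatial) axes of a (B, C, H, W) tensor."""
    if pad == 0:
        return t
    b, c, h, w = t.shape
    return _zero_pad(t, (b, c, h + 2 * pad, w + 2 * pad), (0, 0, pad, pad))


def slice_hw(t: Tensor, pad: int) -> Tensor:
    if pad == 0:
        return t
    b, c, h, w = t.shape
    idx = (slice(0, b), slice(0, c), slice(pad, h - pad), slice(pad, w - pad))
    return narrow_nd(t, idx)


def gather_hw(t: Tensor, rows: np.ndarray, cols: np.ndarray) -> Tensor:
    """Advanced-index the spatial axes: (B, C, H, W) -> (B, C, *rows.shape).

    The adjoint is a scatter-add; both are linear, so second derivatives are
    exact.
    """
    h, w = t.shape[2], t.shape[3]
    return Tensor(t.data[:, :, rows, cols], _parents=(t,),
                  _grad_fn=lambda g: (scatter_hw(g, rows, cols, h, w),))


def scatter_hw(g: Tensor, rows: np.ndarray, cols: np.ndarray, h: int, w: int) -> Tensor:
    b, c = g.shape[0], g.shape[1]
    out = np.zeros((b, c, h, w))
    np.add.at(out, (slice(None), slice(None), rows, cols), g.data)
    return Tensor(out, _parents=(g,),
                  _grad_fn=lambda gg: (gather_hw(gg, rows, cols),))


# ------------------------------------------------------------------ backward
def _topo(root: Tensor) -> list:
    order, seen = [], set()
    stack = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    return order


def grad(output: Tensor, inputs: Iterable[Tensor], create_graph: bool = False,
         grad_output: Tensor | None = None) -> list:
    """Return d(output)/d(input) for each input.

    ``create_graph=True`` keeps the returned gradients differentiable.
    """
    inputs = list(inputs)
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    grads: dict[int, Tensor] = {id(output): grad_output}
    for node in reversed(_topo(output)):
        g = grads.get(id(node))
        if g is None or node._grad_fn is None:
            continue
        parent_grads = node._grad_fn(g)
        for p, pg in zip(node._parents, parent_grads):
            if pg is None or not p.requires_grad:
                continue
            if id(p) in grads:
                grads[id(p)] = grads[id(p)] + pg
            else:
                grads[id(p)] = pg
    out = []
    for x in inputs:
        g = grads.get(id(x))
        if g is None:
            g = Tensor(np.zeros_like(x.data))
        if not create_graph:
            g = g.detach()
        out.append(g)
    return out


def backward(loss: Tensor) -> None:
    """Accumulate ``.grad`` (detached) on every reachable leaf tensor."""
    grads: dict[int, Tensor] = {id(loss): Tensor(np.ones_like(loss.data))}
    order = _topo(loss)
    for node in reversed(order):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        if node._grad_fn is None:
            node.grad = g.detach() if node.grad is None else Tensor(node.grad.data + g.data)
            continue
        for p, pg in zip(node._parents, node._grad_fn(g)):
            if pg is None or not p.requires_grad:
                continue
            if id(p) in grads:
                grads[id(p)] = grads[id(p)] + pg
            else:
                grads[id(p)] = pg
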
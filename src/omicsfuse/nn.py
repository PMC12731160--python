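"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains small transductive graph networks (a few hundred nodes,
hidden widths in the tens to hundreds), a regime where dense numpy matmuls
on one CPU are entirely adequate.  This module provides the only machinery
the models need: a :class:`Tensor` wrapping an ``ndarray`` with a gradient
slot, a handful of differentiable primitives with numpy broadcasting, and an
Adam optimizer.  Gradients are accumulated by topological-order backward
passes; correctness is verified against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "add",
    "mul",
    "div",
    "matmul",
    "exp",
    "log",
    "relu",
    "leaky_relu",
    "sigmoid",
    "tensor_sum",
    "concat",
    "transpose",
    "softmax_axis",
    "dropout",
    "Adam",
]


class Tensor:
    """A numpy array plus a gradient and the tape entry that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate d(self)/d(leaf) into every reachable leaf's ``grad``."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # Operator sugar (constants are wrapped automatically).
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), _wrap(-1.0)))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, _wrap(-1.0)))

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __neg__(self):
        return mul(self, _wrap(-1.0))

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _tracked(out: Tensor, parents: tuple[Tensor, ...], backward) -> Tensor:
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad = t.grad + g


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data)

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _tracked(out, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data)

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _tracked(out, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data / b.data)

    def backward(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _tracked(out, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data)

    def backward(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return _tracked(out, (a, b), backward)


def exp(a: Tensor) -> Tensor:
    val = np.exp(a.data)
    out = Tensor(val)

    def backward(g):
        _accum(a, g * val)

    return _tracked(out, (a,), backward)


def log(a: Tensor) -> Tensor:
    out = Tensor(np.log(a.data))

    def backward(g):
        _accum(a, g / a.data)

    return _tracked(out, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask)

    def backward(g):
        _accum(a, g * mask)

    return _tracked(out, (a,), backward)


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    mask = a.data > 0
    out = Tensor(np.where(mask, a.data, slope * a.data))

    def backward(g):
        _accum(a, g * np.where(mask, 1.0, slope))

    return _tracked(out, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    # Numerically stable logistic on both tails.
    val = np.empty_like(a.data)
    pos = a.data >= 0
    val[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ez = np.exp(a.data[~pos])
    val[~pos] = ez / (1.0 + ez)
    out = Tensor(val)

    def backward(g):
        _accum(a, g * val * (1.0 - val))

    return _tracked(out, (a,), backward)


def tensor_sum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims))

    def backward(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape).copy())

    return _tracked(out, (a,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return _tracked(out, tuple(tensors), backward)


def slice_rows(a: Tensor, lo: int, hi: int) -> Tensor:
    out = Tensor(a.data[lo:hi])

    def backward(g):
        full = np.zeros_like(a.data)
        full[lo:hi] = g
        _accum(a, full)

    return _tracked(out, (a,), backward)


def transpose(a: Tensor) -> Tensor:
    out = Tensor(a.data.T)

    def backward(g):
        _accum(a, g.T)

    return _tracked(out, (a,), backward)


def softmax_axis(a: Tensor, axis: int) -> Tensor:
    """Softmax along ``axis`` (max-shift applied as a constant for stability)."""
    shift = constant(a.data.max(axis=axis, keepdims=True))
    e = exp(add(a, mul(shift, constant(-1.0))))
    return div(e, tensor_sum(e, axis=axis, keepdims=True))


def dropout(a: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return a
    mask = (rng.random(a.data.shape) >= p) / (1.0 - p)
    return mul(a, constant(mask))


class Adam:
    """Adam with the standard bias correction; optional decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1 ** self.t)
            vhat = self._v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay > 0:
                p.data = p.data - self.lr * self.weight_decay * p.data


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple[int, ...] | None = None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))
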
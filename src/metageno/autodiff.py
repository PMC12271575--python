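"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the embedding layer, sequence backbones
and losses need: broadcasting arithmetic, (batched) matmul, row gathering
for embedding lookups, softmax, and the usual pointwise nonlinearities.
All tensors are float64; gradients are exact up to floating point, which
the finite-difference tests rely on.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "stack", "concat", "numeric_grad",
           "no_grad"]

_grad_enabled: bool = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._old = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._old
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over broadcast dimensions so it matches `shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = lambda: None
        self._prev = _prev

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, prev) -> "Tensor":
        rg = _grad_enabled and any(p.requires_grad for p in prev)
        if not rg:
            return Tensor(data)
        return Tensor(data, requires_grad=True,
                      _prev=tuple(p for p in prev if p.requires_grad))

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _acc(self, g: np.ndarray) -> None:
        """Lazily accumulate a gradient contribution.

        First contribution is adopted by reference (copied if it is a view);
        later ones allocate a fresh sum, so no buffer is ever mutated in
        place and aliasing upstream gradients is safe.
        """
        if self.grad is None:
            g = np.asarray(g)
            self.grad = g if g.flags.owndata else g.copy()
        else:
            self.grad = self.grad + g

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out = self._make(self.data + other.data, (self, other))

        def _bw():
            if self.requires_grad:
                self._acc(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(out.grad, other.data.shape))

        if out.requires_grad:
            out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,))

        def _bw():
            if self.requires_grad:
                self._acc(-out.grad)

        if out.requires_grad:
            out._backward = _bw
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = self._make(self.data * other.data, (self, other))

        def _bw():
            if self.requires_grad:
                self._acc(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(out.grad * self.data, other.data.shape))

        if out.requires_grad:
            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = self._make(self.data / other.data, (self, other))

        def _bw():
            if self.requires_grad:
                self._acc(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(
                    -out.grad * self.data / (other.data**2), other.data.shape))

        if out.requires_grad:
            out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out = self._make(self.data**exponent, (self,))

        def _bw():
            if self.requires_grad:
                self._acc(out.grad * exponent * self.data ** (exponent - 1))

        if out.requires_grad:
            out._backward = _bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = self._make(self.data @ other.data, (self, other))

        def _bw():
            if self.requires_grad:
                ga = out.grad @ np.swapaxes(other.data, -1, -2)
                self._acc(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ out.grad
                other._acc(_unbroadcast(gb, other.data.shape))

        if out.requires_grad:
            out._backward = _bw
        return out

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        out = self._make(self.data.reshape(*shape), (self,))

        def _bw():
            if self.requires_grad:
                self._acc(out.grad.reshape(self.data.shape))

        if out.requires_grad:
            out._backward = _bw
        return out

    def transpose(self, *axes):
        out = self._make(self.data.transpose(*axes), (self,))
        inv = np.argsort(axes)

        def _bw():
            if self.requires_grad:
                self._acc(out.grad.transpose(*inv))

        if out.requires_grad:
            out._backward = _bw
        return out

    def swapaxes(self, a: int, b: int):
        out = self._make(np.swapaxes(self.data, a, b), (self,))

        def _bw():
            if self.requires_grad:
                self._acc(np.swapaxes(out.grad, a, b))

        if out.requires_grad:
            out._backward = _bw
        return out

    def __getitem__(self, key):
        """Basic indexing (ints/slices); safe because such keys never alias."""
        out = self._make(self.data[key], (self,))

        def _bw():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                g[key] = out.grad
                self._acc(g)

        if out.requires_grad:
            out._backward = _bw
        return out

    def take0(self, idx: np.ndarray):
        """Gather rows along axis 0 with an integer array (embedding lookup).

        Duplicate indices accumulate correctly in the backward pass.
        """
        idx = np.asarray(idx)
        out = self._make(np.take(self.data, idx, axis=0), (self,))

        def _bw():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._acc(g)

        if out.requires_grad:
            out._backward = _bw
        return out

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def _bw():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._acc(np.broadcast_to(g, self.data.shape))

        if out.requires_grad:
            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- pointwise nonlinearities ----------------------------------------------

    def exp(self):
        out = self._make(np.exp(self.data), (self,))

        def _bw():
            if self.requires_grad:
                self._acc(out.grad * out.data)

        if out.requires_grad:
            out._backward = _bw
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,))

        def _bw():
            if self.requires_grad:
                self._acc(out.grad / self.data)

        if out.requires_grad:
            out._backward = _bw
        return out

    def tanh(self):
        out = self._make(np.tanh(self.data), (self,))

        def _bw():
            if self.requires_grad:
                self._acc(out.grad * (1.0 - out.data**2))

        if out.requires_grad:
            out._backward = _bw
        return out

    def sigmoid(self):
        s = np.where(self.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(self.data))),
                     np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))))
        out = self._make(s, (self,))

        def _bw():
            if self.requires_grad:
                self._acc(out.grad * out.data * (1.0 - out.data))

        if out.requires_grad:
            out._backward = _bw
        return out

    def relu(self):
        out = self._make(np.maximum(self.data, 0.0), (self,))

        def _bw():
            if self.requires_grad:
                self._acc(out.grad * (self.data > 0))

        if out.requires_grad:
            out._backward = _bw
        return out

    def softplus(self):
        out = self._make(np.logaddexp(0.0, self.data), (self,))

        def _bw():
            if self.requires_grad:
                x = self.data
                sig = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                               np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
                self._acc(out.grad * sig)

        if out.requires_grad:
            out._backward = _bw
        return out

    def softmax(self, axis: int = -1):
        # max-subtraction: the subtracted constant is piecewise constant so it
        # does not affect the gradient
        x = self.data
        e = np.exp(x - x.max(axis=axis, keepdims=True))
        s = e / e.sum(axis=axis, keepdims=True)
        out = self._make(s, (self,))

        def _bw():
            if self.requires_grad:
                g = out.grad
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._acc(s * (g - dot))

        if out.requires_grad:
            out._backward = _bw
        return out

    # -- autodiff driver --------------------------------------------------------

    def backward(self):
        # iterative post-order DFS (recurrent nets make deep graphs)
        topo: list[Tensor] = []
        visited: set[int] = set()
        work: list[tuple[Tensor, bool]] = [(self, False)]
        while work:
            node, processed = work.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            work.append((node, True))
            for child in node._prev:
                if id(child) not in visited:
                    work.append((child, False))
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.grad is not None and node._backward is not None:
                node._backward()
        # break closure reference cycles so buffers free by refcount, not gc;
        # leaves (parameters, inputs) keep their gradients
        for node in topo:
            if node._prev:
                node.grad = None
            node._backward = None
            node._prev = ()


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    data = np.stack([t.data for t in tensors], axis=axis)
    prev = tuple(t for t in tensors if t.requires_grad) if _grad_enabled else ()
    out = Tensor(data, requires_grad=bool(prev), _prev=prev)

    def _bw():
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._acc(np.take(out.grad, i, axis=axis))

    if out.requires_grad:
        out._backward = _bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    prev = tuple(t for t in tensors if t.requires_grad) if _grad_enabled else ()
    out = Tensor(data, requires_grad=bool(prev), _prev=prev)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw():
        for i, t in enumerate(tensors):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(offsets[i], offsets[i + 1])
                t._acc(out.grad[tuple(sl)])

    if out.requires_grad:
        out._backward = _bw
    return out


class Adam:
    """Adaptive-moment optimizer over a list of Parameters."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1**self.t)
            vhat = self._v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data  # decoupled


def numeric_grad(f, param: Tensor, eps: float = 1e-5) -> np.ndarray:
    """Central finite-difference gradient of scalar-valued `f` w.r.t. `param`.

    `f` is called with no arguments and must re-run the forward pass reading
    `param.data` in place.
    """
    g = np.zeros_like(param.data)
    flat = param.data.ravel()
    gflat = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f()
        flat[i] = orig - eps
        fm = f()
        flat[i] = orig
        gflat[i] = (fp - fm) / (2 * eps)
    return g
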
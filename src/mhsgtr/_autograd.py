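"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the joint training objective needs:
broadcasting arithmetic, matrix products, ReLU/LeakyReLU, abs, exp, log,
transpose, concatenation, reductions and a numerically stabilised softmax.
Gradients are accumulated in float64; graphs are rebuilt every step
(define-by-run), so no retain/free bookkeeping is needed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g, out=None):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g, out=None: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g, out=None):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g, out=None):
            return (_unbroadcast(g / other.data, self.data.shape),
                    _unbroadcast(-g * self.data / other.data ** 2,
                                 other.data.shape))

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g, out=None):
            return (g @ other.data.T, self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g, out=None):
            return (g * p * self.data ** (p - 1),)

        return self._make(out_data, (self,), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g, out=None):
            return (g * (self.data > 0.0),)

        return self._make(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.01):
        out_data = np.where(self.data > 0.0, self.data, slope * self.data)

        def backward(g, out=None):
            return (g * np.where(self.data > 0.0, 1.0, slope),)

        return self._make(out_data, (self,), backward)

    def abs(self):
        out_data = np.abs(self.data)

        def backward(g, out=None):
            return (g * np.sign(self.data),)

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, out=None):
            return (g * out_data,)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g, out=None):
            return (g / self.data,)

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g, out=None):
            return (g * 0.5 / out_data,)

        return self._make(out_data, (self,), backward)

    # -- structural ops ---------------------------------------------------------
    @property
    def T(self):
        out_data = self.data.T

        def backward(g, out=None):
            return (g.T,)

        return self._make(out_data, (self,), backward)

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, out=None):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return self._make(out_data, (self,), backward)

    # -- autodiff driver --------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None or t._backward is None:
                if t._backward is None and g is not None:
                    t.grad = g if t.grad is None else t.grad + g
                continue
            parent_grads = t._backward(g)
            for p, pg in zip(t._parents, parent_grads):
                if not p.requires_grad:
                    continue
                if p._backward is None:  # leaf
                    p.grad = pg if p.grad is None else p.grad + pg
                else:
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg

    def zero_grad(self):
        self.grad = None


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g, out=None):
        return tuple(np.split(g, splits, axis=axis))

    out = Tensor(out_data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    """Row-stabilised softmax built from primitive ops (exact gradient)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant w.r.t. grad
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Full-batch Adam with the standard bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
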
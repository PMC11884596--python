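"""A small reverse-mode automatic-differentiation engine over numpy arrays.

Just enough machinery for the fusion model: dense affine maps, scaled
dot-product attention, ReLU/sigmoid/log, reductions, concatenation, dropout
masks, and an AdamW optimizer.  Gradients flow through a dynamically built
tape; ``Tensor.backward()`` runs the tape in reverse topological order.

Numerics are float64 throughout — the models here are small, and exact
reproducibility across runs matters more than speed.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> np.ndarray:
        return self.data

    def _make(self, data, prev, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in prev))
        if out.requires_grad:
            out._prev = tuple(prev)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += _unbroadcast(grad, self.data.shape)

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out = self._make(self.data + other.data, (self, other), None)

        def backward(grad):
            self._accum(grad)
            other._accum(grad)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)
        out._backward = lambda grad: self._accum(-grad)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = self._make(self.data * other.data, (self, other), None)

        def backward(grad):
            self._accum(grad * other.data)
            other._accum(grad * self.data)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / scalar)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out = self._make(self.data @ other.data, (self, other), None)

        def backward(grad):
            self._accum(grad @ other.data.T)
            other._accum(self.data.T @ grad)

        out._backward = backward
        return out

    __matmul__ = matmul

    def transpose(self) -> "Tensor":
        out = self._make(self.data.T, (self,), None)
        out._backward = lambda grad: self._accum(grad.T)
        return out

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape
        out = self._make(self.data.reshape(*shape), (self,), None)
        out._backward = lambda grad: self._accum(grad.reshape(old))
        return out

    # -- nonlinearities and reductions ---------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = self._make(self.data * mask, (self,), None)
        out._backward = lambda grad: self._accum(grad * mask)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = self._make(s, (self,), None)
        out._backward = lambda grad: self._accum(grad * s * (1.0 - s))
        return out

    def log(self) -> "Tensor":
        out = self._make(np.log(self.data), (self,), None)
        out._backward = lambda grad: self._accum(grad / self.data)
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        mask = (self.data > lo) & (self.data < hi)
        out = self._make(np.clip(self.data, lo, hi), (self,), None)
        out._backward = lambda grad: self._accum(grad * mask)
        return out

    def softmax(self) -> "Tensor":
        """Row softmax over the last axis."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=-1, keepdims=True)
        out = self._make(s, (self,), None)

        def backward(grad):
            dot = (grad * s).sum(axis=-1, keepdims=True)
            self._accum(s * (grad - dot))

        out._backward = backward
        return out

    def sum(self) -> "Tensor":
        out = self._make(self.data.sum(), (self,), None)
        out._backward = lambda grad: self._accum(np.full_like(self.data, grad))
        return out

    def mean(self, axis: int | None = None) -> "Tensor":
        out = self._make(self.data.mean(axis=axis), (self,), None)
        n = self.data.size if axis is None else self.data.shape[axis]

        def backward(grad):
            if axis is None:
                self._accum(np.full_like(self.data, grad / n))
            else:
                self._accum(np.expand_dims(grad, axis) * np.ones_like(self.data) / n)

        out._backward = backward
        return out

    def take_row(self, index: int) -> "Tensor":
        out = self._make(self.data[index], (self,), None)

        def backward(grad):
            full = np.zeros_like(self.data)
            full[index] = grad
            self._accum(full)

        out._backward = backward
        return out

    # -- graph walk ----------------------------------------------------------
    def backward(self, grad: np.ndarray | float = 1.0) -> None:
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    out = Tensor(out_data, requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def backward(grad):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(grad[tuple(sl)])

        out._prev = tuple(tensors)
        out._backward = backward
    return out


def stack_rows(tensors: list[Tensor]) -> Tensor:
    return concat([t.reshape(1, -1) for t in tensors], axis=0)


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for key, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            m_hat = self.m[key] / (1 - self.beta1 ** self.t)
            v_hat = self.v[key] / (1 - self.beta2 ** self.t)
            p.data -= self.lr * (
                m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data
            )
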
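"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model is a handful of small fully connected networks joined by
concatenations, elementwise products and a partial-likelihood head, so a
compact tape-based engine covers every operation the training loop needs.
Gradients are exact (no approximation); correctness is enforced by
finite-difference tests.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape entry."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        value,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    @property
    def ndim(self) -> int:
        return self.value.ndim

    def item(self) -> float:
        return float(self.value)

    def detach(self) -> "Tensor":
        return Tensor(self.value.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.value.shape)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad: np.ndarray | float | None = None) -> None:
        """Run reverse-mode accumulation from this node."""
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -------------------------------------------------------------- operators
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.value + other.value, parents=(self, other))
        out._backward = lambda g: (self._accumulate(g), other._accumulate(g))
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.value, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.value * other.value, parents=(self, other))

        def bwd(g):
            self._accumulate(g * other.value)
            other._accumulate(g * self.value)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            raise TypeError("division only supported by constants")
        return self * (1.0 / float(other))

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.value @ other.value, parents=(self, other))

        def bwd(g):
            self._accumulate(g @ other.value.T)
            other._accumulate(self.value.T @ g)

        out._backward = bwd
        return out

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.value.T, parents=(self,))
        out._backward = lambda g: self._accumulate(g.T)
        return out

    # ------------------------------------------------------------ nonlinear
    def relu(self) -> "Tensor":
        mask = self.value > 0
        out = Tensor(np.where(mask, self.value, 0.0), parents=(self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.value, -500, 500)))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.value)
        out = Tensor(t, parents=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - t * t))
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.value), parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.value)
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.value)
        out = Tensor(e, parents=(self,))
        out._backward = lambda g: self._accumulate(g * e)
        return out

    def square(self) -> "Tensor":
        out = Tensor(self.value**2, parents=(self,))
        out._backward = lambda g: self._accumulate(g * 2.0 * self.value)
        return out

    def abs(self) -> "Tensor":
        out = Tensor(np.abs(self.value), parents=(self,))
        out._backward = lambda g: self._accumulate(g * np.sign(self.value))
        return out

    def clamp(self, lo: float, hi: float) -> "Tensor":
        """Clip values; gradient is zero where the clip is active."""
        mask = (self.value > lo) & (self.value < hi)
        out = Tensor(np.clip(self.value, lo, hi), parents=(self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.value.shape))

        out._backward = bwd
        return out

    def mean(self, axis: int | None = None) -> "Tensor":
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis) / n

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.value[idx], parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.value)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bwd
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.value.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.value.shape))
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.value for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out._backward = bwd
    return out


class Adam:
    """Adam optimizer over a dict of named parameter tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self, only: Iterable[str] | None = None) -> None:
        """Apply one update; `only` restricts to a subset of parameter names."""
        names = set(only) if only is not None else None
        self.t += 1
        bias1 = 1.0 - self.b1**self.t
        bias2 = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            if p.grad is None or (names is not None and k not in names):
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad**2
            mhat = self.m[k] / bias1
            vhat = self.v[k] / bias2
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
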
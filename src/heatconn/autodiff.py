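"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model and explainer in this package need gradients of scalar losses with
respect to dense parameters (GIN weights, diffusion scales, explanation
masks).  The computations involved are ordinary dense linear algebra on
small matrices, so a compact tape-based autograd over :class:`numpy.ndarray`
is sufficient: each :class:`Tensor` records the operation that produced it
and backpropagation walks the tape in reverse topological order.

Only the operations the package actually uses are provided (broadcasted
arithmetic, batched matrix products, ReLU/sigmoid/exp/log, reductions,
concatenation, clamping).  Gradients follow the standard rules; broadcasting
is undone in the backward pass by summing over the broadcast axes.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "Adam", "SGD"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("value", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    @property
    def ndim(self) -> int:
        return self.value.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, value: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(value)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self) -> None:
        """Backpropagate from this scalar tensor through the tape."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: tapes can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.value.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = self._make(self.value + other.value, (self, other), None)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        out._backward = backward if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = self._make(-self.value, (self,), None)

        def backward(g: np.ndarray) -> None:
            self._accumulate(-g)

        out._backward = backward if out.requires_grad else None
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = self._make(self.value * other.value, (self, other), None)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * other.value)
            if other.requires_grad:
                other._accumulate(g * self.value)

        out._backward = backward if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float) -> "Tensor":
        p = float(p)
        out = self._make(self.value ** p, (self,), None)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * p * self.value ** (p - 1.0))

        out._backward = backward if out.requires_grad else None
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = self._make(self.value @ other.value, (self, other), None)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g @ np.swapaxes(other.value, -1, -2))
            if other.requires_grad:
                other._accumulate(np.swapaxes(self.value, -1, -2) @ g)

        out._backward = backward if out.requires_grad else None
        return out

    # ------------------------------------------------------------ elementwise
    def relu(self) -> "Tensor":
        mask = self.value > 0
        out = self._make(np.where(mask, self.value, 0.0), (self,), None)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * mask)

        out._backward = backward if out.requires_grad else None
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.value))
        out = self._make(s, (self,), None)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * s * (1.0 - s))

        out._backward = backward if out.requires_grad else None
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.value)
        out = self._make(e, (self,), None)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * e)

        out._backward = backward if out.requires_grad else None
        return out

    def log(self) -> "Tensor":
        out = self._make(np.log(self.value), (self,), None)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g / self.value)

        out._backward = backward if out.requires_grad else None
        return out

    def clamp(self, lo: float, hi: float) -> "Tensor":
        """Clip values to [lo, hi]; gradient flows only inside the interval."""
        inside = (self.value > lo) & (self.value < hi)
        out = self._make(np.clip(self.value, lo, hi), (self,), None)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * inside)

        out._backward = backward if out.requires_grad else None
        return out

    # -------------------------------------------------------------- structure
    def swap_last(self) -> "Tensor":
        """Transpose the last two axes (batched matrix transpose)."""
        out = self._make(np.swapaxes(self.value, -1, -2), (self,), None)

        def backward(g: np.ndarray) -> None:
            self._accumulate(np.swapaxes(g, -1, -2))

        out._backward = backward if out.requires_grad else None
        return out

    def reshape(self, *shape: int) -> "Tensor":
        orig = self.value.shape
        out = self._make(self.value.reshape(shape), (self,), None)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g.reshape(orig))

        out._backward = backward if out.requires_grad else None
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self._make(self.value.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g: np.ndarray) -> None:
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.value.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.value.shape).copy())

        out._backward = backward if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    ts = [Tensor._lift(t) for t in tensors]
    values = [t.value for t in ts]
    out_val = np.concatenate(values, axis=axis)
    out = Tensor(out_val)
    if not any(t.requires_grad for t in ts):
        return out
    out.requires_grad = True
    out._parents = tuple(ts)
    sizes = [v.shape[axis] for v in values]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = backward
    return out


class SGD:
    """Plain gradient descent; used for small deterministic fits in tests."""

    def __init__(self, params: Sequence[Tensor], lr: float):
        self.params = [p for p in params if p.requires_grad]
        self.lr = float(lr)

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.value -= self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class Adam:
    """Adaptive-moment optimizer with optional decoupled weight decay."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.weight_decay = float(weight_decay)
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            if self.weight_decay:
                # decoupled decay: shrink weights directly, not through g
                p.value *= 1.0 - self.lr * self.weight_decay
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
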
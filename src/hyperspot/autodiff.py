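"""Minimal reverse-mode automatic differentiation over numpy arrays.

A tape-based engine with exactly the operations the model needs: affine maps,
Elu/ReLU, elementwise arithmetic with broadcasting, reductions, sparse-dense
products, concatenation, row gathering and a global max. Everything is float64
end to end, which is what lets analytic gradients match central differences to
~1e-6 in the gradient checks.

Typical use::

    x = Tensor(np.random.randn(3, 4), requires_grad=True)
    loss = ((x @ w + b).elu() ** 2).mean()
    loss.backward()
    x.grad  # dloss/dx
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = ["Tensor", "cat", "spmm"]


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
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- graph machinery ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Accumulate gradients of this scalar into every ancestor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed recursion limits
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, _parents=(self, other), _backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor(-self.data, _parents=(self,), _backward=bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, _parents=(self, other), _backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return Tensor(self.data / other.data, _parents=(self, other), _backward=bw)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents supported")

        def bw(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor(self.data**exponent, _parents=(self,), _backward=bw)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor(self.data @ other.data, _parents=(self, other), _backward=bw)

    @property
    def T(self) -> "Tensor":
        def bw(g):
            if self.requires_grad:
                self._accum(g.T)

        return Tensor(self.data.T, _parents=(self,), _backward=bw)

    # -- elementwise nonlinearities ---------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor(self.data * mask, _parents=(self,), _backward=bw)

    def elu(self, alpha: float = 1.0) -> "Tensor":
        pos = self.data > 0
        out = np.where(pos, self.data, alpha * np.expm1(self.data))

        def bw(g):
            if self.requires_grad:
                self._accum(g * np.where(pos, 1.0, out + alpha))

        return Tensor(out, _parents=(self,), _backward=bw)

    def exp(self) -> "Tensor":
        out = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * out)

        return Tensor(out, _parents=(self,), _backward=bw)

    def log(self) -> "Tensor":
        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bw)

    def sqrt(self) -> "Tensor":
        out = np.sqrt(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out)

        return Tensor(out, _parents=(self,), _backward=bw)

    def clamp(self, lo: float, hi: float) -> "Tensor":
        """Clip values; gradient is zero outside [lo, hi] (straight-through not used)."""
        inside = (self.data >= lo) & (self.data <= hi)

        def bw(g):
            if self.requires_grad:
                self._accum(g * inside)

        return Tensor(np.clip(self.data, lo, hi), _parents=(self,), _backward=bw)

    # -- reductions & shaping ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,), _backward=bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self) -> "Tensor":
        """Global maximum; gradient routed to the first argmax entry."""
        flat_idx = int(np.argmax(self.data))

        def bw(g):
            if self.requires_grad:
                gg = np.zeros_like(self.data)
                gg.flat[flat_idx] = float(np.asarray(g).ravel()[0])
                self._accum(gg)

        return Tensor(self.data.max(), _parents=(self,), _backward=bw)

    def take_rows(self, idx: np.ndarray) -> "Tensor":
        idx = np.asarray(idx, dtype=np.int64)

        def bw(g):
            if self.requires_grad:
                gg = np.zeros_like(self.data)
                np.add.at(gg, idx, g)
                self._accum(gg)

        return Tensor(self.data[idx], _parents=(self,), _backward=bw)


def cat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along ``axis``."""
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=bw,
    )


def spmm(A: sparse.spmatrix, H: Tensor) -> Tensor:
    """Sparse-constant @ dense-variable product; backward uses A^T."""
    A = sparse.csr_matrix(A)

    def bw(g):
        if H.requires_grad:
            H._accum(A.T @ g)

    return Tensor(A @ H.data, _parents=(H,), _backward=bw)
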
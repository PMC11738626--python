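"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the graph backbones and the attention head
need: broadcasted arithmetic, matmul, pointwise nonlinearities, reductions,
row gather / segment scatter-add (message passing), concatenation and basic
slicing.  All arrays are float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concatenate",
    "gather_rows",
    "segment_sum",
    "segment_softmax",
    "relu",
    "silu",
    "sigmoid",
    "tanh",
    "exp",
    "log",
    "sqrt",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # remove leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative topo sort; graphs can be deep
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray, fresh: bool = False):
        # `fresh` marks a grad array newly allocated by the caller, safe to
        # own without copying
        if self.grad is None:
            self.grad = grad if fresh else grad.copy()
        else:
            self.grad += grad

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g, fresh=True)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape), fresh=True)
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape), fresh=True)

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape), fresh=True)
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape),
                    fresh=True,
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1), fresh=True)

        return Tensor._make(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T, fresh=True)
            if other.requires_grad:
                other._accum(self.data.T @ g, fresh=True)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy(), fresh=True)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy(), fresh=True)

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def __getitem__(self, key):
        def backward(g):
            if not self.requires_grad:
                return
            out = np.zeros_like(self.data)
            np.add.at(out, key, g)
            self._accum(out)

        return Tensor._make(self.data[key], (self,), backward)


# -- pointwise nonlinearities ------------------------------------------------


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)

    def backward(g):
        if x.requires_grad:
            x._accum(g * (1.0 - y**2), fresh=True)

    return Tensor._make(y, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x._accum(g * y * (1.0 - y), fresh=True)

    return Tensor._make(y, (x,), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask, fresh=True)

    return Tensor._make(x.data * mask, (x,), backward)


def silu(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    y = x.data * s

    def backward(g):
        if x.requires_grad:
            x._accum(g * (s + y * (1.0 - s)), fresh=True)

    return Tensor._make(y, (x,), backward)


def exp(x: Tensor) -> Tensor:
    y = np.exp(x.data)

    def backward(g):
        if x.requires_grad:
            x._accum(g * y, fresh=True)

    return Tensor._make(y, (x,), backward)


def log(x: Tensor) -> Tensor:
    def backward(g):
        if x.requires_grad:
            x._accum(g / x.data, fresh=True)

    return Tensor._make(np.log(x.data), (x,), backward)


def sqrt(x: Tensor) -> Tensor:
    y = np.sqrt(x.data)

    def backward(g):
        if x.requires_grad:
            x._accum(g * 0.5 / y, fresh=True)

    return Tensor._make(y, (x,), backward)


# -- structural ops ----------------------------------------------------------


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def _scatter_rows(index: np.ndarray, values: np.ndarray, n: int) -> np.ndarray:
    """Row scatter-add via per-column bincount (faster than np.add.at)."""
    if values.ndim == 1:
        return np.bincount(index, weights=values, minlength=n)
    return np.stack(
        [np.bincount(index, weights=values[:, c], minlength=n)
         for c in range(values.shape[1])],
        axis=1,
    )


def sparse_matmul(S, x: Tensor) -> Tensor:
    """out = S @ x for a constant scipy sparse matrix S (grad: S.T @ g).

    Used for neighbor aggregation: with S[i, j] = w_e for each edge j -> i,
    this computes the weighted sum of neighbor rows in one pass.
    """

    ST = S.T.tocsr() if x.requires_grad else None

    def backward(g):
        if x.requires_grad:
            x._accum(ST @ g, fresh=True)

    return Tensor._make(S @ x.data, (x,), backward)


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """x[index] along axis 0, with scatter-add backward."""
    index = np.asarray(index, dtype=np.intp)

    def backward(g):
        if x.requires_grad:
            x._accum(_scatter_rows(index, g, x.data.shape[0]), fresh=True)

    return Tensor._make(x.data[index], (x,), backward)


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """out[s] = sum of rows of x whose segment_ids == s."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)

    def backward(g):
        if x.requires_grad:
            x._accum(g[segment_ids], fresh=True)

    return Tensor._make(
        _scatter_rows(segment_ids, x.data, num_segments), (x,), backward
    )


def segment_softmax(logits: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax normalized within each segment.

    `logits` is a length-M vector (or Mx1); returns weights of the same shape
    that are nonnegative and sum to one within each segment.  The max-shift is
    treated as a constant, which leaves the gradient unchanged.
    """
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    flat = logits if logits.ndim == 1 else logits.reshape(-1)
    shift = np.full(num_segments, -np.inf)
    np.maximum.at(shift, segment_ids, flat.data)
    e = exp(flat - shift[segment_ids])
    denom = segment_sum(e.reshape(-1, 1), segment_ids, num_segments).reshape(-1)
    w = e / gather_rows(denom.reshape(-1, 1), segment_ids).reshape(-1)
    return w if logits.ndim == 1 else w.reshape(*logits.shape)
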
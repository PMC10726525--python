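"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The whole model stack (graph encoders, dense branches, fusion head) is
expressed in terms of the primitives here.  Tensors record a closure that
accumulates gradients into their parents; :meth:`Tensor.backward` runs the
closures in reverse topological order.

Design notes
------------
* Gradients are plain ``float64`` ndarrays; broadcasting in ``+``/``*``/``-``
  and division is undone by summing the gradient over broadcast axes.
* Graph operations (gather / segment-sum / segment-max) are first-class
  primitives, which is what makes sparse message passing differentiable
  without materialising adjacency matrices.
* There is no graph retention or higher-order differentiation: one forward,
  one backward, then the tape is garbage.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather",
    "segment_sum",
    "segment_max",
    "segment_softmax",
]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # remove leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- bookkeeping ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: molecule batches can create deep tapes
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
        self._accum(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return Tensor(self.data / other.data, parents=(self, other), backward=backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=backward)

    def __pow__(self, p: float):
        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor(self.data**p, parents=(self,), backward=backward)

    # -- elementwise nonlinearities -------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor(out_data, parents=(self,), backward=backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=backward)

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)

        def backward(g):
            if self.requires_grad:
                self._accum(g * factor)

        return Tensor(self.data * factor, parents=(self,), backward=backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor(out_data, parents=(self,), backward=backward)

    def sqrt(self):
        return self**0.5

    # -- reductions / reshaping ----------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=backward)

    @property
    def T(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g.T)

        return Tensor(self.data.T, parents=(self,), backward=backward)


# -- free functions -----------------------------------------------------


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, part in zip(tensors, parts):
            if t.requires_grad:
                t._accum(part)

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=backward,
    )


def gather(x: Tensor, idx) -> Tensor:
    """Row-gather ``x[idx]``; gradient scatter-adds back into ``x``."""
    idx = np.asarray(idx, dtype=np.intp)

    def backward(g):
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            np.add.at(acc, idx, g)
            x._accum(acc)

    return Tensor(x.data[idx], parents=(x,), backward=backward)


def segment_sum(x: Tensor, seg, n_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``n_segments`` buckets given per-row segment ids."""
    seg = np.asarray(seg, dtype=np.intp)
    out_data = np.zeros((n_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(out_data, seg, x.data)

    def backward(g):
        if x.requires_grad:
            x._accum(g[seg])

    return Tensor(out_data, parents=(x,), backward=backward)


def segment_max(x: Tensor, seg, n_segments: int) -> Tensor:
    """Per-segment elementwise maximum (e.g. global max pooling over graphs).

    Gradient flows to every row attaining the maximum, split evenly on ties.
    Empty segments are an error: a pooled graph must have at least one node.
    """
    seg = np.asarray(seg, dtype=np.intp)
    counts = np.bincount(seg, minlength=n_segments)
    if np.any(counts == 0):
        raise ValueError("segment_max: empty segment (graph with no nodes)")
    out_data = np.full((n_segments,) + x.data.shape[1:], -np.inf)
    np.maximum.at(out_data, seg, x.data)
    is_max = x.data == out_data[seg]
    n_max = np.zeros_like(out_data)
    np.add.at(n_max, seg, is_max.astype(np.float64))

    def backward(g):
        if x.requires_grad:
            x._accum(is_max * (g / n_max)[seg])

    return Tensor(out_data, parents=(x,), backward=backward)


def segment_softmax(logits: Tensor, seg, n_segments: int) -> Tensor:
    """Softmax over rows sharing a segment id (attention normalisation).

    The max-shift is treated as a constant, which leaves the gradient exact.
    """
    seg = np.asarray(seg, dtype=np.intp)
    shift = np.full((n_segments,) + logits.data.shape[1:], -np.inf)
    np.maximum.at(shift, seg, logits.data)
    shifted = logits + Tensor(-shift[seg])
    e = shifted.exp()
    denom = segment_sum(e, seg, n_segments)
    return e / gather(denom, seg)
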
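"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Only the operations the message-passing layers need are provided: dense
linear maps, elementwise arithmetic and rectifiers, row gather/scatter for
arc-wise message passing, segment softmax for attention, segment means for
pooling, dropout, and numerically stable classification losses. Gradients
are accumulated by a topologically ordered backward sweep from a scalar loss.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def scale(a: Tensor, c) -> Tensor:
    """Multiply by a constant array/scalar (no gradient through ``c``)."""
    c = np.asarray(c, dtype=np.float64)
    out_data = a.data * c

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * c, a.data.shape))

    return Tensor(out_data, parents=(a,), backward=backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.swapaxes(-1, -2))
        if b.requires_grad:
            b._accumulate(a.data.swapaxes(-1, -2) @ g)

    return Tensor(out_data, parents=(a, b), backward=backward)


def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """x @ W^T (+ b), with W of shape (out, in)."""
    out = matmul(x, transpose(weight))
    if bias is not None:
        out = add(out, bias)
    return out


def transpose(a: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g.T)

    return Tensor(a.data.T, parents=(a,), backward=backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return Tensor(a.data * mask, parents=(a,), backward=backward)


def leaky_relu(a: Tensor, negative_slope: float = 0.2) -> Tensor:
    factor = np.where(a.data > 0, 1.0, negative_slope)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * factor)

    return Tensor(a.data * factor, parents=(a,), backward=backward)


def gather_rows(a: Tensor, index: np.ndarray) -> Tensor:
    """Select rows of ``a`` by integer index (repeats allowed)."""
    index = np.asarray(index, dtype=np.int64)

    def backward(g):
        if a.requires_grad:
            grad = np.zeros_like(a.data)
            np.add.at(grad, index, g)
            a._accumulate(grad)

    return Tensor(a.data[index], parents=(a,), backward=backward)


def segment_sum(a: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``a`` into ``n_segments`` buckets given by ``segments``."""
    segments = np.asarray(segments, dtype=np.int64)
    out_data = np.zeros((n_segments,) + a.data.shape[1:])
    np.add.at(out_data, segments, a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[segments])

    return Tensor(out_data, parents=(a,), backward=backward)


def segment_mean(a: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Mean of rows per segment; empty segments yield zero rows."""
    segments = np.asarray(segments, dtype=np.int64)
    counts = np.bincount(segments, minlength=n_segments).astype(np.float64)
    safe = np.maximum(counts, 1.0)
    summed = segment_sum(a, segments, n_segments)
    return scale(summed, (1.0 / safe)[:, None] if a.data.ndim > 1 else 1.0 / safe)


def segment_softmax(logits: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of a 1-d logit vector within each segment (numerically stable)."""
    segments = np.asarray(segments, dtype=np.int64)
    seg_max = np.full(n_segments, -np.inf)
    np.maximum.at(seg_max, segments, logits.data)
    shifted = logits.data - seg_max[segments]
    exp = np.exp(shifted)
    seg_sum = np.zeros(n_segments)
    np.add.at(seg_sum, segments, exp)
    alpha = exp / seg_sum[segments]

    def backward(g):
        if logits.requires_grad:
            # d alpha_i / d logit_j = alpha_i (delta_ij - alpha_j) within segment
            weighted = np.zeros(n_segments)
            np.add.at(weighted, segments, g * alpha)
            logits._accumulate(alpha * (g - weighted[segments]))

    return Tensor(alpha, parents=(logits,), backward=backward)


def dropout(a: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when ``rng`` is None (evaluation mode)."""
    if rng is None or rate <= 0.0:
        return a
    if not (0.0 <= rate < 1.0):
        raise ValueError("dropout rate must be in [0, 1)")
    mask = (rng.random(a.data.shape) >= rate) / (1.0 - rate)
    return scale(a, mask)


def reshape(a: Tensor, shape) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    return Tensor(a.data.reshape(shape), parents=(a,), backward=backward)


def bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean sigmoid cross-entropy on raw logits (log-sum-exp stabilised)."""
    labels = np.asarray(labels, dtype=np.float64)
    z = logits.data
    if z.shape != labels.shape:
        raise ValueError("logits/labels shape mismatch")
    # loss_i = max(z,0) - z*y + log(1 + exp(-|z|))
    losses = np.maximum(z, 0) - z * labels + np.log1p(np.exp(-np.abs(z)))
    n = max(z.size, 1)

    def backward(g):
        if logits.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-z))
            logits._accumulate(g * (sig - labels) / n)

    return Tensor(losses.mean(), parents=(logits,), backward=backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy for (n, k) logits and integer class labels."""
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data
    if z.ndim != 2 or labels.shape != (z.shape[0],):
        raise ValueError("expected (n, k) logits and (n,) integer labels")
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    losses = lse - z[np.arange(z.shape[0]), labels]
    n = z.shape[0]

    def backward(g):
        if logits.requires_grad:
            soft = np.exp(z - zmax)
            soft /= soft.sum(axis=1, keepdims=True)
            soft[np.arange(n), labels] -= 1.0
            logits._accumulate(g * soft / n)

    return Tensor(losses.mean(), parents=(logits,), backward=backward)
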
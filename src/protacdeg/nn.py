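"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical engine behind the degradation-capacity network: a
tape-based autodiff ``Tensor``, the handful of differentiable operations the
architecture needs (matrix products, gathers/scatters for embeddings and
edge messages, gated recurrences, pooling reductions, cross-entropy), and an
Adam optimizer.  All shapes in this package are small (pockets of a few
hundred atoms, linkers of a few dozen tokens), so dense NumPy kernels are
entirely adequate on one CPU.

Gradients are checked against central finite differences in the test suite;
nothing here is approximate.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "add",
    "mul",
    "matmul",
    "left_matmul_const",
    "scale",
    "concat",
    "sigmoid",
    "tanh",
    "leaky_relu",
    "gather_rows",
    "scatter_sum",
    "reduce_max",
    "reduce_mean",
    "reduce_sum",
    "reshape",
    "slice_cols",
    "row",
    "cross_entropy_logits",
    "softmax",
    "backward",
    "Adam",
    "glorot_uniform",
]


class Tensor:
    """A node in the computation graph holding a float64 array."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(
        self,
        data: np.ndarray,
        *,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward_fn: Callable[[np.ndarray], None] | None = None,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self._backward = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data: np.ndarray) -> None:
        super().__init__(np.array(data, dtype=np.float64), requires_grad=True)


def _make(data, parents, backward_fn) -> Tensor:
    t = Tensor(data, parents=parents, backward_fn=backward_fn)
    if not t.requires_grad:
        t._backward = None
        t.parents = ()
    return t


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g @ b.data.T)
        if b.requires_grad:
            b.accumulate(a.data.T @ g)

    return _make(out_data, (a, b), bwd)


def left_matmul_const(const: np.ndarray, x: Tensor) -> Tensor:
    """``const @ x`` where ``const`` carries no gradient (e.g. a normalized
    adjacency matrix)."""
    out_data = const @ x.data

    def bwd(g):
        if x.requires_grad:
            x.accumulate(const.T @ g)

    return _make(out_data, (x,), bwd)


def scale(x: Tensor, const: np.ndarray | float) -> Tensor:
    """Elementwise product with a non-learnable constant."""
    c = np.asarray(const, dtype=np.float64)
    out_data = x.data * c

    def bwd(g):
        if x.requires_grad:
            x.accumulate(_unbroadcast(g * c, x.data.shape))

    return _make(out_data, (x,), bwd)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t.accumulate(g[tuple(idx)])

    return _make(out_data, tuple(tensors), bwd)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g * s * (1.0 - s))

    return _make(s, (x,), bwd)


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g * (1.0 - t * t))

    return _make(t, (x,), bwd)


def leaky_relu(x: Tensor, negative_slope: float = 0.01) -> Tensor:
    mask = x.data >= 0
    out_data = np.where(mask, x.data, negative_slope * x.data)

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g * np.where(mask, 1.0, negative_slope))

    return _make(out_data, (x,), bwd)


def gather_rows(table: Tensor, index: np.ndarray) -> Tensor:
    """Embedding lookup: rows ``table[index]``; gradient scatter-adds back."""
    index = np.asarray(index, dtype=np.intp)
    out_data = table.data[index]

    def bwd(g):
        if table.requires_grad:
            acc = np.zeros_like(table.data)
            np.add.at(acc, index, g)
            table.accumulate(acc)

    return _make(out_data, (table,), bwd)


def scatter_sum(src: Tensor, index: np.ndarray, num_rows: int) -> Tensor:
    """``out[i] = sum over k with index[k] == i of src[k]`` (edge -> node)."""
    index = np.asarray(index, dtype=np.intp)
    out_data = np.zeros((num_rows, src.data.shape[1]), dtype=np.float64)
    np.add.at(out_data, index, src.data)

    def bwd(g):
        if src.requires_grad:
            src.accumulate(g[index])

    return _make(out_data, (src,), bwd)


def reduce_max(x: Tensor, axis: int = 0) -> Tensor:
    """Max over one axis; gradient flows to the (first) argmax entries."""
    arg = np.argmax(x.data, axis=axis)
    out_data = np.max(x.data, axis=axis)

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            if axis == 0:
                gx[arg, np.arange(x.data.shape[1])] = g
            else:  # pragma: no cover - only axis 0 used by the network
                raise NotImplementedError
            x.accumulate(gx)

    return _make(out_data, (x,), bwd)


def reduce_mean(x: Tensor, axis: int = 0) -> Tensor:
    n = x.data.shape[axis]
    out_data = x.data.mean(axis=axis)

    def bwd(g):
        if x.requires_grad:
            x.accumulate(np.broadcast_to(g / n, x.data.shape).copy())

    return _make(out_data, (x,), bwd)


def reduce_sum(x: Tensor, axis: int = 0) -> Tensor:
    out_data = x.data.sum(axis=axis)

    def bwd(g):
        if x.requires_grad:
            x.accumulate(np.broadcast_to(g, x.data.shape).copy())

    return _make(out_data, (x,), bwd)


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    out_data = x.data.reshape(shape)

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g.reshape(x.data.shape))

    return _make(out_data, (x,), bwd)


def slice_cols(x: Tensor, lo: int, hi: int) -> Tensor:
    out_data = x.data[:, lo:hi]

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[:, lo:hi] = g
            x.accumulate(gx)

    return _make(out_data, (x,), bwd)


def row(x: Tensor, i: int) -> Tensor:
    out_data = x.data[i : i + 1]

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[i : i + 1] = g
            x.accumulate(gx)

    return _make(out_data, (x,), bwd)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - np.max(logits)
    e = np.exp(z)
    return e / e.sum()


def cross_entropy_logits(logits: Tensor, target: int, weight: float = 1.0) -> Tensor:
    """Weighted negative log-likelihood of class ``target`` from raw logits.

    ``logits`` is a flat vector (one sample); the softmax and the log are
    fused for numerical stability.
    """
    p = softmax(logits.data.ravel())
    loss = -weight * np.log(max(p[target], 1e-300))

    def bwd(g):
        if logits.requires_grad:
            grad = p.copy()
            grad[target] -= 1.0
            logits.accumulate((g * weight * grad).reshape(logits.data.shape))

    return _make(np.float64(loss), (logits,), bwd)


def backward(loss: Tensor) -> None:
    """Reverse-accumulate gradients from a scalar loss."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(loss, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))
    loss.accumulate(np.ones_like(loss.data))
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam with the standard bias correction; shared parameters are
    deduplicated by identity so each receives a single update per step."""

    def __init__(
        self,
        parameters: Iterable[Parameter],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        unique: dict[int, Parameter] = {}
        for p in parameters:
            unique[id(p)] = p
        self.parameters = list(unique.values())
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.parameters]
        self._v = [np.zeros_like(p.data) for p in self.parameters]

    def zero_grad(self) -> None:
        for p in self.parameters:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.parameters, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
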
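"""Minimal reverse-mode tensor autodiff core.

Just enough machinery to train the fragment generator: dense matmul,
elementwise nonlinearities, row gather/scatter for message passing and
segment pooling, and a fused softmax cross-entropy.  Gradients are
accumulated by topological-order backward passes over a dynamically
recorded graph.  Inference runs with recording disabled
(:func:`no_grad`), which makes forward passes plain NumPy.

All arrays are float64; molecular graphs are tiny, so clarity beats
throughput everywhere except the batched training path.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled", "parameter",
           "relu", "sigmoid", "tanh", "matmul", "add", "sub", "mul", "concat",
           "split", "gather_rows", "scatter_add_rows", "scale_rows",
           "softmax_cross_entropy", "softmax", "add_all"]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(self, data, requires_grad=False, parents=(), backward_fn=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self.parents = parents if self.requires_grad else ()
        self.backward_fn = backward_fn if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        done: set[int] = set()
        expanded: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep (GRU over time)
            node, processed = stack.pop()
            if processed:
                done.add(id(node))
                topo.append(node)
                continue
            if id(node) in done or id(node) in expanded:
                continue
            expanded.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if id(p) not in done and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.backward_fn is not None and node.grad is not None:
                node.backward_fn(node.grad)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def parameter(data) -> Tensor:
    t = Tensor(np.asarray(data, dtype=np.float64))
    t.requires_grad = True  # parameters track gradients even under no_grad
    return t


def _accum(t: Tensor, g) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g, shape):
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _make(data, parents, backward_fn):
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=tuple(parents),
                  backward_fn=backward_fn if req else None)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), bwd)


def add_all(tensors) -> Tensor:
    tensors = list(tensors)
    out = tensors[0]
    for t in tensors[1:]:
        out = add(out, t)
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    return _make(out_data, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bwd(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return _make(out_data, (a, b), bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(g):
        _accum(x, g * mask)

    return _make(x.data * mask, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def bwd(g):
        _accum(x, g * s * (1 - s))

    return _make(s, (x,), bwd)


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)

    def bwd(g):
        _accum(x, g * (1 - t * t))

    return _make(t, (x,), bwd)


def concat(tensors, axis=-1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _make(out_data, tensors, bwd)


def split(x: Tensor, sizes, axis=-1):
    """Split along ``axis`` into pieces of the given sizes."""
    cuts = np.cumsum(sizes)[:-1]
    pieces_data = np.split(x.data, cuts, axis=axis)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    out = []
    for k, pd in enumerate(pieces_data):
        def bwd(g, k=k):
            full = np.zeros_like(x.data)
            sl = [slice(None)] * full.ndim
            sl[axis] = slice(int(offsets[k]), int(offsets[k + 1]))
            full[tuple(sl)] = g
            _accum(x, full)

        out.append(_make(pd, (x,), bwd))
    return out


def gather_rows(x: Tensor, idx) -> Tensor:
    """Select rows ``x[idx]``; backward scatter-adds into the source rows."""
    idx = np.asarray(idx, dtype=np.intp)
    out_data = x.data[idx]

    def bwd(g):
        acc = np.zeros_like(x.data)
        np.add.at(acc, idx, g)
        _accum(x, acc)

    return _make(out_data, (x,), bwd)


def scatter_add_rows(x: Tensor, idx, n_out: int) -> Tensor:
    """Sum rows of ``x`` into ``n_out`` buckets given by ``idx``.

    Used both for neighbor aggregation in message passing and for
    graph-level sum pooling (segment sum).
    """
    idx = np.asarray(idx, dtype=np.intp)
    out_data = np.zeros((n_out,) + x.data.shape[1:])
    np.add.at(out_data, idx, x.data)

    def bwd(g):
        _accum(x, g[idx])

    return _make(out_data, (x,), bwd)


def scale_rows(x: Tensor, coeff) -> Tensor:
    """Multiply each row of ``x`` by a per-row scalar coefficient."""
    coeff = np.asarray(coeff, dtype=np.float64).reshape(-1, 1)
    out_data = x.data * coeff

    def bwd(g):
        _accum(x, g * coeff)

    return _make(out_data, (x,), bwd)


def softmax(logits: np.ndarray, axis=-1) -> np.ndarray:
    """Plain-array softmax for inference-side sampling."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels, weights=None) -> Tensor:
    """Sum of per-row cross-entropies; optional per-row weights."""
    labels = np.asarray(labels, dtype=np.intp)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsumexp
    rows = np.arange(len(labels))
    w = np.ones(len(labels)) if weights is None else np.asarray(weights, float)
    loss = -(logp[rows, labels] * w).sum()

    def bwd(g):
        p = np.exp(logp)
        p[rows, labels] -= 1.0
        _accum(logits, g * p * w[:, None])

    return _make(loss, (logits,), bwd)
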
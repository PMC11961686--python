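"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model in :mod:`mslgat.model` is a full-batch graph network trained on a
few hundred nodes, so a small tape-based engine over float64 numpy arrays is
sufficient: every operation builds a node in a DAG and ``backward`` runs the
chain rule in reverse topological order.  Only the primitives the model needs
are implemented (broadcast arithmetic, matmul, gather / segment-sum for
edge-list message passing, the usual activations, and a numerically stable
binary cross-entropy on logits).

Gradient correctness is asserted against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "matmul",
    "exp",
    "log",
    "sqrt",
    "power",
    "leaky_relu",
    "sigmoid",
    "softmax",
    "sum_",
    "mean_",
    "concat",
    "gather",
    "segment_sum",
    "segment_softmax",
    "bce_with_logits",
    "dropout",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing over broadcast axes."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.value.shape

    def detach(self) -> "Tensor":
        return Tensor(self.value.copy())

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    # -- backprop --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every upstream tensor."""
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without a seed gradient requires a scalar")
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(value, requires_grad: bool = False) -> Tensor:
    return Tensor(value, requires_grad=requires_grad)


def _make(value, parents, grads) -> Tensor:
    """Build an op node; ``grads`` maps each parent to a vjp callable."""
    out = Tensor(value, parents=parents)
    if out.requires_grad:
        def backward(g):
            for p, vjp in zip(parents, grads):
                if p.requires_grad:
                    p._accumulate(vjp(g))
        out._backward = backward
    return out


# -- arithmetic ----------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(a.value + b.value, (a, b),
                 (lambda g: _unbroadcast(g, a.shape),
                  lambda g: _unbroadcast(g, b.shape)))


def sub(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(a.value - b.value, (a, b),
                 (lambda g: _unbroadcast(g, a.shape),
                  lambda g: _unbroadcast(-g, b.shape)))


def neg(a: Tensor) -> Tensor:
    return _make(-a.value, (a,), (lambda g: -g,))


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(a.value * b.value, (a, b),
                 (lambda g: _unbroadcast(g * b.value, a.shape),
                  lambda g: _unbroadcast(g * a.value, b.shape)))


def div(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(a.value / b.value, (a, b),
                 (lambda g: _unbroadcast(g / b.value, a.shape),
                  lambda g: _unbroadcast(-g * a.value / b.value ** 2, b.shape)))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(a.value @ b.value, (a, b),
                 (lambda g: g @ b.value.T,
                  lambda g: a.value.T @ g))


def power(a: Tensor, p: float) -> Tensor:
    return _make(a.value ** p, (a,), (lambda g: g * p * a.value ** (p - 1),))


def exp(a: Tensor) -> Tensor:
    out_val = np.exp(a.value)
    return _make(out_val, (a,), (lambda g: g * out_val,))


def log(a: Tensor) -> Tensor:
    return _make(np.log(a.value), (a,), (lambda g: g / a.value,))


def sqrt(a: Tensor) -> Tensor:
    out_val = np.sqrt(a.value)
    return _make(out_val, (a,), (lambda g: g * 0.5 / out_val,))


# -- activations ---------------------------------------------------------

def leaky_relu(a: Tensor, slope: float = 0.01) -> Tensor:
    mask = np.where(a.value >= 0.0, 1.0, slope)
    return _make(a.value * mask, (a,), (lambda g: g * mask,))


def sigmoid(a: Tensor) -> Tensor:
    out_val = 0.5 * (1.0 + np.tanh(0.5 * a.value))  # stable sigmoid
    return _make(out_val, (a,), (lambda g: g * out_val * (1.0 - out_val),))


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    """Softmax along ``axis`` (max-shifted; the shift is treated as constant)."""
    shifted = a.value - a.value.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_val = e / e.sum(axis=axis, keepdims=True)

    def vjp(g):
        dot = (g * out_val).sum(axis=axis, keepdims=True)
        return out_val * (g - dot)

    return _make(out_val, (a,), (vjp,))


# -- reductions / shape --------------------------------------------------

def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_val = a.value.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return np.broadcast_to(g, a.shape).copy()
        gg = g if keepdims else np.expand_dims(g, axis)
        return np.broadcast_to(gg, a.shape).copy()

    return _make(out_val, (a,), (vjp,))


def mean_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.value.size if axis is None else a.value.shape[axis]
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_val = np.concatenate([t.value for t in tensors], axis=axis)
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offsets[i], offsets[i + 1])
            return g[tuple(sl)]
        return vjp

    return _make(out_val, tuple(tensors), tuple(make_vjp(i) for i in range(len(tensors))))


# -- graph primitives ----------------------------------------------------

def gather(a: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows ``a[idx]`` (axis 0); duplicates allowed."""
    idx = np.asarray(idx)

    def vjp(g):
        out = np.zeros_like(a.value)
        np.add.at(out, idx, g)
        return out

    return _make(a.value[idx], (a,), (vjp,))


def segment_sum(a: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``a`` into ``num_segments`` buckets given by ``segment_ids``."""
    segment_ids = np.asarray(segment_ids)
    out_val = np.zeros((num_segments,) + a.value.shape[1:], dtype=np.float64)
    np.add.at(out_val, segment_ids, a.value)
    return _make(out_val, (a,), (lambda g: g[segment_ids],))


def segment_softmax(scores: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of a 1-D score vector within each segment (per-node attention).

    Scores are shifted by the per-segment max (held constant) for stability.
    """
    ids = np.asarray(segment_ids)
    seg_max = np.full(num_segments, -np.inf)
    np.maximum.at(seg_max, ids, scores.value)
    shifted = sub(scores, Tensor(seg_max[ids]))
    e = exp(shifted)
    denom = segment_sum(e, ids, num_segments)
    return div(e, gather(denom, ids))


# -- losses / regularization ---------------------------------------------

def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits; grad is sigmoid(z) - y."""
    z = logits.value
    y = np.asarray(targets, dtype=np.float64)
    # log(1+e^z) - y z, computed stably
    loss = np.maximum(z, 0.0) - y * z + np.log1p(np.exp(-np.abs(z)))
    n = z.size
    p = 0.5 * (1.0 + np.tanh(0.5 * z))

    def vjp(g):
        return g * (p - y) / n

    return _make(loss.mean(), (logits,), (vjp,))


def dropout(a: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when ``rng`` is None (eval mode) or rate 0."""
    if rng is None or rate == 0.0:
        return a
    keep = (rng.random(a.shape) >= rate).astype(np.float64) / (1.0 - rate)
    return mul(a, Tensor(keep))
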
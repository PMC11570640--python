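"""Minimal reverse-mode automatic differentiation over numpy arrays.

The trainable network in this package (neighbor-aggregation reduction,
stacked graph-convolution units with learned sparse structure, attention
fusion and a linear classifier head) needs gradients through a modest set
of dense/batched operations.  This module provides exactly that set: a
:class:`Tensor` wrapping an ``ndarray`` plus a tape of primitive ops, each
with a hand-written vector-Jacobian product.  Gradients are checked against
central finite differences in the test suite.

Only what the model uses is implemented; this is not a general framework.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "tensor",
    "data_of",
    "relu",
    "sigmoid",
    "tanh",
    "exp",
    "log",
    "concat",
    "gather",
    "sparse_left_matmul",
    "softmax",
    "sparsemax_rows",
    "softmax_cross_entropy",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative topological sort (graphs can be deep: units x ops)
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            pending = [p for p in node._parents if id(p) not in seen]
            if pending:
                stack.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g: np.ndarray):
        g = _unbroadcast(np.asarray(g), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add,
                       lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract,
                       lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return _binary(_wrap(other), self, np.subtract,
                       lambda g, a, b: g, lambda g, a, b: -g)

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, np.divide,
                       lambda g, a, b: g / b,
                       lambda g, a, b: -g * a / (b * b))

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, exponent: float):
        e = float(exponent)
        out = _make(np.power(self.data, e), (self,))
        if out.requires_grad:
            a = self.data

            def _bwd(g, self=self, a=a, e=e):
                self._accumulate(g * e * np.power(a, e - 1.0))

            out._backward = _bwd
        return out

    def __matmul__(self, other):
        other = _wrap(other)
        out = _make(self.data @ other.data, (self, other))
        if out.requires_grad:
            a, b = self.data, other.data

            def _bwd(g, sa=self, sb=other, a=a, b=b):
                if sa.requires_grad:
                    if b.ndim == 1:
                        ga = g[..., None] * b          # (..., n) x (d,) case
                    else:
                        ga = g @ np.swapaxes(b, -1, -2)
                    sa._accumulate(ga)
                if sb.requires_grad:
                    if b.ndim == 1:
                        gb = (a * g[..., None]).reshape(-1, b.shape[0]).sum(0)
                    elif a.ndim == 1:
                        gb = np.outer(a, g)
                    else:
                        gb = np.swapaxes(a, -1, -2) @ g
                    sb._accumulate(gb)

            out._backward = _bwd
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            shape = self.data.shape

            def _bwd(g, self=self, axis=axis, keepdims=keepdims, shape=shape):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, shape))

            out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims=False):
        """Maximum along one axis; gradient flows to the argmax entries
        (first occurrence on ties, matching ``np.argmax``)."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis),
                                      axis=axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)
        out = _make(out_data, (self,))
        if out.requires_grad:

            def _bwd(g, self=self, idx=idx, axis=axis, keepdims=keepdims):
                if not keepdims:
                    g = np.expand_dims(g, axis)
                full = np.zeros_like(self.data)
                np.put_along_axis(full, np.expand_dims(idx, axis), g, axis=axis)
                self._accumulate(full)

            out._backward = _bwd
        return out

    def reshape(self, *shape):
        out = _make(self.data.reshape(*shape), (self,))
        if out.requires_grad:
            orig = self.data.shape

            def _bwd(g, self=self, orig=orig):
                self._accumulate(g.reshape(orig))

            out._backward = _bwd
        return out

    def __getitem__(self, key):
        """Basic (slice/int) indexing with gradient scatter back."""
        out = _make(self.data[key], (self,))
        if out.requires_grad:

            def _bwd(g, self=self, key=key):
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)

            out._backward = _bwd
        return out

    def swapaxes(self, a: int, b: int):
        out = _make(np.swapaxes(self.data, a, b), (self,))
        if out.requires_grad:

            def _bwd(g, self=self, a=a, b=b):
                self._accumulate(np.swapaxes(g, a, b))

            out._backward = _bwd
        return out


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    return out


def _binary(a, b, fwd, vjp_a, vjp_b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = _make(fwd(a.data, b.data), (a, b))
    if out.requires_grad:
        da, db = a.data, b.data

        def _bwd(g, a=a, b=b, da=da, db=db):
            if a.requires_grad:
                a._accumulate(vjp_a(g, da, db))
            if b.requires_grad:
                b._accumulate(vjp_b(g, da, db))

        out._backward = _bwd
    return out


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(np.asarray(data), requires_grad=requires_grad)


def data_of(x) -> np.ndarray:
    """The plain ndarray behind ``x`` (Tensor or array-like)."""
    return x.data if isinstance(x, Tensor) else np.asarray(x)


# -- elementwise nonlinearities -------------------------------------------

def relu(x):
    if not isinstance(x, Tensor):
        return np.maximum(x, 0.0)
    out = _make(np.maximum(x.data, 0.0), (x,))
    if out.requires_grad:
        mask = x.data > 0

        def _bwd(g, x=x, mask=mask):
            x._accumulate(g * mask)

        out._backward = _bwd
    return out


def sigmoid(x):
    if not isinstance(x, Tensor):
        x = np.asarray(x, dtype=float)
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        return out
    s = sigmoid(x.data)
    out = _make(s, (x,))
    if out.requires_grad:

        def _bwd(g, x=x, s=s):
            x._accumulate(g * s * (1.0 - s))

        out._backward = _bwd
    return out


def tanh(x):
    if not isinstance(x, Tensor):
        return np.tanh(x)
    t = np.tanh(x.data)
    out = _make(t, (x,))
    if out.requires_grad:

        def _bwd(g, x=x, t=t):
            x._accumulate(g * (1.0 - t * t))

        out._backward = _bwd
    return out


def exp(x):
    if not isinstance(x, Tensor):
        return np.exp(x)
    e = np.exp(x.data)
    out = _make(e, (x,))
    if out.requires_grad:

        def _bwd(g, x=x, e=e):
            x._accumulate(g * e)

        out._backward = _bwd
    return out


def log(x):
    if not isinstance(x, Tensor):
        return np.log(x)
    out = _make(np.log(x.data), (x,))
    if out.requires_grad:

        def _bwd(g, x=x):
            x._accumulate(g / x.data)

        out._backward = _bwd
    return out


# -- structural ops --------------------------------------------------------

def concat(tensors, axis: int = -1):
    tensors = [_wrap(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis),
                tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def _bwd(g, tensors=tensors, splits=splits, axis=axis):
            for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(gpart)

        out._backward = _bwd
    return out


def gather(x, idx: np.ndarray, axis: int):
    """``np.take_along_axis`` with gradient scatter-add back into ``x``.

    ``idx`` is a fixed integer array broadcastable per take_along_axis rules.
    """
    if not isinstance(x, Tensor):
        return np.take_along_axis(x, idx, axis=axis)
    idx = np.asarray(idx)
    out = _make(np.take_along_axis(x.data, idx, axis=axis), (x,))
    if out.requires_grad:

        def _bwd(g, x=x, idx=idx, axis=axis):
            full = np.zeros_like(x.data)
            # scatter-add: indices may repeat only if caller repeats them
            np.add.at(full, _expand_index(idx, x.data.shape, axis, g.shape), g)
            x._accumulate(full)

        out._backward = _bwd
    return out


def _expand_index(idx, shape, axis, gshape):
    """Build an advanced-index tuple equivalent to take_along_axis."""
    axis = axis % len(shape)
    idx = np.broadcast_to(idx, gshape)
    grids = np.ogrid[tuple(slice(n) for n in gshape)]
    grids = list(grids)
    grids[axis] = idx
    return tuple(grids)


def sparse_left_matmul(m: sp.spmatrix, x):
    """Compute ``M @ x`` for a fixed sparse (n, n) matrix and ``x`` of shape
    (..., n, d); used for the shared-adjacency convolution at unit 1."""
    m = sp.csr_matrix(m)

    def apply(mat: sp.spmatrix, arr: np.ndarray) -> np.ndarray:
        if arr.ndim == 2:
            return np.asarray(mat @ arr)
        lead = arr.shape[:-2]
        n, d = arr.shape[-2:]
        flat = np.moveaxis(arr.reshape(-1, n, d), 0, 1).reshape(n, -1)
        res = np.asarray(mat @ flat)
        res = np.moveaxis(res.reshape(n, -1, d), 1, 0).reshape(*lead, n, d)
        return res

    if not isinstance(x, Tensor):
        return apply(m, x)
    out = _make(apply(m, x.data), (x,))
    if out.requires_grad:
        mt = sp.csr_matrix(m.T)

        def _bwd(g, x=x, mt=mt):
            x._accumulate(apply(mt, g))

        out._backward = _bwd
    return out


def softmax(x, axis: int = -1):
    if not isinstance(x, Tensor):
        z = x - np.max(x, axis=axis, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=axis, keepdims=True)
    s = softmax(x.data, axis=axis)
    out = _make(s, (x,))
    if out.requires_grad:

        def _bwd(g, x=x, s=s, axis=axis):
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accumulate(s * (g - dot))

        out._backward = _bwd
    return out


def _sparsemax_nd(z: np.ndarray) -> np.ndarray:
    """Euclidean projection of the last axis of ``z`` onto the simplex."""
    z = np.asarray(z, dtype=float)
    n = z.shape[-1]
    srt = -np.sort(-z, axis=-1)
    csum = np.cumsum(srt, axis=-1)
    ks = np.arange(1, n + 1, dtype=float)
    support = 1.0 + ks * srt > csum
    k = support.sum(axis=-1, keepdims=True)  # size of the support, >= 1
    tau = (np.take_along_axis(csum, k - 1, axis=-1) - 1.0) / k
    return np.maximum(z - tau, 0.0)


def sparsemax_rows(x):
    """Row-wise sparsemax (projection onto the probability simplex) along the
    last axis.  VJP: on the support S, ``dz = g - mean_S(g)``; zero off it."""
    if not isinstance(x, Tensor):
        return _sparsemax_nd(x)
    p = _sparsemax_nd(x.data)
    out = _make(p, (x,))
    if out.requires_grad:
        support = p > 0

        def _bwd(g, x=x, support=support):
            masked = np.where(support, g, 0.0)
            k = support.sum(axis=-1, keepdims=True)
            mean = masked.sum(axis=-1, keepdims=True) / k
            x._accumulate(np.where(support, g - mean, 0.0))

        out._backward = _bwd
    return out


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray,
                          sample_weight: np.ndarray | None = None) -> Tensor:
    """Mean cross-entropy of softmax(logits) against one-hot targets.

    Fused op: numerically stable forward, closed-form gradient
    ``(softmax - onehot) / B``.
    """
    onehot = np.asarray(onehot, dtype=float)
    z = logits.data
    zmax = z.max(axis=-1, keepdims=True)
    lse = zmax + np.log(np.exp(z - zmax).sum(axis=-1, keepdims=True))
    logp = z - lse
    per_sample = -(onehot * logp).sum(axis=-1)
    if sample_weight is None:
        w = np.full(per_sample.shape, 1.0 / per_sample.size)
    else:
        w = np.asarray(sample_weight, dtype=float)
        w = w / w.sum()
    out = _make(np.asarray((per_sample * w).sum()), (logits,))
    if out.requires_grad:
        probs = np.exp(logp)

        def _bwd(g, logits=logits, probs=probs, onehot=onehot, w=w):
            logits._accumulate(g * (probs - onehot) * w[..., None])

        out._backward = _bwd
    return out
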
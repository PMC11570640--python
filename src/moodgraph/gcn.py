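"""Hierarchical graph-convolution core: conv, info-score top-k pooling,
sparsemax structure learning, and mean||max readout.

One *unit* applies, in order,

1. a normalized graph convolution
   ``H' = sigma(D^{-1/2} (A + I) D^{-1/2} H W)`` (self-loops added inside
   the convolution so every degree is positive);
2. information-score pooling: each node is scored by how much it differs
   from the mean of its neighbors, ``score(v) = ||row_v((I - D^{-1}A) H)||``,
   and the top ``ceil(pool_ratio * n)`` nodes are kept (features row-sliced,
   adjacency row/column-sliced);
3. structure learning: pairwise scores
   ``E(p,q) = sigma(a [H_p || H_q]^T) + lambda A(p,q)`` are pushed row-wise
   through sparsemax, producing a sparse row-stochastic connectivity S that
   replaces A for the next unit.

Each unit contributes a mean||max readout; stacking K units and summing the
K readouts yields the graph-level embedding f_g of length 2d.  With K = 0
the embedding is simply the readout of the input state.

These are the reference (single-graph, float64 numpy) implementations; the
trainable estimator mirrors them in batched autodiff form and is tested for
equivalence against this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import _sparsemax_nd, sigmoid as _sigmoid

__all__ = [
    "UnitParams",
    "gcn_forward",
    "info_score",
    "top_k_select",
    "pool",
    "sparsemax",
    "structure_learning",
    "readout",
    "multi_gcn_forward",
]


@dataclass(frozen=True)
class UnitParams:
    """Parameters of one conv + pool + structure-learning unit."""

    conv_weight: np.ndarray          # (d_in, d_out)
    attention_vector: np.ndarray     # (2 * d_out,)
    lam: float = 1.0                 # balance between attention and A
    pool_ratio: float = 0.5

    def __post_init__(self):
        w = np.asarray(self.conv_weight, dtype=float)
        a = np.asarray(self.attention_vector, dtype=float).ravel()
        object.__setattr__(self, "conv_weight", w)
        object.__setattr__(self, "attention_vector", a)
        if not 0.0 < self.pool_ratio <= 1.0:
            raise ValueError(f"pool_ratio must be in (0, 1], got {self.pool_ratio}")
        if self.lam < 0:
            raise ValueError(f"lambda must be non-negative, got {self.lam}")
        if a.size != 2 * w.shape[1]:
            raise ValueError(
                f"attention vector length {a.size} must be 2 x conv output "
                f"dim {w.shape[1]}")


_ACTIVATIONS = {
    "relu": lambda x: np.maximum(x, 0.0),
    "sigmoid": _sigmoid,
    "tanh": np.tanh,
    "identity": lambda x: x,
}


def _check_state(h: np.ndarray, a: np.ndarray):
    h = np.asarray(h, dtype=float)
    a = np.asarray(a, dtype=float)
    if h.ndim != 2:
        raise ValueError(f"feature matrix must be 2-D, got shape {h.shape}")
    if a.shape != (h.shape[0], h.shape[0]):
        raise ValueError(
            f"adjacency shape {a.shape} incompatible with {h.shape[0]} nodes")
    if not (np.all(np.isfinite(h)) and np.all(np.isfinite(a))):
        raise ValueError("graph state contains non-finite values")
    return h, a


def gcn_forward(h: np.ndarray, a: np.ndarray, w: np.ndarray,
                activation: str = "relu") -> np.ndarray:
    """Normalized graph convolution with internal self-loops.

    ``H' = sigma(D^{-1/2} (A + I) D^{-1/2} H W)`` where D holds the row
    degrees of A + I (always positive, so isolated nodes are well-defined).
    For the real-valued, possibly asymmetric connectivities produced by
    structure learning, D uses row sums.
    """
    h, a = _check_state(h, a)
    w = np.asarray(w, dtype=float)
    a_hat = a + np.eye(a.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_hat.sum(axis=1))
    norm = a_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    return _ACTIVATIONS[activation](norm @ h @ w)


def info_score(h: np.ndarray, a: np.ndarray, norm: str = "l1") -> np.ndarray:
    """Per-node information score ``||row_v((I - D^{-1} A) H)||``.

    The score measures how much a node's features deviate from the mean of
    its neighbors; nodes that merely repeat their neighborhood carry little
    extra information and are pooled away.  D uses the degrees of the
    current A *without* self-loops; an isolated node's ``D^{-1}A`` row is
    zero, so its score is simply the norm of its own feature row.
    """
    h, a = _check_state(h, a)
    deg = a.sum(axis=1)
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    diff = h - (a * inv[:, None]) @ h
    if norm == "l1":
        return np.abs(diff).sum(axis=1)
    if norm == "l2":
        return np.sqrt((diff ** 2).sum(axis=1))
    raise ValueError(f"unknown norm {norm!r}")


def top_k_select(scores: np.ndarray, pool_ratio: float) -> np.ndarray:
    """Indices of the ``ceil(pool_ratio * n)`` highest scores.

    Ties are broken by lower node index; the result is sorted ascending so
    the pooled subgraph preserves relative node order.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if not 0.0 < pool_ratio <= 1.0:
        raise ValueError(f"pool_ratio must be in (0, 1], got {pool_ratio}")
    k = max(1, math.ceil(pool_ratio * scores.size))
    order = np.argsort(-scores, kind="stable")[:k]
    return np.sort(order)


def pool(h: np.ndarray, a: np.ndarray, idx: np.ndarray
         ) -> tuple[np.ndarray, np.ndarray]:
    """Row-slice features and row/column-slice adjacency to ``idx``."""
    h, a = _check_state(h, a)
    idx = np.asarray(idx, dtype=int)
    if idx.size == 0:
        raise ValueError("cannot pool to an empty node set")
    if len(np.unique(idx)) != idx.size:
        raise ValueError("pooling indices must be unique")
    if idx.min() < 0 or idx.max() >= h.shape[0]:
        raise IndexError(f"pooling index out of range for n={h.shape[0]}")
    return h[idx, :], a[np.ix_(idx, idx)]


def sparsemax(z: np.ndarray) -> np.ndarray:
    """Euclidean projection of ``z`` onto the probability simplex.

    Sort descending, find the largest support size k with
    ``1 + k z_(k) > sum_{j<=k} z_(j)``, set
    ``tau = (sum_{j<=k} z_(j) - 1) / k`` and return ``max(z - tau, 0)``.
    The output sums to 1 and puts exact zeros on low scores, unlike softmax.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.size == 0:
        raise ValueError("sparsemax expects a non-empty 1-D vector")
    if not np.all(np.isfinite(z)):
        raise ValueError("sparsemax input must be finite")
    return _sparsemax_nd(z)


def structure_learning(h: np.ndarray, a: np.ndarray,
                       attention_vector: np.ndarray, lam: float = 1.0,
                       activation: str = "sigmoid") -> np.ndarray:
    """Learn a sparse row-stochastic connectivity among the pooled nodes.

    ``E(p,q) = sigma(a [H_p || H_q]^T) + lambda A(p,q)`` scored for every
    ordered pair, then each row of E is projected by sparsemax.  The result
    S is row-stochastic (each row a sparse distribution) and generally
    asymmetric; it replaces A for the next unit's message passing, repairing
    disconnections introduced by pooling.
    """
    h, a = _check_state(h, a)
    v = np.asarray(attention_vector, dtype=float).ravel()
    d = h.shape[1]
    if v.size != 2 * d:
        raise ValueError(
            f"attention vector length {v.size} must equal 2 x feature dim {d}")
    act = _ACTIVATIONS[activation]
    left = h @ v[:d]     # contribution of H(p,:)
    right = h @ v[d:]    # contribution of H(q,:)
    e = act(left[:, None] + right[None, :]) + lam * a
    return _sparsemax_nd(e)


def readout(h: np.ndarray) -> np.ndarray:
    """Fixed-size graph vector: column means || column maxima."""
    h = np.asarray(h, dtype=float)
    if h.ndim != 2 or h.shape[0] == 0:
        raise ValueError("readout requires a non-empty 2-D feature matrix")
    return np.concatenate([h.mean(axis=0), h.max(axis=0)])


def multi_gcn_forward(x0: np.ndarray, a0: np.ndarray,
                      units: list[UnitParams],
                      conv_activation: str = "relu",
                      attention_activation: str = "sigmoid",
                      score_norm: str = "l1",
                      return_trace: bool = False):
    """Run K = len(units) conv/pool/structure-learning units and sum the
    per-unit mean||max readouts into the graph embedding f_g.

    With an empty unit list the embedding is the readout of the input state
    (the depth-0 ablation convention).
    """
    h, a = _check_state(x0, a0)
    if not units:
        f_g = readout(h)
        return (f_g, []) if return_trace else f_g
    trace = []
    f_g = None
    for params in units:
        h = gcn_forward(h, a, params.conv_weight, activation=conv_activation)
        scores = info_score(h, a, norm=score_norm)
        idx = top_k_select(scores, params.pool_ratio)
        h, a_pooled = pool(h, a, idx)
        a = structure_learning(h, a_pooled, params.attention_vector,
                               lam=params.lam, activation=attention_activation)
        r = readout(h)
        f_g = r if f_g is None else f_g + r
        if return_trace:
            trace.append({"idx": idx, "h": h, "a": a, "readout": r})
    return (f_g, trace) if return_trace else f_g
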
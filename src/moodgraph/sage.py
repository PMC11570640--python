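"""Neighbor-mean feature reduction for high-dimensional EEG channels.

Each channel's raw feature vector is concatenated with the arithmetic mean
of its graph neighbors' vectors and passed through one linear + ReLU layer:

    h'_v = ReLU(W (e_v || mean_{u in N(v)} e_u) + b)

a single-hop aggregation that maps channel features of any dimension m to
the configured reduced width while keeping all channels as graph nodes.
Isolated nodes use a zero vector as their neighbor mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ReductionParams", "neighbor_mean", "sage_reduce", "init_reduction_params"]


@dataclass(frozen=True)
class ReductionParams:
    """Linear-layer parameters of the reduction: weight (2m, m_out), bias (m_out,)."""

    weight: np.ndarray
    bias: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weight, dtype=float)
        b = np.asarray(self.bias, dtype=float)
        object.__setattr__(self, "weight", w)
        object.__setattr__(self, "bias", b)
        if w.ndim != 2 or b.ndim != 1 or w.shape[1] != b.shape[0]:
            raise ValueError(
                f"inconsistent reduction params: weight {w.shape}, bias {b.shape}")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
            raise ValueError("reduction params must be finite")


def neighbor_mean(x: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Per-node arithmetic mean of neighbor feature rows.

    Row v of the result is ``mean(x[u] for u in N(v))``; nodes without
    neighbors get a zero row.
    """
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    if x.ndim != 2 or a.shape != (x.shape[0], x.shape[0]):
        raise ValueError(
            f"shape mismatch: features {x.shape} vs adjacency {a.shape}")
    deg = a.sum(axis=1, keepdims=True)
    agg = a @ x
    return np.divide(agg, deg, out=np.zeros_like(agg), where=deg > 0)


def sage_reduce(x: np.ndarray, a: np.ndarray, params: ReductionParams) -> np.ndarray:
    """ReLU(W (x_v || neighbor_mean_v) + b) for every node v."""
    x = np.asarray(x, dtype=float)
    h = np.concatenate([x, neighbor_mean(x, a)], axis=1)
    if params.weight.shape[0] != h.shape[1]:
        raise ValueError(
            f"reduction weight expects input dim {params.weight.shape[0]}, "
            f"got concatenated dim {h.shape[1]} (2 x {x.shape[1]})")
    return np.maximum(h @ params.weight + params.bias, 0.0)


def init_reduction_params(m_in: int, m_out: int,
                          rng: np.random.Generator) -> ReductionParams:
    """Glorot-uniform initialization for a (2*m_in -> m_out) reduction."""
    fan_in = 2 * m_in
    limit = np.sqrt(6.0 / (fan_in + m_out))
    return ReductionParams(
        weight=rng.uniform(-limit, limit, size=(fan_in, m_out)),
        bias=np.zeros(m_out),
    )
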
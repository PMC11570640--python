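"""Batched differentiable forward pass of the full multimodal network.

This mirrors the reference single-graph operations in :mod:`moodgraph.gcn`,
:mod:`moodgraph.sage` and :mod:`moodgraph.fusion`, but runs whole
minibatches as stacked (B, n, d) tensors on the autodiff engine so training
is fast on one CPU.  Equivalence with the reference path is asserted in the
test suite.

Node selection for pooling is discrete, so information scores are computed
outside the tape (no gradient flows through the scores, only through the
selected rows), matching the slicing semantics of the pooling step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["ModalityStream", "NetworkParams", "init_params", "forward", "Adam"]


@dataclass
class ModalityStream:
    """Trainable tensors of one modality stream."""

    sage_w: Tensor | None          # (2m, sage_dim) or None (audio: X used directly)
    sage_b: Tensor | None
    att_w: Tensor                  # (m0, att_dim)
    att_b: Tensor                  # (att_dim,)
    att_v: Tensor                  # (att_dim,)
    conv_weights: list             # K tensors (d_in, d_out)
    attn_vectors: list             # K tensors (2 d_out,)
    gate: Tensor                   # (m0 + 2d  [or 3 m0 when K = 0],)

    def tensors(self) -> list[Tensor]:
        out = [self.att_w, self.att_b, self.att_v, self.gate]
        if self.sage_w is not None:
            out += [self.sage_w, self.sage_b]
        out += list(self.conv_weights) + list(self.attn_vectors)
        return out


@dataclass
class NetworkParams:
    eeg: ModalityStream
    audio: ModalityStream
    out_w: Tensor                  # (fused_dim, 2)
    out_b: Tensor                  # (2,)
    lam: float = 1.0
    pool_ratio: float = 0.5

    def tensors(self) -> list[Tensor]:
        return self.eeg.tensors() + self.audio.tensors() + [self.out_w, self.out_b]


def _glorot(rng, shape):
    limit = math.sqrt(6.0 / (shape[0] + shape[-1]))
    return rng.uniform(-limit, limit, size=shape)


def _embed_dim(m0: int, hidden: int, n_units: int) -> int:
    return m0 + (2 * hidden if n_units > 0 else 2 * m0)


def _init_stream(rng, m_raw: int, n_units: int, hidden: int,
                 sage_dim: int | None, att_dim: int, dtype) -> ModalityStream:
    if sage_dim is not None:
        sage_w = Tensor(_glorot(rng, (2 * m_raw, sage_dim)).astype(dtype), True)
        sage_b = Tensor(np.zeros(sage_dim, dtype=dtype), True)
        m0 = sage_dim
    else:
        sage_w = sage_b = None
        m0 = m_raw
    convs, attns = [], []
    d_in = m0
    for _ in range(n_units):
        convs.append(Tensor(_glorot(rng, (d_in, hidden)).astype(dtype), True))
        attns.append(Tensor((0.1 * rng.standard_normal(2 * hidden)).astype(dtype), True))
        d_in = hidden
    return ModalityStream(
        sage_w=sage_w, sage_b=sage_b,
        att_w=Tensor(_glorot(rng, (m0, att_dim)).astype(dtype), True),
        att_b=Tensor(np.zeros(att_dim, dtype=dtype), True),
        att_v=Tensor((0.1 * rng.standard_normal(att_dim)).astype(dtype), True),
        conv_weights=convs, attn_vectors=attns,
        gate=Tensor(np.zeros(_embed_dim(m0, hidden, n_units), dtype=dtype), True),
    )


def init_params(rng: np.random.Generator, *, m_eeg: int, m_audio: int,
                n_units_eeg: int, n_units_audio: int, hidden: int,
                sage_dim: int, att_dim: int, lam: float, pool_ratio: float,
                dtype=np.float32) -> NetworkParams:
    eeg = _init_stream(rng, m_eeg, n_units_eeg, hidden, sage_dim, att_dim, dtype)
    audio = _init_stream(rng, m_audio, n_units_audio, hidden, None, att_dim, dtype)
    fused = (_embed_dim(sage_dim, hidden, n_units_eeg)
             + _embed_dim(m_audio, hidden, n_units_audio))
    return NetworkParams(
        eeg=eeg, audio=audio,
        out_w=Tensor(_glorot(rng, (fused, 2)).astype(dtype), True),
        out_b=Tensor(np.zeros(2, dtype=dtype), True),
        lam=lam, pool_ratio=pool_ratio,
    )


# -- fixed preprocessing ---------------------------------------------------

def normalized_adjacency(a: np.ndarray) -> sp.csr_matrix:
    """D^{-1/2} (A + I) D^{-1/2} as a sparse matrix (shared across samples)."""
    a_hat = np.asarray(a, dtype=float) + np.eye(a.shape[0])
    d = 1.0 / np.sqrt(a_hat.sum(axis=1))
    return sp.csr_matrix(a_hat * d[:, None] * d[None, :])


def neighbor_mean_operator(a: np.ndarray) -> np.ndarray:
    """Row-normalized adjacency D^{-1} A (zero rows for isolated nodes)."""
    a = np.asarray(a, dtype=float)
    deg = a.sum(axis=1, keepdims=True)
    return np.divide(a, deg, out=np.zeros_like(a), where=deg > 0)


# -- batched unit operations ----------------------------------------------

def _batched_scores(h: np.ndarray, a: np.ndarray) -> np.ndarray:
    """L1 information scores per node for (B, n, d) features.

    ``a`` is either a shared (n, n) matrix or per-sample (B, n, n).
    """
    deg = a.sum(axis=-1, keepdims=True)
    p = np.divide(a, deg, out=np.zeros_like(a, dtype=float), where=deg > 0)
    diff = h - p @ h
    return np.abs(diff).sum(axis=-1)


def _batched_topk(scores: np.ndarray, pool_ratio: float) -> np.ndarray:
    """(B, k) kept indices, ties to lower index, ascending order."""
    n = scores.shape[-1]
    k = max(1, math.ceil(pool_ratio * n))
    order = np.argsort(-scores, axis=-1, kind="stable")[..., :k]
    return np.sort(order, axis=-1)


def _conv(h, a_tensor, w):
    """Batched normalized convolution for per-sample connectivity."""
    n = ad.data_of(h).shape[-2]
    a_hat = a_tensor + np.eye(n, dtype=ad.data_of(h).dtype)
    deg = a_hat.sum(axis=-1)
    d_inv = deg ** -0.5
    b = ad.data_of(d_inv).shape[0]
    norm = a_hat * d_inv.reshape(b, n, 1) * d_inv.reshape(b, 1, n)
    return ad.relu(norm @ h @ w)


def _structure_learning(h, a_const_or_tensor, attn_vec, lam):
    b, k, d = ad.data_of(h).shape
    left = h @ attn_vec[:d]
    right = h @ attn_vec[d:]
    return ad.sparsemax_rows(
        ad.sigmoid(left.reshape(b, k, 1) + right.reshape(b, 1, k))
        + lam * a_const_or_tensor)


def _readout(h):
    return ad.concat([h.mean(axis=1), h.max(axis=1)], axis=-1)


def _stream_forward(x_raw: np.ndarray, stream: ModalityStream,
                    adjacency: np.ndarray, lam: float, pool_ratio: float,
                    collect: dict | None = None):
    """Run one modality: reduction -> node attention -> K units -> f_emb."""
    dtype = stream.att_w.data.dtype
    if stream.sage_w is not None:
        nm = neighbor_mean_operator(adjacency).astype(dtype)
        x_cat = np.concatenate([x_raw, nm @ x_raw], axis=-1).astype(dtype)
        x0 = ad.relu(Tensor(x_cat) @ stream.sage_w + stream.sage_b)
    else:
        x0 = Tensor(x_raw.astype(dtype))

    b, n, m0 = ad.data_of(x0).shape
    logits = ad.tanh(x0 @ stream.att_w + stream.att_b) @ stream.att_v
    alpha = ad.softmax(logits, axis=-1)                       # (B, n)
    f_b = (alpha.reshape(b, n, 1) * x0).sum(axis=1)           # (B, m0)
    if collect is not None:
        collect["alpha"] = ad.data_of(alpha)

    if not stream.conv_weights:
        f_g = _readout(x0)
    else:
        norm_shared = normalized_adjacency(adjacency).astype(dtype)
        h = x0
        a_np: np.ndarray = np.asarray(adjacency, dtype=dtype)  # shared at unit 1
        a_tensor = None
        f_g = None
        for i, (w, attn) in enumerate(zip(stream.conv_weights,
                                          stream.attn_vectors)):
            if i == 0:
                h = ad.relu(ad.sparse_left_matmul(norm_shared, h) @ w)
                scores = _batched_scores(ad.data_of(h), a_np)
            else:
                h = _conv(h, a_tensor, w)
                scores = _batched_scores(ad.data_of(h), ad.data_of(a_tensor))
            idx = _batched_topk(scores, pool_ratio)           # (B, k)
            h = ad.gather(h, idx[:, :, None], axis=1)
            if i == 0:
                a_pooled = a_np[idx[:, :, None], idx[:, None, :]]
            else:
                a_rows = ad.gather(a_tensor, idx[:, :, None], axis=1)
                a_pooled = ad.gather(a_rows, idx[:, None, :], axis=2)
            a_tensor = _structure_learning(h, a_pooled, attn, lam)
            r = _readout(h)
            f_g = r if f_g is None else f_g + r
    f_emb = ad.concat([f_b, f_g], axis=-1)
    return f_emb * ad.sigmoid(stream.gate)


def forward(params: NetworkParams, eeg: np.ndarray, audio: np.ndarray,
            eeg_adjacency: np.ndarray, audio_adjacency: np.ndarray,
            collect: dict | None = None) -> Tensor:
    """Class logits (B, 2) for a minibatch of paired samples."""
    c_eeg = {} if collect is not None else None
    c_audio = {} if collect is not None else None
    fe = _stream_forward(eeg, params.eeg, eeg_adjacency, params.lam,
                         params.pool_ratio, c_eeg)
    fa = _stream_forward(audio, params.audio, audio_adjacency, params.lam,
                         params.pool_ratio, c_audio)
    fused = ad.concat([fe, fa], axis=-1)
    logits = fused @ params.out_w + params.out_b
    if collect is not None:
        collect["eeg"] = c_eeg
        collect["audio"] = c_audio
    return logits


class Adam:
    """Plain Adam over a list of parameter tensors."""

    def __init__(self, tensors: list[Tensor], lr: float = 3e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.tensors = tensors
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(t.data) for t in tensors]
        self.v = [np.zeros_like(t.data) for t in tensors]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.tensors):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.tensors:
            p.grad = None
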
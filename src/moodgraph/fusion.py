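"""Attention fusion of the two modality streams and the classifier head.

Per modality, a node-level attention over the initial feature matrix X0
produces a context vector ``f_b = sum_i alpha_i X0(i,:)`` with
``alpha = softmax(V tanh(W X0 + b))`` — over EEG channels for the EEG
stream and over audio slices for the audio stream.  The modality embedding
is ``f_embedding = f_b || f_g`` (context vector first).  A feature-level
gate ``Att(f) = f ⊙ sigmoid(w)`` weights each modality's embedding; the two
gated embeddings are concatenated and classified by one affine layer with a
softmax over the two classes (MDD vs HC).

The attention weights double as interpretability outputs: per-channel (and
per-slice) alpha scores, and per-feature-family audio gate values averaged
over each family's column span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import sigmoid as _sigmoid, softmax as _softmax

__all__ = [
    "NodeAttentionParams",
    "node_attention",
    "assemble_embedding",
    "modality_attention",
    "fuse_and_classify",
    "baseline_subtract",
    "export_attention",
]


@dataclass(frozen=True)
class NodeAttentionParams:
    """Eq-style node attention: one logit per node, V . tanh(W x + b)."""

    v: np.ndarray   # (h,)
    w: np.ndarray   # (m, h)
    b: np.ndarray   # (h,)

    def __post_init__(self):
        v = np.asarray(self.v, dtype=float).ravel()
        w = np.asarray(self.w, dtype=float)
        b = np.asarray(self.b, dtype=float).ravel()
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "b", b)
        if w.ndim != 2 or v.size != w.shape[1] or b.size != w.shape[1]:
            raise ValueError(
                f"incompatible attention shapes: V {v.shape}, W {w.shape}, b {b.shape}")


def node_attention(x0: np.ndarray, params: NodeAttentionParams
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Attention distribution over nodes and the context vector f_b.

    Returns ``(alpha, f_b)`` with ``alpha = softmax_i(V . tanh(W x_i + b))``
    (strictly positive, sums to 1) and ``f_b = sum_i alpha_i x_i``.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.ndim != 2 or x0.shape[0] == 0:
        raise ValueError("node attention requires a non-empty 2-D matrix")
    if x0.shape[1] != params.w.shape[0]:
        raise ValueError(
            f"attention W expects feature dim {params.w.shape[0]}, got {x0.shape[1]}")
    logits = np.tanh(x0 @ params.w + params.b) @ params.v
    alpha = _softmax(logits)
    return alpha, alpha @ x0


def assemble_embedding(f_b: np.ndarray, f_g: np.ndarray) -> np.ndarray:
    """Modality embedding ``f_b || f_g`` (context vector first)."""
    f_b = np.asarray(f_b, dtype=float).ravel()
    f_g = np.asarray(f_g, dtype=float).ravel()
    if not (np.all(np.isfinite(f_b)) and np.all(np.isfinite(f_g))):
        raise ValueError("embedding parts must be finite")
    return np.concatenate([f_b, f_g])


def modality_attention(embedding: np.ndarray, gate: np.ndarray) -> np.ndarray:
    """Feature-level gate: ``f ⊙ sigmoid(w)`` (never flips a sign)."""
    embedding = np.asarray(embedding, dtype=float).ravel()
    gate = np.asarray(gate, dtype=float).ravel()
    if embedding.size != gate.size:
        raise ValueError(
            f"gate length {gate.size} must match embedding length {embedding.size}")
    return embedding * _sigmoid(gate)


def fuse_and_classify(eeg_embedding: np.ndarray, audio_embedding: np.ndarray,
                      eeg_gate: np.ndarray, audio_gate: np.ndarray,
                      out_weight: np.ndarray, out_bias: np.ndarray
                      ) -> np.ndarray:
    """Gate each modality, concatenate, apply one affine layer + softmax."""
    fused = np.concatenate([
        modality_attention(eeg_embedding, eeg_gate),
        modality_attention(audio_embedding, audio_gate),
    ])
    if not np.all(np.isfinite(fused)):
        raise ValueError("fused embedding contains non-finite values")
    out_weight = np.asarray(out_weight, dtype=float)
    logits = fused @ out_weight + np.asarray(out_bias, dtype=float)
    return _softmax(logits)


def baseline_subtract(scores: np.ndarray) -> np.ndarray:
    """Shift scores so the smallest becomes the zero baseline."""
    scores = np.asarray(scores, dtype=float)
    return scores - scores.min()


def export_attention(channel_alpha: np.ndarray, channel_labels,
                     family_scores: dict[str, float]):
    """Attention report: per-channel and per-audio-family scores, each also
    baseline-subtracted (minimum taken as the baseline).

    Returns two DataFrames ``(channels, families)`` with columns
    label/score/baseline_subtracted.
    """
    import pandas as pd

    channel_alpha = np.asarray(channel_alpha, dtype=float).ravel()
    if len(channel_labels) != channel_alpha.size:
        raise ValueError("channel label count must match score count")
    channels = pd.DataFrame({
        "channel_label": list(channel_labels),
        "score": channel_alpha,
        "baseline_subtracted": baseline_subtract(channel_alpha),
    })
    fam_names = list(family_scores)
    fam_vals = np.array([family_scores[k] for k in fam_names], dtype=float)
    families = pd.DataFrame({
        "feature_family": fam_names,
        "score": fam_vals,
        "baseline_subtracted": baseline_subtract(fam_vals),
    })
    return channels, families
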
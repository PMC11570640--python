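"""Scikit-learn style estimator for multimodal (EEG + audio) graph
classification.

:class:`MoodGraphClassifier` wires the pipeline together: neighbor-mean
reduction of raw channel features, per-modality node attention, a stack of
graph-convolution units with information-score pooling and sparsemax
structure learning, feature-level modality gates and a linear softmax head,
trained end-to-end with Adam on cross-entropy.

Input convention: ``X`` is a dict (or mapping) with

* ``eeg``   — float array (N, n_channels, m_eeg) of per-channel features,
* ``audio`` — float array (N, n_slices, m_audio) of per-slice features,

and optionally ``eeg_adjacency`` / ``audio_adjacency``.  The audio adjacency
defaults to the temporal chain; the EEG adjacency must be supplied either in
``X`` or via the constructor (it encodes the montage, which the estimator
cannot guess).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import network as net
from .autodiff import sigmoid as _np_sigmoid, softmax_cross_entropy
from .graphs import build_chain_adjacency

__all__ = ["MoodGraphClassifier"]


class MoodGraphClassifier(ClassifierMixin, BaseEstimator):
    """Binary graph classifier over paired EEG/audio samples.

    Parameters
    ----------
    n_units_eeg, n_units_audio : int
        Stack depth K per modality (0 = read out the initial features).
    hidden_dim : int
        Width d of the convolution units; the graph embedding has length 2d.
    sage_dim : int
        Output width of the EEG neighbor-mean reduction (the audio feature
        rows are used directly as node features).
    attention_dim : int
        Hidden width of the node-attention scorer.
    pool_ratio : float
        Fraction of nodes kept by each pooling step (ceil, at least 1).
    lam : float
        Balance between learned pairwise attention and the existing
        connectivity inside structure learning.
    lr, n_epochs, batch_size, tol, patience : optimizer settings; training
        stops early when the epoch loss stops improving by more than ``tol``
        for ``patience`` epochs (or immediately at zero training error with
        near-zero loss).
    eeg_adjacency, audio_adjacency : array or None
        Default connectivities used when ``X`` does not carry them.
    random_state : int
        Seed for parameter initialization and minibatch shuffling.

    Attributes
    ----------
    classes_ : (2,) array — sorted class labels; the second is positive.
    params_ : trained :class:`moodgraph.network.NetworkParams`.
    loss_history_ : list of per-epoch mean training losses.
    """

    def __init__(self, n_units_eeg: int = 3, n_units_audio: int = 3,
                 hidden_dim: int = 32, sage_dim: int = 32,
                 attention_dim: int = 16, pool_ratio: float = 0.5,
                 lam: float = 1.0, lr: float = 3e-3, n_epochs: int = 25,
                 batch_size: int = 256, tol: float = 1e-3, patience: int = 4,
                 eeg_adjacency=None, audio_adjacency=None,
                 dtype: str = "float32", random_state: int = 0,
                 verbose: int = 0):
        self.n_units_eeg = n_units_eeg
        self.n_units_audio = n_units_audio
        self.hidden_dim = hidden_dim
        self.sage_dim = sage_dim
        self.attention_dim = attention_dim
        self.pool_ratio = pool_ratio
        self.lam = lam
        self.lr = lr
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.tol = tol
        self.patience = patience
        self.eeg_adjacency = eeg_adjacency
        self.audio_adjacency = audio_adjacency
        self.dtype = dtype
        self.random_state = random_state
        self.verbose = verbose

    # -- plumbing ---------------------------------------------------------
    def _unpack(self, X, *, fitting: bool):
        eeg = np.asarray(X["eeg"], dtype=float)
        audio = np.asarray(X["audio"], dtype=float)
        if eeg.ndim != 3 or audio.ndim != 3:
            raise ValueError("eeg and audio must be 3-D (N, nodes, features)")
        if eeg.shape[0] != audio.shape[0]:
            raise ValueError("eeg and audio sample counts differ")
        if not (np.all(np.isfinite(eeg)) and np.all(np.isfinite(audio))):
            raise ValueError("inputs contain non-finite values")
        if fitting:
            a_e = X.get("eeg_adjacency", self.eeg_adjacency)
            if a_e is None:
                raise ValueError(
                    "an EEG adjacency is required (pass eeg_adjacency in X "
                    "or to the constructor)")
            a_a = X.get("audio_adjacency", self.audio_adjacency)
            if a_a is None:
                a_a = build_chain_adjacency(audio.shape[1])
            self._a_eeg = np.asarray(a_e, dtype=float)
            self._a_audio = np.asarray(a_a, dtype=float)
            if self._a_eeg.shape != (eeg.shape[1],) * 2:
                raise ValueError("EEG adjacency shape does not match channels")
            if self._a_audio.shape != (audio.shape[1],) * 2:
                raise ValueError("audio adjacency shape does not match slices")
        return eeg, audio

    def _encode_y(self, y):
        y = np.asarray(y).ravel()
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"expected exactly 2 classes, got {classes.size}")
        return classes, (y == classes[1]).astype(int)

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y):
        eeg, audio = self._unpack(X, fitting=True)
        self.classes_, y01 = self._encode_y(y)
        n = eeg.shape[0]
        if y01.size != n:
            raise ValueError("label count does not match sample count")
        rng = np.random.default_rng(self.random_state)
        dtype = np.dtype(self.dtype).type
        params = net.init_params(
            rng, m_eeg=eeg.shape[2], m_audio=audio.shape[2],
            n_units_eeg=self.n_units_eeg, n_units_audio=self.n_units_audio,
            hidden=self.hidden_dim, sage_dim=self.sage_dim,
            att_dim=self.attention_dim, lam=self.lam,
            pool_ratio=self.pool_ratio, dtype=dtype)
        opt = net.Adam(params.tensors(), lr=self.lr)
        onehot = np.eye(2)[y01]
        self.loss_history_ = []
        best = np.inf
        stale = 0
        for epoch in range(self.n_epochs):
            order = rng.permutation(n)
            losses, hits = [], 0
            for start in range(0, n, self.batch_size):
                b = order[start:start + self.batch_size]
                opt.zero_grad()
                logits = net.forward(params, eeg[b], audio[b],
                                     self._a_eeg, self._a_audio)
                loss = softmax_cross_entropy(logits, onehot[b])
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
                hits += int((logits.data.argmax(axis=1) == y01[b]).sum())
            epoch_loss = float(np.mean(losses))
            self.loss_history_.append(epoch_loss)
            if self.verbose:
                print(f"epoch {epoch + 1}: loss={epoch_loss:.4f} "
                      f"acc={hits / n:.3f}")
            if epoch_loss < best - self.tol:
                best = epoch_loss
                stale = 0
            else:
                stale += 1
            if hits == n and epoch_loss < 0.01:
                break
            if stale >= self.patience:
                break
        self.params_ = params
        self.n_epochs_run_ = len(self.loss_history_)
        return self

    def _logits(self, X, collect: dict | None = None) -> np.ndarray:
        eeg, audio = self._unpack(X, fitting=False)
        out = []
        alphas_e, alphas_a = [], []
        for start in range(0, eeg.shape[0], self.batch_size):
            sl = slice(start, start + self.batch_size)
            c = {} if collect is not None else None
            logits = net.forward(self.params_, eeg[sl], audio[sl],
                                 self._a_eeg, self._a_audio, collect=c)
            out.append(logits.data)
            if collect is not None:
                alphas_e.append(c["eeg"]["alpha"])
                alphas_a.append(c["audio"]["alpha"])
        if collect is not None:
            collect["eeg_alpha"] = np.concatenate(alphas_e)
            collect["audio_alpha"] = np.concatenate(alphas_a)
        return np.concatenate(out)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        z = self._logits(X)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    # -- interpretability -------------------------------------------------
    def channel_attention(self, X) -> dict[str, np.ndarray]:
        """Mean node-attention distribution over the given samples.

        Returns per-EEG-channel and per-audio-slice scores (each a
        probability vector averaged over samples).
        """
        check_is_fitted(self, "params_")
        collect: dict = {}
        self._logits(X, collect=collect)
        return {"eeg": collect["eeg_alpha"].mean(axis=0),
                "audio": collect["audio_alpha"].mean(axis=0)}

    def audio_family_attention(self, family_slices: dict) -> dict[str, float]:
        """Per-family audio attention: the feature-level gate values
        sigmoid(w) averaged within each family's column span of the audio
        feature matrix (the context-vector part of the embedding)."""
        check_is_fitted(self, "params_")
        gate = _np_sigmoid(self.params_.audio.gate.data.astype(float))
        return {fam: float(gate[sl].mean()) for fam, sl in family_slices.items()}
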
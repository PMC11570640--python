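"""Speech emotion features for the audio graph.

An interview recording is cut into ``n_slices`` equal-duration slices; each
slice becomes one node of a temporal chain graph and is summarized by a
fixed-length row of frame-averaged acoustic statistics drawn from seven
families: MFCC, Mel-spectrogram, pitch, RMS energy, chroma, spectral
contrast and tonnetz.  Stacking the rows in slice order yields the initial
audio feature matrix X0 (``n_slices`` x ``n_features``).

The default layout totals 580 columns:

=========  ============================================  =======
family     contents                                      columns
=========  ============================================  =======
mfcc       40 coeffs + deltas, mean and std               160
mel        180 band log-energies, mean and std            360
pitch      mean, std, median, min, max, voiced fraction     6
energy     RMS mean, std, min, max                          4
chroma     12 pitch classes, mean and std                  24
contrast   7 octave bands, mean and std                    14
tonnetz    6 tonal centroids, mean and std                 12
=========  ============================================  =======

All statistics are means/stds over analysis frames within the slice, so the
extraction is deterministic.  Silence is well-defined: RMS statistics are 0
and pitch uses 0 as the unvoiced sentinel; no NaN is ever emitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, rfft
from scipy.io import wavfile

__all__ = [
    "AudioRecording",
    "FeatureConfig",
    "SliceFeatureMatrix",
    "read_wav",
    "write_wav",
    "slice_waveform",
    "compute_slice_features",
    "build_audio_feature_matrix",
]

_EPS = 1e-10
_STAT_NAMES = ("mean", "std")
FAMILY_ORDER = ("mfcc", "mel", "pitch", "energy", "chroma", "contrast", "tonnetz")


@dataclass(frozen=True)
class AudioRecording:
    """A mono waveform with its sampling rate in Hz."""

    samples: np.ndarray
    rate: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float).ravel()
        object.__setattr__(self, "samples", samples)
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class FeatureConfig:
    """Layout and frame parameters of the per-slice feature row.

    ``frame_length``/``hop_length`` are in samples (defaults sized for
    44.1 kHz speech); a slice shorter than one frame is analyzed as a single
    zero-padded frame.
    """

    n_mfcc: int = 40
    mfcc_deltas: bool = True
    n_mels: int = 180
    n_chroma: int = 12
    n_contrast_bands: int = 6          # yields n_contrast_bands + 1 rows
    frame_length: int = 2048
    hop_length: int = 512
    fmin_pitch: float = 50.0
    fmax_pitch: float = 600.0
    contrast_fmin: float = 200.0
    contrast_quantile: float = 0.2

    def family_sizes(self) -> dict[str, int]:
        mfcc = self.n_mfcc * 2 * (2 if self.mfcc_deltas else 1)
        return {
            "mfcc": mfcc,
            "mel": self.n_mels * 2,
            "pitch": 6,
            "energy": 4,
            "chroma": self.n_chroma * 2,
            "contrast": (self.n_contrast_bands + 1) * 2,
            "tonnetz": 12,
        }

    @property
    def n_features(self) -> int:
        return sum(self.family_sizes().values())

    def feature_names(self) -> list[str]:
        names: list[str] = []
        for fam in FAMILY_ORDER:
            size = self.family_sizes()[fam]
            if fam == "pitch":
                names += [f"pitch_{s}" for s in
                          ("mean", "std", "median", "min", "max", "voiced_frac")]
            elif fam == "energy":
                names += [f"energy_rms_{s}" for s in ("mean", "std", "min", "max")]
            else:
                per_stat = size // 2
                for stat in _STAT_NAMES:
                    names += [f"{fam}_{stat}_{i:03d}" for i in range(per_stat)]
        return names

    def family_slices(self) -> dict[str, slice]:
        """Column span of each family, in the fixed emission order."""
        out: dict[str, slice] = {}
        start = 0
        sizes = self.family_sizes()
        for fam in FAMILY_ORDER:
            out[fam] = slice(start, start + sizes[fam])
            start += sizes[fam]
        return out

    def manifest(self) -> dict:
        return {
            "n_features": self.n_features,
            "family_order": list(FAMILY_ORDER),
            "family_sizes": self.family_sizes(),
            "frame_length": self.frame_length,
            "hop_length": self.hop_length,
        }


@dataclass(frozen=True)
class SliceFeatureMatrix:
    """The initial audio graph feature matrix X0 plus its column labels."""

    values: np.ndarray
    feature_names: tuple
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if values.ndim != 2:
            raise ValueError("slice feature matrix must be 2-D")
        if len(self.feature_names) != values.shape[1]:
            raise ValueError("feature_names length must equal column count")
        if not np.all(np.isfinite(values)):
            raise ValueError("slice feature matrix contains non-finite values")


# -- WAV I/O ---------------------------------------------------------------

def read_wav(path) -> AudioRecording:
    """Read a WAV file as a mono float recording (channels averaged,
    integer formats rescaled to [-1, 1])."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return AudioRecording(samples=data.astype(float), rate=float(rate))


def write_wav(recording: AudioRecording, path) -> None:
    wavfile.write(path, int(recording.rate),
                  recording.samples.astype(np.float32))


# -- slicing ---------------------------------------------------------------

def slice_waveform(recording: AudioRecording, n_slices: int) -> list[AudioRecording]:
    """Cut the recording into ``n_slices`` equal-length slices.

    Each slice holds ``floor(L / n_slices)`` samples; trailing remainder
    samples are discarded so every node summarizes the same duration.
    """
    if n_slices <= 0:
        raise ValueError(f"n_slices must be positive, got {n_slices}")
    length = len(recording)
    if length < n_slices:
        raise ValueError(
            f"recording too short: {length} samples for {n_slices} slices")
    per = length // n_slices
    return [AudioRecording(recording.samples[i * per:(i + 1) * per],
                           recording.rate)
            for i in range(n_slices)]


# -- spectral helpers ------------------------------------------------------

def _frame(x: np.ndarray, frame: int, hop: int) -> np.ndarray:
    """(n_frames, frame) view of x; a short signal gives one padded frame."""
    if x.size < frame:
        out = np.zeros(frame)
        out[:x.size] = x
        return out[None, :]
    n_frames = 1 + (x.size - frame) // hop
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def _power_spectrogram(frames: np.ndarray, n_fft: int) -> np.ndarray:
    window = np.hanning(frames.shape[1])
    spec = rfft(frames * window, n=n_fft, axis=1)
    return np.abs(spec) ** 2


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def _mel_filterbank(n_mels: int, n_fft: int, rate: float) -> np.ndarray:
    freqs = np.linspace(0.0, rate / 2.0, n_fft // 2 + 1)
    edges = _mel_to_hz(np.linspace(_hz_to_mel(0.0), _hz_to_mel(rate / 2.0),
                                   n_mels + 2))
    fb = np.zeros((n_mels, freqs.size))
    for i in range(n_mels):
        lo, mid, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (freqs - lo) / max(mid - lo, _EPS)
        down = (hi - freqs) / max(hi - mid, _EPS)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def _stats(x: np.ndarray) -> np.ndarray:
    """mean then std over frames (axis 0), concatenated."""
    return np.concatenate([x.mean(axis=0), x.std(axis=0)])


def _pitch_autocorr(frames: np.ndarray, rate: float, fmin: float,
                    fmax: float) -> np.ndarray:
    """Per-frame fundamental frequency by normalized autocorrelation peak;
    0 marks unvoiced frames (low energy or weak periodicity)."""
    n = frames.shape[1]
    lag_min = max(2, int(np.floor(rate / fmax)))
    lag_max = min(n - 1, int(np.ceil(rate / fmin)))
    pitches = np.zeros(frames.shape[0])
    if lag_max <= lag_min:
        return pitches
    for i, fr in enumerate(frames):
        energy = float(fr @ fr)
        if energy < _EPS:
            continue
        ac = np.correlate(fr, fr, mode="full")[n - 1:]
        ac = ac / (ac[0] + _EPS)
        seg = ac[lag_min:lag_max + 1]
        best = int(np.argmax(seg))
        if seg[best] < 0.3:
            continue
        lag = lag_min + best
        # parabolic interpolation around the peak for sub-sample accuracy
        if 0 < lag < len(ac) - 1:
            a, b, c = ac[lag - 1], ac[lag], ac[lag + 1]
            denom = a - 2 * b + c
            if abs(denom) > _EPS:
                lag = lag + 0.5 * (a - c) / denom
        pitches[i] = rate / lag
    return pitches


def _spectral_contrast(power: np.ndarray, rate: float, n_fft: int,
                       n_bands: int, fmin: float, quantile: float) -> np.ndarray:
    """Octave-band peak-to-valley log contrast, (n_frames, n_bands+1)."""
    freqs = np.linspace(0.0, rate / 2.0, n_fft // 2 + 1)
    edges = [0.0] + [fmin * 2.0 ** b for b in range(n_bands)] + [rate / 2.0]
    out = np.zeros((power.shape[0], n_bands + 1))
    for b in range(n_bands + 1):
        lo, hi = edges[b], edges[b + 1]
        mask = (freqs >= lo) & (freqs < hi) if b < n_bands else \
               (freqs >= lo) & (freqs <= hi)
        band = power[:, mask]
        if band.shape[1] == 0:
            continue
        k = max(1, int(round(quantile * band.shape[1])))
        srt = np.sort(band, axis=1)
        valley = srt[:, :k].mean(axis=1)
        peak = srt[:, -k:].mean(axis=1)
        out[:, b] = np.log(peak + _EPS) - np.log(valley + _EPS)
    return out


def _chroma(power: np.ndarray, rate: float, n_fft: int,
            n_chroma: int) -> np.ndarray:
    """Pitch-class energy profile per frame, inf-norm normalized (so the
    family is invariant to amplitude scaling)."""
    freqs = np.linspace(0.0, rate / 2.0, n_fft // 2 + 1)
    c0 = 32.703195662574764  # C1 reference for pitch-class folding
    valid = freqs > c0 / 2
    classes = np.zeros(freqs.size, dtype=int)
    classes[valid] = np.round(n_chroma * np.log2(freqs[valid] / c0)).astype(int) % n_chroma
    ch = np.zeros((power.shape[0], n_chroma))
    for pc in range(n_chroma):
        mask = valid & (classes == pc)
        if mask.any():
            ch[:, pc] = power[:, mask].sum(axis=1)
    peak = ch.max(axis=1, keepdims=True)
    return np.where(peak > _EPS, ch / np.maximum(peak, _EPS), 0.0)


_TONNETZ_BASIS = None


def _tonnetz_basis(n_chroma: int) -> np.ndarray:
    """6 x n_chroma tonal-centroid transform (fifths, minor/major thirds)."""
    p = np.arange(n_chroma)
    angles = np.vstack([
        p * 7.0 * np.pi / 6.0,
        p * 7.0 * np.pi / 6.0,
        p * 3.0 * np.pi / 2.0,
        p * 3.0 * np.pi / 2.0,
        p * 2.0 * np.pi / 3.0,
        p * 2.0 * np.pi / 3.0,
    ])
    radii = np.array([1.0, 1.0, 1.0, 1.0, 0.5, 0.5])[:, None]
    basis = radii * np.vstack([
        np.sin(angles[0]), np.cos(angles[1]),
        np.sin(angles[2]), np.cos(angles[3]),
        np.sin(angles[4]), np.cos(angles[5]),
    ])
    return basis


def _tonnetz(chroma: np.ndarray) -> np.ndarray:
    norm = chroma.sum(axis=1, keepdims=True)
    cn = np.where(norm > _EPS, chroma / np.maximum(norm, _EPS), 0.0)
    return cn @ _tonnetz_basis(chroma.shape[1]).T


# -- per-slice feature row -------------------------------------------------

def compute_slice_features(slice_rec: AudioRecording,
                           config: FeatureConfig | None = None) -> np.ndarray:
    """One feature row (length ``config.n_features``) for a single slice."""
    config = config or FeatureConfig()
    x = slice_rec.samples
    if x.size == 0:
        raise ValueError("cannot compute features of an empty slice")
    rate = slice_rec.rate
    frames = _frame(x, config.frame_length, config.hop_length)
    n_fft = config.frame_length
    power = _power_spectrogram(frames, n_fft)

    mel_fb = _mel_filterbank(config.n_mels, n_fft, rate)
    mel_power = power @ mel_fb.T
    log_mel = np.log(mel_power + _EPS)

    mfcc = dct(log_mel, type=2, norm="ortho", axis=1)[:, :config.n_mfcc]
    parts = [_stats(mfcc)]
    if config.mfcc_deltas:
        delta = np.diff(mfcc, axis=0, prepend=mfcc[:1])
        parts.append(_stats(delta))
    mfcc_block = np.concatenate(parts)

    mel_block = _stats(log_mel)

    pitches = _pitch_autocorr(frames, rate, config.fmin_pitch, config.fmax_pitch)
    voiced = pitches[pitches > 0]
    if voiced.size:
        pitch_block = np.array([voiced.mean(), voiced.std(), np.median(voiced),
                                voiced.min(), voiced.max(),
                                voiced.size / pitches.size])
    else:
        pitch_block = np.zeros(6)

    rms = np.sqrt((frames ** 2).mean(axis=1))
    energy_block = np.array([rms.mean(), rms.std(), rms.min(), rms.max()])

    chroma = _chroma(power, rate, n_fft, config.n_chroma)
    chroma_block = _stats(chroma)

    contrast = _spectral_contrast(power, rate, n_fft, config.n_contrast_bands,
                                  config.contrast_fmin, config.contrast_quantile)
    contrast_block = _stats(contrast)

    tonnetz_block = _stats(_tonnetz(chroma))

    row = np.concatenate([mfcc_block, mel_block, pitch_block, energy_block,
                          chroma_block, contrast_block, tonnetz_block])
    assert row.size == config.n_features
    return row


def build_audio_feature_matrix(recording: AudioRecording, n_slices: int = 32,
                               config: FeatureConfig | None = None
                               ) -> SliceFeatureMatrix:
    """Slice the recording and stack per-slice feature rows in time order."""
    config = config or FeatureConfig()
    slices = slice_waveform(recording, n_slices)
    rows = np.stack([compute_slice_features(s, config) for s in slices])
    return SliceFeatureMatrix(values=rows,
                              feature_names=config.feature_names(),
                              manifest=config.manifest())


def write_feature_matrix(fm: SliceFeatureMatrix, values_path, manifest_path) -> None:
    """CSV matrix (columns = feature names) plus a JSON layout manifest."""
    import pandas as pd

    pd.DataFrame(fm.values, columns=list(fm.feature_names)).to_csv(
        values_path, index=False)
    with open(manifest_path, "w") as fh:
        json.dump(fm.manifest, fh, indent=2)
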
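"""Synthetic paired EEG/audio fixture with known class structure.

The generator emulates the *layout* of a multimodal depression corpus:
22 depressed (MDD) and 29 healthy-control (HC) subjects, 29 paired
segments each (so 638 MDD and 841 HC samples), 128 EEG channels on a
2-D projected montage, and 32 audio slices per sample.  It does not
attempt physiological realism — channel features are band-power-like
Gaussian summaries and audio features are family-structured Gaussian
rows — but it plants a known, recoverable class signal:

* EEG: a mean shift of ``effect_size * noise_sd`` on a designated
  frontal/temporal channel subset (first ``n_signal_features`` feature
  columns), with a left/right hemispheric asymmetry for MDD (left-side
  signal channels shifted more than right-side ones);
* audio: MDD shifts Mel-band means upward and pitch/energy statistics
  downward, mirroring the family importance ranking the attention head
  should recover;
* a per-subject random effect shared across a subject's segments, so
  segments are correlated within subject and subject-level CV splitting
  is the honest evaluation.

Everything is driven by one seed; identical configs produce identical
datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .acoustic import FAMILY_ORDER, AudioRecording
from .graphs import ElectrodeMontage

__all__ = [
    "FixtureConfig",
    "FixtureSample",
    "COMPACT_AUDIO_LAYOUT",
    "compact_audio_family_slices",
    "generate_montage",
    "generate_dataset",
    "write_fixture",
    "read_fixture",
    "as_arrays",
]

# Compact per-family audio layout used by the feature-mode fixture (the
# full 580-column layout of moodgraph.acoustic is for real recordings).
COMPACT_AUDIO_LAYOUT: dict[str, int] = {
    "mfcc": 13, "mel": 16, "pitch": 3, "energy": 3,
    "chroma": 6, "contrast": 4, "tonnetz": 3,
}


def compact_audio_family_slices(layout: dict[str, int] | None = None
                                ) -> dict[str, slice]:
    layout = layout or COMPACT_AUDIO_LAYOUT
    out, start = {}, 0
    for fam in FAMILY_ORDER:
        n = layout[fam]
        out[fam] = slice(start, start + n)
        start += n
    return out


@dataclass(frozen=True)
class FixtureConfig:
    """Study-layout and signal parameters of the synthetic dataset."""

    n_mdd_subjects: int = 22
    n_hc_subjects: int = 29
    segments_per_subject: int = 29
    n_eeg_channels: int = 128
    n_audio_slices: int = 32
    n_eeg_features: int = 16        # band-power-like summaries per channel
    n_signal_features: int = 6      # leading EEG feature columns carrying signal
    effect_size: float = 1.0        # standardized class mean shift
    asymmetry: float = 0.5          # extra left / reduced right shift for MDD
    noise_sd: float = 1.0
    subject_sd: float = 0.2         # sd of the per-subject random effect
    audio_mode: str = "features"    # "features" | "waveform"
    audio_rate: float = 8000.0      # waveform mode only
    audio_samples_per_slice: int = 400
    seed: int = 0

    def __post_init__(self):
        for name in ("n_mdd_subjects", "n_hc_subjects", "segments_per_subject",
                     "n_eeg_channels", "n_audio_slices", "n_eeg_features"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.audio_mode not in ("features", "waveform"):
            raise ValueError(f"unknown audio_mode {self.audio_mode!r}")
        if not 0 < self.n_signal_features <= self.n_eeg_features:
            raise ValueError("n_signal_features must be in [1, n_eeg_features]")


@dataclass(frozen=True)
class FixtureSample:
    """One subject-segment: paired EEG and audio with a shared label."""

    subject_id: str
    segment_id: int
    label: str                      # "MDD" | "HC"
    eeg: np.ndarray                 # (n_eeg_channels, n_eeg_features)
    audio: np.ndarray | AudioRecording


def generate_montage(n_channels: int) -> ElectrodeMontage:
    """Deterministic ring montage on the unit disk, mirrored across x=0.

    Channels sit on concentric rings; each ring's angles are evenly spaced
    starting from the top (pi/2), which makes the layout exactly symmetric
    under x -> -x.  Hemisphere tags follow the sign of x.
    """
    if n_channels < 2:
        raise ValueError("montage needs at least 2 channels")
    n_rings = max(1, int(np.ceil(np.sqrt(n_channels) / 3.0)))
    radii = (np.arange(n_rings) + 1.0) / n_rings
    weights = radii / radii.sum()
    counts = np.maximum(np.floor(weights * n_channels).astype(int), 1)
    # largest-remainder rounding, outermost rings first (deterministic)
    remainders = weights * n_channels - counts
    order = np.argsort(-remainders, kind="stable")
    i = 0
    while counts.sum() < n_channels:
        counts[order[i % n_rings]] += 1
        i += 1
    while counts.sum() > n_channels:
        counts[np.argmax(counts)] -= 1
    coords, hemis = [], []
    for r, c in zip(radii, counts):
        angles = np.pi / 2.0 + 2.0 * np.pi * np.arange(c) / c
        xs = r * np.cos(angles)
        ys = r * np.sin(angles)
        xs[np.abs(xs) < 1e-9] = 0.0
        for x, y in zip(xs, ys):
            coords.append((x, y))
            hemis.append("left" if x < 0 else ("right" if x > 0 else "midline"))
    labels = [f"E{i + 1:03d}" for i in range(n_channels)]
    return ElectrodeMontage(labels=labels, coords=np.array(coords),
                            hemisphere=hemis)


def default_eeg_adjacency(n_channels: int, k: int = 4) -> np.ndarray:
    """EEG adjacency for the ring montage: k-NN local edges united with the
    mirror-matched symmetric-pair edges."""
    from .graphs import (build_local_adjacency, build_symmetric_adjacency,
                         combine_adjacency, default_symmetric_pairs)

    montage = generate_montage(n_channels)
    local = build_local_adjacency(montage, k=k)
    sym = build_symmetric_adjacency(montage, default_symmetric_pairs(montage))
    return combine_adjacency(local, sym)


def signal_channel_indices(montage: ElectrodeMontage) -> np.ndarray:
    """Frontal (top of the disk) plus temporal (far lateral) channels."""
    x, y = montage.coords[:, 0], montage.coords[:, 1]
    return np.flatnonzero((y >= 0.5) | (np.abs(x) >= 0.85))


def _synth_waveform(rng: np.random.Generator, cfg: FixtureConfig,
                    is_mdd: bool, subject_jitter: float) -> AudioRecording:
    """Tone-plus-noise stand-in for a speech segment; MDD lowers the
    fundamental and the amplitude."""
    n = cfg.n_audio_slices * cfg.audio_samples_per_slice
    t = np.arange(n) / cfg.audio_rate
    f0 = 175.0 + subject_jitter - (20.0 * cfg.effect_size if is_mdd else 0.0)
    amp = 0.5 * (1.0 - (0.25 * cfg.effect_size if is_mdd else 0.0))
    wave = amp * np.sin(2.0 * np.pi * f0 * t) + 0.05 * rng.normal(size=n)
    return AudioRecording(samples=wave, rate=cfg.audio_rate)


def generate_dataset(config: FixtureConfig | None = None
                     ) -> tuple[list[FixtureSample], dict]:
    """Generate all subject-segments plus a manifest describing the layout.

    Sample counts follow the emulated corpus exactly:
    ``n_mdd_subjects * segments_per_subject`` MDD samples and
    ``n_hc_subjects * segments_per_subject`` HC samples (638 + 841 with the
    defaults).
    """
    cfg = config or FixtureConfig()
    rng = np.random.default_rng(cfg.seed)
    montage = generate_montage(cfg.n_eeg_channels)
    sig_idx = signal_channel_indices(montage)
    left_sig = sig_idx[montage.coords[sig_idx, 0] < 0]
    right_sig = sig_idx[montage.coords[sig_idx, 0] > 0]

    n_af = sum(COMPACT_AUDIO_LAYOUT.values())
    fam = compact_audio_family_slices()
    delta = cfg.effect_size * cfg.noise_sd

    samples: list[FixtureSample] = []
    subjects = ([("MDD", i) for i in range(cfg.n_mdd_subjects)]
                + [("HC", i) for i in range(cfg.n_hc_subjects)])
    for label, si in subjects:
        subject_id = f"{label}{si + 1:02d}"
        is_mdd = label == "MDD"
        u_eeg = rng.normal(0.0, cfg.subject_sd, size=cfg.n_eeg_features)
        u_audio = rng.normal(0.0, cfg.subject_sd, size=n_af)
        f0_jitter = rng.normal(0.0, 5.0)
        for seg in range(cfg.segments_per_subject):
            eeg = cfg.noise_sd * rng.normal(
                size=(cfg.n_eeg_channels, cfg.n_eeg_features)) + u_eeg
            if is_mdd and cfg.effect_size > 0:
                fsl = slice(0, cfg.n_signal_features)
                eeg[sig_idx, fsl] += delta
                eeg[left_sig, fsl] += cfg.asymmetry * delta
                eeg[right_sig, fsl] -= cfg.asymmetry * delta
            if cfg.audio_mode == "features":
                audio = cfg.noise_sd * rng.normal(
                    size=(cfg.n_audio_slices, n_af)) + u_audio
                if is_mdd and cfg.effect_size > 0:
                    audio[:, fam["mel"]] += 0.5 * delta
                    audio[:, fam["pitch"]] -= 0.8 * delta
                    audio[:, fam["energy"]] -= 0.8 * delta
                audio_obj: np.ndarray | AudioRecording = audio
            else:
                audio_obj = _synth_waveform(rng, cfg, is_mdd, f0_jitter)
            samples.append(FixtureSample(subject_id=subject_id,
                                         segment_id=seg, label=label,
                                         eeg=eeg, audio=audio_obj))
    manifest = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "n_samples": len(samples),
        "n_mdd_samples": cfg.n_mdd_subjects * cfg.segments_per_subject,
        "n_hc_samples": cfg.n_hc_subjects * cfg.segments_per_subject,
        "signal_channels": sig_idx.tolist(),
        "signal_feature_columns": list(range(cfg.n_signal_features)),
        "hemisphere_counts": {
            h: int(sum(1 for t in montage.hemisphere if t == h))
            for h in ("left", "right", "midline")},
        "audio_family_layout": dict(COMPACT_AUDIO_LAYOUT),
    }
    return samples, manifest


# -- on-disk layout --------------------------------------------------------

def write_fixture(samples: list[FixtureSample], manifest: dict, out_dir) -> None:
    """One directory per subject, one compressed array file per segment."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in samples:
        sub = out / s.subject_id
        sub.mkdir(exist_ok=True)
        path = sub / f"segment_{s.segment_id:02d}.npz"
        if isinstance(s.audio, AudioRecording):
            np.savez_compressed(path, eeg=s.eeg, audio=s.audio.samples,
                                audio_rate=s.audio.rate,
                                label=np.array(s.label))
        else:
            np.savez_compressed(path, eeg=s.eeg, audio=s.audio,
                                label=np.array(s.label))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_fixture(in_dir) -> tuple[list[FixtureSample], dict]:
    src = Path(in_dir)
    manifest_path = src / "manifest.json"
    if not manifest_path.exists():
        raise ValueError(f"fixture manifest missing at {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    samples: list[FixtureSample] = []
    for sub in sorted(p for p in src.iterdir() if p.is_dir()):
        for seg_path in sorted(sub.glob("segment_*.npz")):
            with np.load(seg_path) as z:
                label = str(z["label"])
                if "audio_rate" in z.files:
                    audio: np.ndarray | AudioRecording = AudioRecording(
                        samples=z["audio"], rate=float(z["audio_rate"]))
                else:
                    audio = z["audio"]
                samples.append(FixtureSample(
                    subject_id=sub.name,
                    segment_id=int(seg_path.stem.split("_")[1]),
                    label=label, eeg=z["eeg"], audio=audio))
    if len(samples) != manifest["n_samples"]:
        raise ValueError(
            f"fixture integrity error: manifest lists {manifest['n_samples']} "
            f"samples but {len(samples)} segment files were found")
    return samples, manifest


def as_arrays(samples: list[FixtureSample]) -> dict:
    """Stack feature-mode samples into model-ready arrays.

    Returns a dict with ``eeg`` (N, n_ch, m_e), ``audio`` (N, n_slices, m_a),
    ``y`` (N,) with MDD = 1, and ``subjects`` (N,) string ids.
    """
    if any(isinstance(s.audio, AudioRecording) for s in samples):
        raise ValueError("as_arrays requires feature-mode audio; extract "
                         "features from waveforms first")
    return {
        "eeg": np.stack([s.eeg for s in samples]),
        "audio": np.stack([np.asarray(s.audio) for s in samples]),
        "y": np.array([1 if s.label == "MDD" else 0 for s in samples]),
        "subjects": np.array([s.subject_id for s in samples]),
    }
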
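"""Cross-validated training, reporting, and the GCN-depth ablation grid.

Folds are stratified at the *subject* level by default: all segments of a
subject stay in one fold, so validation measures generalization to unseen
subjects rather than to unseen segments of already-seen subjects (the
per-subject random effect in the fixture makes the difference material).
A ``split_unit="segment"`` flag preserves the plain per-sample split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import KFold, StratifiedKFold

from .metrics import FoldMetrics, compute_metrics
from .model import MoodGraphClassifier

__all__ = ["CVReport", "make_folds", "run_cv", "run_ablation_grid",
           "ablation_markdown"]


@dataclass
class CVReport:
    """Per-fold metrics plus their arithmetic means and the run config."""

    folds: list
    mean_acc: float
    mean_pre: float
    mean_rec: float
    mean_f1: float
    seed: int
    k: int
    split_unit: str
    config: dict = field(default_factory=dict)

    @classmethod
    def from_folds(cls, folds: list[FoldMetrics], *, seed: int, k: int,
                   split_unit: str, config: dict) -> "CVReport":
        return cls(
            folds=folds,
            mean_acc=float(np.mean([f.acc for f in folds])),
            mean_pre=float(np.mean([f.pre for f in folds])),
            mean_rec=float(np.mean([f.rec for f in folds])),
            mean_f1=float(np.mean([f.f1 for f in folds])),
            seed=seed, k=k, split_unit=split_unit, config=config)

    def to_dict(self) -> dict:
        return {
            "folds": [f.to_dict() for f in self.folds],
            "mean_acc": self.mean_acc, "mean_pre": self.mean_pre,
            "mean_rec": self.mean_rec, "mean_f1": self.mean_f1,
            "seed": self.seed, "k": self.k, "split_unit": self.split_unit,
            "config": self.config,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def make_folds(y: np.ndarray, subjects: np.ndarray, k: int, seed: int,
               split_unit: str = "subject") -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified folds as (train_idx, val_idx) sample-index pairs."""
    y = np.asarray(y)
    subjects = np.asarray(subjects)

    def splitter(unit_y):
        # stratify when every class can appear in every fold; otherwise
        # (e.g. leave-one-subject-out) fall back to a plain shuffled split
        if np.bincount(np.unique(unit_y, return_inverse=True)[1]).min() >= k:
            return StratifiedKFold(n_splits=k, shuffle=True,
                                   random_state=seed).split(
                np.zeros_like(unit_y), unit_y)
        return KFold(n_splits=k, shuffle=True, random_state=seed).split(
            np.zeros_like(unit_y))

    if split_unit == "segment":
        return list(splitter(y))
    if split_unit != "subject":
        raise ValueError(f"unknown split_unit {split_unit!r}")
    uniq, first = np.unique(subjects, return_index=True)
    subj_y = y[first]
    folds = []
    for tr_s, va_s in splitter(subj_y):
        tr = np.flatnonzero(np.isin(subjects, uniq[tr_s]))
        va = np.flatnonzero(np.isin(subjects, uniq[va_s]))
        folds.append((tr, va))
        if len(set(y[tr])) < 2:
            raise ValueError("a class is absent from a training split; "
                             "use more subjects or fewer folds")
    return folds


def _take(data: dict, idx: np.ndarray) -> dict:
    x = {"eeg": data["eeg"][idx], "audio": data["audio"][idx]}
    for key in ("eeg_adjacency", "audio_adjacency"):
        if key in data:
            x[key] = data[key]
    return x


def run_cv(data: dict, estimator: MoodGraphClassifier | None = None,
           k: int = 10, seed: int = 0, split_unit: str = "subject"
           ) -> CVReport:
    """Train and evaluate ``estimator`` across ``k`` stratified folds.

    ``data`` holds ``eeg``, ``audio``, ``y`` (binary, positive = larger
    label), ``subjects`` and the adjacencies.  The model is re-initialized
    per fold from a fold-specific seed derived from ``seed``, so the whole
    report is reproducible from (data, config, seed).
    """
    estimator = estimator if estimator is not None else MoodGraphClassifier()
    y = np.asarray(data["y"])
    folds = make_folds(y, data["subjects"], k=k, seed=seed,
                       split_unit=split_unit)
    fold_seeds = np.random.SeedSequence(seed).generate_state(k) % (2 ** 31)
    results: list[FoldMetrics] = []
    positive = np.unique(y)[1]
    for i, (tr, va) in enumerate(folds):
        model = clone(estimator)
        model.set_params(random_state=int(fold_seeds[i]))
        model.fit(_take(data, tr), y[tr])
        pred = model.predict(_take(data, va))
        results.append(compute_metrics(pred, y[va], positive_label=positive,
                                       fold_id=i))
    return CVReport.from_folds(results, seed=seed, k=k, split_unit=split_unit,
                               config=estimator.get_params(deep=False))


def run_ablation_grid(data: dict, eeg_layers=(0, 1, 2, 3, 4),
                      audio_layers=(0, 1, 2, 3, 4), fixed_layers: int = 3,
                      estimator: MoodGraphClassifier | None = None,
                      k: int = 10, seed: int = 0,
                      split_unit: str = "subject") -> list[dict]:
    """Depth ablation: vary one modality's unit count with the other fixed.

    Returns one cell per (modality, n_units): a dict with the varied
    modality, its depth, the fixed depth of the other modality, and the
    resulting :class:`CVReport`.
    """
    estimator = estimator if estimator is not None else MoodGraphClassifier()
    cells = []
    for n in eeg_layers:
        est = clone(estimator)
        est.set_params(n_units_eeg=int(n), n_units_audio=fixed_layers)
        report = run_cv(data, est, k=k, seed=seed, split_unit=split_unit)
        cells.append({"modality": "eeg", "n_units": int(n),
                      "other_fixed": fixed_layers, "report": report})
    for n in audio_layers:
        est = clone(estimator)
        est.set_params(n_units_eeg=fixed_layers, n_units_audio=int(n))
        report = run_cv(data, est, k=k, seed=seed, split_unit=split_unit)
        cells.append({"modality": "audio", "n_units": int(n),
                      "other_fixed": fixed_layers, "report": report})
    return cells


def ablation_markdown(cells: list[dict]) -> str:
    """Markdown table of the ablation grid (mean metrics per cell)."""
    lines = ["| varied modality | units | ACC (%) | PRE (%) | REC (%) | F1 (%) |",
             "|---|---|---|---|---|---|"]
    for c in cells:
        r = c["report"]
        lines.append(
            f"| {c['modality']} | {c['n_units']} | {r.mean_acc:.2f} "
            f"| {r.mean_pre:.2f} | {r.mean_rec:.2f} | {r.mean_f1:.2f} |")
    return "\n".join(lines)
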
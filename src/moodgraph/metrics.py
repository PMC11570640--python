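"""Confusion-count classification metrics (MDD is the positive class).

ACC/PRE/REC/F1 are reported as percentages in [0, 100] and are always
recomputable from the stored confusion counts.  Degenerate denominators
(no predicted or no true positives) yield 0 with a warning flag rather
than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["FoldMetrics", "compute_metrics"]


@dataclass(frozen=True)
class FoldMetrics:
    fold_id: int
    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    pre: float
    rec: float
    f1: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def compute_metrics(predictions, labels, positive_label=1,
                    fold_id: int = 0) -> FoldMetrics:
    """ACC, PRE, REC and F1 (in %) from predicted and true labels.

    ``ACC=(TP+TN)/N``, ``PRE=TP/(TP+FP)``, ``REC=TP/(TP+FN)``,
    ``F1=2*PRE*REC/(PRE+REC)``.
    """
    predictions = np.asarray(predictions).ravel()
    labels = np.asarray(labels).ravel()
    if predictions.size == 0:
        raise ValueError("cannot compute metrics of empty predictions")
    if predictions.size != labels.size:
        raise ValueError("predictions and labels must have equal length")
    pred_pos = predictions == positive_label
    true_pos = labels == positive_label
    tp = int(np.sum(pred_pos & true_pos))
    fp = int(np.sum(pred_pos & ~true_pos))
    fn = int(np.sum(~pred_pos & true_pos))
    tn = int(np.sum(~pred_pos & ~true_pos))
    acc = 100.0 * (tp + tn) / predictions.size
    degenerate = False
    if tp + fp == 0:
        pre, degenerate = 0.0, True
    else:
        pre = 100.0 * tp / (tp + fp)
    if tp + fn == 0:
        rec, degenerate = 0.0, True
    else:
        rec = 100.0 * tp / (tp + fn)
    if pre + rec == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2.0 * pre * rec / (pre + rec)
    return FoldMetrics(fold_id=fold_id, tp=tp, fp=fp, tn=tn, fn=fn,
                       acc=acc, pre=pre, rec=rec, f1=f1, degenerate=degenerate)
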
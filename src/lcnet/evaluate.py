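"""Confusion-matrix metrics and ROC/AUC on a held-out split.

Melanoma (MEL) is the positive class everywhere: TP is a melanoma
correctly called melanoma, TN a benign lesion correctly called benign.
The five derived metrics are

    ACC = (TP+TN) / (TP+FP+TN+FN)      accuracy
    PRE = TP / (TP+FP)                 precision
    REC = TP / (TP+FN)                 recall / sensitivity
    SPE = TN / (TN+FP)                 specificity
    F1  = 2TP / (2TP+FP+FN)            harmonic mean of PRE and REC

A zero denominator yields 0 with the report's ``degenerate`` flag set,
never NaN.  The ROC curve sweeps every distinct score threshold; its
trapezoidal area equals the Mann-Whitney statistic (ties counted half).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataio import ImageRecord, Label

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion",
    "metrics",
    "roc_auc",
    "predict_proba",
    "predict_labels",
    "evaluate_model",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    counts: ConfusionCounts
    acc: float
    pre: float
    rec: float
    spe: float
    f1: float
    degenerate: bool = False
    auc: float | None = None
    roc_points: list[tuple[float, float]] | None = None


def confusion(
    predicted_labels: Sequence[Label],
    true_labels: Sequence[Label],
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN with MEL as the positive class."""
    if len(predicted_labels) != len(true_labels):
        raise ValueError(
            f"length mismatch: {len(predicted_labels)} predictions "
            f"vs {len(true_labels)} truths"
        )
    tp = fp = tn = fn = 0
    for pred, true in zip(predicted_labels, true_labels):
        if true == Label.MEL:
            if pred == Label.MEL:
                tp += 1
            else:
                fn += 1
        else:
            if pred == Label.MEL:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: int, den: int) -> tuple[float, bool]:
    return (num / den, False) if den else (0.0, True)


def metrics(counts: ConfusionCounts) -> EvalReport:
    """Exact formula evaluation of the five confusion-matrix metrics."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics of zero samples")
    acc, d0 = _ratio(counts.tp + counts.tn, counts.total)
    pre, d1 = _ratio(counts.tp, counts.tp + counts.fp)
    rec, d2 = _ratio(counts.tp, counts.tp + counts.fn)
    spe, d3 = _ratio(counts.tn, counts.tn + counts.fp)
    f1, d4 = _ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn)
    return EvalReport(
        counts=counts,
        acc=acc,
        pre=pre,
        rec=rec,
        spe=spe,
        f1=f1,
        degenerate=any((d0, d1, d2, d3, d4)),
    )


def roc_auc(
    scores: Sequence[float],
    true_labels: Sequence[Label],
) -> tuple[float, list[tuple[float, float]]]:
    """ROC curve and AUC from per-sample melanoma scores.

    Sweeps thresholds over the distinct scores (descending); AUC is the
    trapezoidal area, which equals the probability that a random
    melanoma outscores a random benign lesion (ties counted half).
    """
    s = np.asarray(scores, dtype=np.float64)
    if len(s) != len(true_labels):
        raise ValueError("scores and labels must have equal length")
    y = np.array([1 if lab == Label.MEL else 0 for lab in true_labels])
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-s, kind="stable")
    ys, ss = y[order], s[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(1 - ys)
    # one ROC point at the end of each tie group of scores
    last = np.r_[np.nonzero(np.diff(ss))[0], len(ss) - 1]
    fpr = np.r_[0.0, fps[last] / n_neg]
    tpr = np.r_[0.0, tps[last] / n_pos]
    auc = float(np.trapezoid(tpr, fpr))
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def predict_proba(model, records: list[ImageRecord], batch_size: int = 64) -> np.ndarray:
    """Melanoma probability per record (inference-mode forward)."""
    from .train import records_to_arrays  # local import to avoid a cycle

    x, _ = records_to_arrays(records)
    out = []
    for start in range(0, len(records), batch_size):
        out.append(model.forward(x[start : start + batch_size])[:, 0])
    return np.concatenate(out)


def predict_labels(mel_probs: np.ndarray) -> list[Label]:
    """Argmax decision; an exact tie resolves to BEN (conservative)."""
    return [Label.MEL if p > 0.5 else Label.BEN for p in np.asarray(mel_probs)]


def evaluate_model(model, records: list[ImageRecord]) -> EvalReport:
    """Full report on a record set: counts, metrics, ROC and AUC."""
    if not records:
        raise ValueError("no records to evaluate")
    probs = predict_proba(model, records)
    truths = [r.label for r in records]
    report = metrics(confusion(predict_labels(probs), truths))
    if len({r.label for r in records}) == 2:
        report.auc, report.roc_points = roc_auc(probs, truths)
    return report
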
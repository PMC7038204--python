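"""Challenge-style multiclass scores and binary AF-detection scores.

The overall F1 follows the PhysioNet/CinC 2017 Challenge convention: the
mean of the per-class F1 scores of Normal, AF and Other, with the Noisy
class excluded.  The multiclass Matthews correlation coefficient uses the
standard covariance form over the confusion matrix.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .containers import CLASS_ORDER, RhythmLabel


def _as_label(x) -> RhythmLabel:
    return x if isinstance(x, RhythmLabel) else RhythmLabel(x)


@dataclass
class ConfusionMatrix:
    """4x4 counts indexed (true, predicted) in the order Normal, AF, Other, Noisy."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (4, 4):
            raise ValueError("confusion matrix must be 4x4")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self) -> str:
        names = [c.value for c in CLASS_ORDER]
        lines = ["true\\pred," + ",".join(names)]
        for i, name in enumerate(names):
            lines.append(name + "," + ",".join(str(v) for v in self.counts[i]))
        return "\n".join(lines) + "\n"


def confusion(true_labels: Sequence, predicted_labels: Sequence) -> ConfusionMatrix:
    """Tally a 4x4 confusion matrix; raises on length mismatch or unknown labels."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"length mismatch: {len(true_labels)} true vs {len(predicted_labels)} predicted"
        )
    index = {lab: i for i, lab in enumerate(CLASS_ORDER)}
    counts = np.zeros((4, 4), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        counts[index[_as_label(t)], index[_as_label(p)]] += 1
    return ConfusionMatrix(counts)


def challenge_scores(cm: ConfusionMatrix) -> Dict[str, float]:
    """Per-class F1, Challenge overall F1 (Normal/AF/Other mean) and accuracy.

    F1_c = 2 TP_c / (2 TP_c + FP_c + FN_c); a class with no true and no
    predicted members scores 1 (degenerate-denominator convention).
    """
    c = cm.counts
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    f1 = {}
    for i, lab in enumerate(CLASS_ORDER):
        tp = c[i, i]
        fp = c[:, i].sum() - tp
        fn = c[i, :].sum() - tp
        denom = 2 * tp + fp + fn
        f1[lab] = 1.0 if denom == 0 else 2.0 * tp / denom
    overall = (f1[RhythmLabel.NORMAL] + f1[RhythmLabel.AF] + f1[RhythmLabel.OTHER]) / 3.0
    return {
        "f1_normal": f1[RhythmLabel.NORMAL],
        "f1_af": f1[RhythmLabel.AF],
        "f1_other": f1[RhythmLabel.OTHER],
        "f1_noisy": f1[RhythmLabel.NOISY],
        "overall_f1": overall,
        "acc": float(np.trace(c)) / cm.total,
    }


def multiclass_mcc(cm: ConfusionMatrix) -> float:
    """K-class Matthews correlation coefficient (covariance form).

    cov(X, Y) / sqrt(cov(X, X) cov(Y, Y)) over the confusion matrix; returns
    0 for degenerate denominators.
    """
    c = cm.counts.astype(float)
    n = c.sum()
    t = c.sum(axis=1)  # true-class totals
    p = c.sum(axis=0)  # predicted-class totals
    cov_xy = np.trace(c) * n - float(t @ p)
    cov_xx = n * n - float(p @ p)
    cov_yy = n * n - float(t @ t)
    denom = math.sqrt(cov_xx) * math.sqrt(cov_yy)
    if denom == 0:
        return 0.0
    return float(cov_xy / denom)


def binary_af_scores(
    true_labels: Sequence, predicted_labels: Sequence
) -> Dict[str, Optional[float]]:
    """AF-vs-rest sensitivity, specificity and accuracy.

    AF is the positive class; Normal/Other/Noisy are pooled as non-AF.
    Sensitivity is ``None`` (missing, not zero) when truth has no positives;
    likewise specificity with no negatives.
    """
    if len(true_labels) != len(predicted_labels):
        raise ValueError("length mismatch")
    t = np.array([_as_label(x) is RhythmLabel.AF for x in true_labels])
    p = np.array([_as_label(x) is RhythmLabel.AF for x in predicted_labels])
    tp = int(np.sum(t & p))
    tn = int(np.sum(~t & ~p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    acc = (tp + tn) / len(t) if len(t) else None
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc}


@dataclass
class EvaluationReport:
    """Bundle of all scores for one evaluation run."""

    confusion_matrix: ConfusionMatrix
    acc: float
    f1_normal: float
    f1_af: float
    f1_other: float
    f1_noisy: float
    overall_f1: float
    mcc_multiclass: float
    binary: Dict[str, Optional[float]] = field(default_factory=dict)

    def to_json(self) -> str:
        d = {
            "acc": self.acc,
            "f1_normal": self.f1_normal,
            "f1_af": self.f1_af,
            "f1_other": self.f1_other,
            "f1_noisy": self.f1_noisy,
            "overall_f1": self.overall_f1,
            "mcc_multiclass": self.mcc_multiclass,
            "binary": self.binary,
            "confusion": self.confusion_matrix.counts.tolist(),
            "class_order": [c.value for c in CLASS_ORDER],
        }
        return json.dumps(d, indent=2)

    def to_text(self) -> str:
        b = self.binary
        fmt = lambda v: "n/a" if v is None else f"{v:.4f}"
        lines = [
            f"accuracy      {self.acc:.4f}",
            f"F1 Normal     {self.f1_normal:.4f}",
            f"F1 AF         {self.f1_af:.4f}",
            f"F1 Other      {self.f1_other:.4f}",
            f"F1 Noisy      {self.f1_noisy:.4f}",
            f"overall F1    {self.overall_f1:.4f}  (mean of Normal/AF/Other)",
            f"MCC           {self.mcc_multiclass:.4f}",
            f"AF sens/spec/acc  {fmt(b.get('sensitivity'))} / "
            f"{fmt(b.get('specificity'))} / {fmt(b.get('accuracy'))}",
        ]
        return "\n".join(lines) + "\n"


def evaluate(true_labels: Sequence, predicted_labels: Sequence) -> EvaluationReport:
    """Compute the full evaluation report for one set of predictions."""
    cm = confusion(true_labels, predicted_labels)
    s = challenge_scores(cm)
    return EvaluationReport(
        confusion_matrix=cm,
        acc=s["acc"],
        f1_normal=s["f1_normal"],
        f1_af=s["f1_af"],
        f1_other=s["f1_other"],
        f1_noisy=s["f1_noisy"],
        overall_f1=s["overall_f1"],
        mcc_multiclass=multiclass_mcc(cm),
        binary=binary_af_scores(true_labels, predicted_labels),
    )
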
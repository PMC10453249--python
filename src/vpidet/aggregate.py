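"""Subject-level voting and evaluation metrics.

A subject is called VPI when strictly more than half of their phoneme-level
predictions are VPI; a tie (possible only with an even phoneme count) is
resolved to control, since a tie is not "more than half".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class PhonemePrediction:
    subject_id: str
    phoneme: str
    label: str          # predicted: "vpi" | "control"
    score: float = 0.0  # signed margin or P_vpi, model-dependent


@dataclass
class SubjectPrediction:
    subject_id: str
    n_phonemes: int
    n_vpi_votes: int
    label: str
    vote_fraction: float


@dataclass
class MetricSet:
    """Confusion counts and the standard metric set, as percentages."""

    TP: int
    FP: int
    TN: int
    FN: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    tnr: float
    fpr: float

    def as_dict(self, ndigits: int = 2) -> dict:
        d = {"TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN}
        for k in ("accuracy", "precision", "recall", "f1", "tnr", "fpr"):
            v = getattr(self, k)
            d[k] = round(v, ndigits) if np.isfinite(v) else float("nan")
        return d


def vote_subject(preds: list[PhonemePrediction]) -> SubjectPrediction:
    """Strict-majority vote over one subject's phoneme-level predictions."""
    if not preds:
        raise ValueError("no predictions to vote over")
    subjects = {p.subject_id for p in preds}
    if len(subjects) != 1:
        raise ValueError(f"mixed subjects in vote: {sorted(subjects)}")
    n = len(preds)
    votes = sum(1 for p in preds if p.label == "vpi")
    label = "vpi" if votes > n / 2 else "control"
    return SubjectPrediction(subject_id=preds[0].subject_id, n_phonemes=n,
                             n_vpi_votes=votes, label=label,
                             vote_fraction=votes / n)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      stacklevel=3)
        return float("nan")
    return 100.0 * num / den


def compute_metrics(pred_labels, true_labels, positive: str = "vpi") -> MetricSet:
    """Confusion-matrix metrics with the given positive class, as percentages."""
    pred = list(pred_labels)
    true = list(true_labels)
    if len(pred) != len(true):
        raise ValueError("prediction/truth length mismatch")
    TP = sum(1 for p, t in zip(pred, true) if p == positive and t == positive)
    FP = sum(1 for p, t in zip(pred, true) if p == positive and t != positive)
    TN = sum(1 for p, t in zip(pred, true) if p != positive and t != positive)
    FN = sum(1 for p, t in zip(pred, true) if p != positive and t == positive)
    accuracy = _ratio(TP + TN, TP + TN + FP + FN, "accuracy")
    precision = _ratio(TP, TP + FP, "precision")
    recall = _ratio(TP, TP + FN, "recall")
    if np.isfinite(precision) and np.isfinite(recall) and precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1 = float("nan")
    tnr = _ratio(TN, TN + FP, "tnr")
    fpr = _ratio(FP, TN + FP, "fpr")
    return MetricSet(TP=TP, FP=FP, TN=TN, FN=FN, accuracy=accuracy,
                     precision=precision, recall=recall, f1=f1, tnr=tnr, fpr=fpr)
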
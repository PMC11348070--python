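"""Classification metrics: rank-statistic AUC, threshold metrics, ROC.

AUC is computed from the Mann-Whitney U statistic (tie-aware rank sum),
which equals the trapezoidal area under the ROC curve; the equality is
asserted against an independent implementation in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve


class MetricError(ValueError):
    pass


def rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank formulation (handles ties)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUC undefined: only one class present")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> dict:
    """Accuracy/AUC/precision/recall/F1 plus ROC points for one evaluation.

    Thresholded metrics use probability >= *threshold* as the positive call.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise MetricError("labels and scores length mismatch")
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    fpr, tpr, _ = roc_curve(y, s)
    return {
        "accuracy": (tp + tn) / len(y),
        "auc": rank_auc(y, s),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "roc": (fpr, tpr),
    }


METRIC_NAMES = ("accuracy", "auc", "precision", "recall", "f1")


@dataclass
class EvalReport:
    """Per-repeat metric values with mean +/- sd summaries and ROC curves."""

    per_repeat: list[dict] = field(default_factory=list)
    rocs: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def add(self, metrics: dict) -> None:
        self.per_repeat.append({k: metrics[k] for k in METRIC_NAMES})
        self.rocs.append(metrics["roc"])

    def mean(self, name: str) -> float:
        return float(np.mean([m[name] for m in self.per_repeat]))

    def sd(self, name: str) -> float:
        return float(np.std([m[name] for m in self.per_repeat], ddof=1)) if len(
            self.per_repeat
        ) > 1 else 0.0

    def summary(self) -> dict:
        return {name: (self.mean(name), self.sd(name)) for name in METRIC_NAMES}

    def __len__(self) -> int:
        return len(self.per_repeat)
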
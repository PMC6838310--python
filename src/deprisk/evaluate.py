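"""Model application and ROC/AUC evaluation.

The AUC is computed in its rank (Mann-Whitney) form — the probability that
a randomly chosen case scores above a randomly chosen non-case, with ties
credited one half — which equals the trapezoidal area under the empirical
ROC curve.  AUC levels are mapped to the conventional qualitative bands
(excellent / good / fair / poor / fail).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .ensemble_averaging import AveragedModel
from .feature_prep import DesignMatrix

__all__ = [
    "ROCResult",
    "predict_probability",
    "auc",
    "roc_points",
    "performance_band",
]


@dataclass
class ROCResult:
    """Empirical ROC curve: FPR/TPR vertices plus the trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    cohort: str = ""

    def __post_init__(self) -> None:
        if (np.diff(self.fpr) < 0).any() or (np.diff(self.tpr) < 0).any():
            raise ValueError("ROC points must be monotone non-decreasing")
        if not (self.fpr[0] == 0 and self.tpr[0] == 0
                and self.fpr[-1] == 1 and self.tpr[-1] == 1):
            raise ValueError("ROC curve must run from (0,0) to (1,1)")


def predict_probability(model: AveragedModel, design: DesignMatrix) -> np.ndarray:
    """Predicted outcome probability, logistic(intercept + x . beta).

    The design must be standardized with the training scaling parameters
    and contain every column the averaged model retains.
    """
    idx = {c: j for j, c in enumerate(design.columns)}
    missing = [c for c in model.coef if c not in idx]
    if missing:
        raise ValueError(f"design is missing retained column(s): {missing}")
    eta = np.full(design.n, model.intercept)
    for col, b in model.coef.items():
        eta += b * design.X[:, idx[col]]
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


def _check_two_classes(labels: np.ndarray) -> None:
    if not ((labels == 0).any() and (labels == 1).any()):
        raise ValueError("both outcome classes must be present")


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_case > score_noncase), ties count half."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    _check_two_classes(labels)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = len(labels) - n1
    ranks = rankdata(scores)  # average ranks give half credit to ties
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_points(labels: np.ndarray, scores: np.ndarray, cohort: str = "") -> ROCResult:
    """Empirical ROC curve with thresholds at the distinct scores.

    Vertices are accumulated in descending score order starting at (0,0);
    tied scores move diagonally in one step.  The reported AUC is the
    trapezoidal area of these vertices.
    """
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    _check_two_classes(labels)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # Cumulative counts at each distinct threshold.
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1.0 - y)[distinct]
    n1 = labels.sum()
    n0 = len(labels) - n1
    tpr = np.r_[0.0, tp / n1]
    fpr = np.r_[0.0, fp / n0]
    area = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, auc=area, cohort=cohort)


def performance_band(value: float) -> str:
    """Qualitative AUC band; boundaries belong to the upper band.

    0.9-1 excellent, 0.8-0.9 good, 0.7-0.8 fair, 0.6-0.7 poor,
    0.5-0.6 fail; below 0.5 is worse than chance.
    """
    if not 0.0 <= value <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    if value >= 0.9:
        return "excellent"
    if value >= 0.8:
        return "good"
    if value >= 0.7:
        return "fair"
    if value >= 0.6:
        return "poor"
    if value >= 0.5:
        return "fail"
    return "fail (worse than chance)"
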
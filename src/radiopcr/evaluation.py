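"""ROC curves, AUC, and Youden-index operating points.

The positive class is pathological complete response (pCR); residual
disease (pR1/pR2) is the negative class. A case is called positive when its
score is greater than or equal to the threshold. The Youden index
J = sensitivity + specificity - 1 picks the operating threshold; ties are
broken toward the higher (more specific) threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RocCurve", "OperatingPoint", "roc", "auc", "youden_optimal", "operating_metrics", "plot_roc"]


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float

    @property
    def youden_j(self) -> float:
        """J = sensitivity + specificity - 1 (exact identity)."""
        return self.sensitivity + self.specificity - 1.0

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "youden_j": self.youden_j,
        }


@dataclass
class RocCurve:
    """ROC staircase: thresholds descending, (fpr, tpr) from (0,0) to (1,1).

    ``thresholds[0]`` is +inf (the predict-nobody endpoint); every other
    threshold is an observed score value.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    n_positive: int
    n_negative: int

    @property
    def auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to build a ROC curve")
    return labels


def roc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve over the unique score values (predict positive when >= t)."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # keep the last index of each run of equal scores (all-or-none at a threshold)
    last = np.r_[np.diff(s) != 0, True]
    thresholds = np.r_[np.inf, s[last]]
    tpr = np.r_[0.0, tp[last] / n_pos]
    fpr = np.r_[0.0, fp[last] / n_neg]
    return RocCurve(thresholds, fpr, tpr, n_pos, n_neg)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal AUC; equals P(score_pos > score_neg) + 0.5 P(tie)."""
    return roc(scores, labels).auc


def youden_optimal(curve: RocCurve) -> OperatingPoint:
    """Operating point maximising J = tpr - fpr; ties -> higher threshold.

    With the (0,0) and (1,1) endpoints on the curve the optimum always has
    J >= 0. Sensitivity/specificity are read off the ROC point itself;
    accuracy follows from the class counts at that point.
    """
    j = curve.tpr - curve.fpr
    best = int(np.argmax(j))  # argmax returns the first (highest-threshold) tie
    thr = curve.thresholds[best]
    if not np.isfinite(thr):
        thr = 1.0  # predict-nobody endpoint, reported at the top of the score scale
    sens = float(curve.tpr[best])
    spec = float(1.0 - curve.fpr[best])
    n = curve.n_positive + curve.n_negative
    acc = (sens * curve.n_positive + spec * curve.n_negative) / n
    return OperatingPoint(float(thr), sens, spec, float(acc))


def operating_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> OperatingPoint:
    """Sensitivity/specificity/accuracy of the rule score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    pred = scores >= threshold
    pos, neg = labels == 1, labels == 0
    tp = int(np.sum(pred & pos))
    tn = int(np.sum(~pred & neg))
    return OperatingPoint(
        float(threshold),
        tp / int(pos.sum()),
        tn / int(neg.sum()),
        (tp + tn) / len(labels),
    )


def plot_roc(curve: RocCurve, point: OperatingPoint | None = None, ax=None):
    """Plot a ROC staircase (and optionally its operating point)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve.fpr, curve.tpr, drawstyle="steps-post", label=f"AUC = {curve.auc:.2f}")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    if point is not None:
        ax.plot(1 - point.specificity, point.sensitivity, "o", c="crimson",
                label=f"Youden J = {point.youden_j:.3f}")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", frameon=False)
    return ax
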
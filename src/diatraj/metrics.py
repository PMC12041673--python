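"""Binary-classification metric panel with a rank-statistic AUC.

AUC is computed as the normalized Mann-Whitney U statistic (ties contribute
one half), which equals trapezoidal integration of the ROC curve.  With a
single class present the AUC is undefined and reported as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass
class Metrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_measure: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f_measure": self.f_measure,
            "auc": self.auc,
        }


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> Metrics:
    """Confusion-count panel at ``threshold`` plus rank-statistic AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    total = tp + fp + tn + fn

    def safe(num: int, den: int) -> float:
        return num / den if den else float("nan")

    sens = safe(tp, tp + fn)
    spec = safe(tn, tn + fp)
    prec = safe(tp, tp + fp)
    f = (2 * prec * sens / (prec + sens)
         if prec + sens > 0 and np.isfinite(prec) and np.isfinite(sens)
         else float("nan"))
    return Metrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=safe(tp + tn, total),
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f_measure=f,
        auc=auc_score(scores, labels),
    )
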
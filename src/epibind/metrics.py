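"""Imbalance-aware evaluation of binary binder predictions.

AUC ROC is the rank statistic (ties counted half); PR AUC is the
non-interpolated average-precision step sum, whose chance level equals the
prevalence — the honest baseline for heavily imbalanced binding data.
Threshold metrics come from the confusion matrix of binary calls.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass
class MetricsReport:
    auc_roc: float | None
    pr_auc: float | None
    acc: float
    ppv: float
    sensitivity: float
    specificity: float
    f1: float
    prevalence: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def compute_metrics(labels, scores=None, calls=None, threshold: float = 0.5) -> MetricsReport:
    """Full metrics report from labels, continuous scores, and binary calls.

    ``calls`` defaults to thresholding ``scores`` at ``threshold``. With a
    single-class label vector the AUCs are undefined (None) but the
    confusion-matrix metrics are still computed.
    """
    labels = np.asarray(labels, dtype=int)
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        if len(scores) != len(labels):
            raise ValueError("labels and scores length mismatch")
    if calls is None:
        if scores is None:
            raise ValueError("provide scores or calls")
        calls = (scores >= threshold).astype(int)
    calls = np.asarray(calls, dtype=int)
    if len(calls) != len(labels):
        raise ValueError("labels and calls length mismatch")

    both_classes = len(np.unique(labels)) == 2
    auc = float(roc_auc_score(labels, scores)) if both_classes and scores is not None else None
    pr = (
        float(average_precision_score(labels, scores))
        if both_classes and scores is not None
        else None
    )

    tp = int(np.sum((calls == 1) & (labels == 1)))
    tn = int(np.sum((calls == 0) & (labels == 0)))
    fp = int(np.sum((calls == 1) & (labels == 0)))
    fn = int(np.sum((calls == 0) & (labels == 1)))
    n = len(labels)
    acc = (tp + tn) / n if n else math.nan
    ppv = tp / (tp + fp) if tp + fp else 0.0
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * ppv * sens / (ppv + sens) if ppv + sens else 0.0
    prev = (tp + fn) / n if n else math.nan
    return MetricsReport(
        auc_roc=auc, pr_auc=pr, acc=acc, ppv=ppv,
        sensitivity=sens, specificity=spec, f1=f1, prevalence=prev,
    )


def auc_roc_pairs(labels, scores) -> float:
    """Brute-force all-pairs AUC ROC (ties counted half). O(n_pos * n_neg).

    Independent of sklearn's rank-statistic implementation; used as the
    oracle in tests but exported because it is occasionally handy for
    sanity checks on small sets.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required")
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return float(wins / (len(pos) * len(neg)))
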
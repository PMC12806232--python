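"""Multi-class evaluation: accuracy, macro F1, one-vs-rest macro AUC / AUPR.

AUC and AUPR are binary-curve metrics; for E event types they are computed
one-vs-rest per type and macro-averaged (micro averaging over the flattened
binarized labels is also exposed).  Event types that are absent from the
label vector, or cover all of it, have no defined binary curve and are
skipped in the macro mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score


@dataclass
class MetricsReport:
    acc: float
    aupr: float
    auc: float
    f1: float
    per_fold: list = field(default=None)

    def as_dict(self) -> dict:
        return {"acc": self.acc, "aupr": self.aupr, "auc": self.auc, "f1": self.f1}

    @classmethod
    def mean_of(cls, reports: list) -> "MetricsReport":
        """Arithmetic mean over folds, keeping the per-fold reports."""
        return cls(
            acc=float(np.mean([r.acc for r in reports])),
            aupr=float(np.mean([r.aupr for r in reports])),
            auc=float(np.mean([r.auc for r in reports])),
            f1=float(np.mean([r.f1 for r in reports])),
            per_fold=list(reports),
        )


def evaluate(prob_matrix, true_labels, average: str = "macro") -> MetricsReport:
    """Score a probability matrix (rows sum to 1) against integer labels."""
    probs = np.asarray(prob_matrix, dtype=float)
    y = np.asarray(true_labels, dtype=int)
    n, E = probs.shape
    if y.min() < 0 or y.max() >= E:
        raise ValueError(f"label outside 0..{E - 1}")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    pred = probs.argmax(axis=1)
    acc = float(np.mean(pred == y))
    f1 = float(f1_score(y, pred, average=average, labels=np.arange(E),
                        zero_division=0))

    onehot = np.zeros_like(probs)
    onehot[np.arange(n), y] = 1.0
    if average == "micro":
        auc = float(roc_auc_score(onehot.ravel(), probs.ravel()))
        aupr = float(average_precision_score(onehot.ravel(), probs.ravel()))
    else:
        aucs, auprs = [], []
        for e in range(E):
            pos = onehot[:, e]
            if 0 < pos.sum() < n:
                aucs.append(roc_auc_score(pos, probs[:, e]))
                auprs.append(average_precision_score(pos, probs[:, e]))
        auc = float(np.mean(aucs)) if aucs else float("nan")
        aupr = float(np.mean(auprs)) if auprs else float("nan")
    return MetricsReport(acc=acc, aupr=aupr, auc=auc, f1=f1)
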
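"""Diagnostic evaluation of predicted probabilities.

ROC curves with Mann-Whitney AUC, Youden-index operating points, confusion
metrics (sensitivity, specificity, PPV, NPV, accuracy) and a Wilcoxon
rank-sum test of case/control separation.  Throughout, a sample is
predicted positive when its probability is >= the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ROCResult", "ConfusionMetrics", "roc_curve", "youden_cutoff",
           "confusion_metrics", "wilcoxon_rank_sum", "validation_report"]


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass
class ConfusionMetrics:
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def npv(self) -> float | None:
        d = self.tn + self.fn
        return self.tn / d if d else None

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.tn + self.fn)

    def as_dict(self) -> dict:
        return {
            "cutoff": self.cutoff, "TP": self.tp, "FP": self.fp,
            "TN": self.tn, "FN": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "accuracy": self.accuracy,
        }


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes")
    return labels


def roc_curve(probs, labels) -> ROCResult:
    """ROC over the unique probabilities as cutoffs (positive when >= cutoff).

    AUC is the Mann-Whitney concordance probability: the fraction of
    (case, control) pairs where the case scores higher, ties counted 1/2 —
    equivalently U / (n1 n0) from midranks.
    """
    probs = np.asarray(probs, dtype=float)
    labels = _check_labels(labels)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    ranks = stats.rankdata(probs)  # midranks handle ties
    u = float(np.sum(ranks[labels == 1])) - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)
    cuts = np.unique(probs)[::-1]
    sens = np.empty(len(cuts))
    spec = np.empty(len(cuts))
    for i, c in enumerate(cuts):
        pred = probs >= c
        sens[i] = np.sum(pred & (labels == 1)) / n1
        spec[i] = np.sum(~pred & (labels == 0)) / n0
    return ROCResult(cuts, sens, spec, auc)


def youden_cutoff(roc: ROCResult) -> dict:
    """Maximize J = sensitivity + specificity - 1; ties -> smallest cutoff."""
    j = roc.sensitivity + roc.specificity - 1.0
    best = np.max(j)
    # thresholds are sorted descending; the last argmax is the smallest cutoff
    idx = np.where(j >= best - 1e-15)[0][-1]
    return {"cutoff": float(roc.thresholds[idx]), "J": float(j[idx])}


def confusion_metrics(probs, labels, cutoff: float) -> ConfusionMetrics:
    """2x2 table at a cutoff (positive when prob >= cutoff)."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    probs = np.asarray(probs, dtype=float)
    labels = _check_labels(labels)
    pred = probs >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return ConfusionMetrics(float(cutoff), tp, fp, tn, fn)


def wilcoxon_rank_sum(probs_case, probs_control) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact permutation enumeration when n1 + n0 <= 20 (tie-safe);
    otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(probs_case, dtype=float)
    yv = np.asarray(probs_control, dtype=float)
    if x.size == 0 or yv.size == 0:
        raise ValueError("both groups must be nonempty")
    if x.size + yv.size <= 20:
        res = stats.permutation_test(
            (x, yv),
            lambda a, b, axis=-1: stats.mannwhitneyu(
                a, b, alternative="two-sided", axis=axis).statistic,
            permutation_type="independent", alternative="greater",
            n_resamples=np.inf)
        u = float(stats.mannwhitneyu(x, yv, alternative="two-sided").statistic)
        # two-sided p over the U distribution: double the smaller tail of
        # the exact null, capped at 1 (U is symmetric about n1 n0 / 2)
        null = np.asarray(res.null_distribution)
        mu = x.size * yv.size / 2.0
        tail = min(float(np.mean(null >= mu + abs(u - mu) - 1e-12)),
                   float(np.mean(null <= mu - abs(u - mu) + 1e-12)))
        p = min(1.0, 2.0 * tail)
        return {"U": u, "p_value": p, "method": "exact"}
    res = stats.mannwhitneyu(x, yv, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return {"U": float(res.statistic), "p_value": float(res.pvalue),
            "method": "asymptotic"}


def validation_report(probs, labels, sample_ids=None,
                      cutoff: float | str = "youden") -> dict:
    """Full evaluation: ROC/AUC, operating point, confusion metrics, rank-sum."""
    probs = np.asarray(probs, dtype=float)
    labels = _check_labels(labels)
    roc = roc_curve(probs, labels)
    if cutoff == "youden":
        yj = youden_cutoff(roc)
        cut = yj["cutoff"]
    else:
        cut = float(cutoff)
        yj = {"cutoff": cut, "J": None}
    cm = confusion_metrics(probs, labels, cut)
    wrs = wilcoxon_rank_sum(probs[labels == 1], probs[labels == 0])
    report = {
        "auc": round(roc.auc, 3),
        "youden": yj,
        "confusion": cm.as_dict(),
        "percent": {
            "sensitivity": round(100 * cm.sensitivity),
            "specificity": round(100 * cm.specificity),
            "ppv": None if cm.ppv is None else round(100 * cm.ppv),
            "npv": None if cm.npv is None else round(100 * cm.npv),
            "accuracy": round(100 * cm.accuracy),
        },
        "wilcoxon": wrs,
        "probabilities": probs.tolist(),
        "labels": labels.tolist(),
    }
    if sample_ids is not None:
        report["sample_ids"] = list(sample_ids)
    return report
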
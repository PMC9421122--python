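"""Stratified cross-validation, classification metrics, and paired comparisons.

One fold plan is built per experiment and shared by every arm, so paired
per-fold differences against the baseline arm are meaningful. Metrics per
fold: accuracy, sensitivity, specificity at ~90% sensitivity, ROC AUC, PR AUC
(average precision), F1 on the abnormal class, and the confusion matrix.
Arms are compared to the baseline by the 95% paired t-interval of the
per-fold mean difference; an interval excluding zero is called significant.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold

METRICS = ("accuracy", "sensitivity", "specificity_at_90sens", "roc_auc", "pr_auc", "f1")


@dataclass
class FoldPlan:
    """k train/test splits over record ids, stratified by class."""

    k: int
    folds: list  # list of (train_ids, test_ids) tuples of lists
    seed: int

    def plan_hash(self) -> str:
        payload = json.dumps([[list(tr), list(te)] for tr, te in self.folds])
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stratified_folds(record_ids, labels, k: int, seed: int = 0) -> FoldPlan:
    """Stratified k-fold partition, deterministic for a fixed seed.

    Test folds partition the dataset; each fold's class proportion is within
    one sample of the global proportion. Raises if a class has fewer than k
    members.
    """
    record_ids = list(record_ids)
    y = np.asarray(labels)
    if len(record_ids) != y.size:
        raise ValueError("record_ids and labels disagree in length")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs at least k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**32 - 1))
    folds = []
    ids = np.asarray(record_ids, dtype=object)
    for train_idx, test_idx in skf.split(np.zeros(y.size), y):
        folds.append((list(ids[train_idx]), list(ids[test_idx])))
    return FoldPlan(k=k, folds=folds, seed=int(seed))


def roc_pr_curves(scores, labels):
    """ROC and PR curves with their AUCs.

    ROC AUC is the trapezoidal area over all thresholds (equivalently the
    pairwise concordance statistic); PR AUC is average precision (the standard
    step interpolation).
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(y, s)
    precision, recall, _ = precision_recall_curve(y, s)
    return {
        "roc": (fpr, tpr),
        "pr": (recall, precision),
        "roc_auc": float(roc_auc_score(y, s)),
        "pr_auc": float(average_precision_score(y, s)),
    }


def specificity_at_sensitivity(scores, labels, target: float = 0.90):
    """Specificity at the loosest threshold whose sensitivity >= target.

    Operating points are score >= threshold over the distinct scores (plus the
    all-negative point); among points with sensitivity >= target, the largest
    threshold — the smallest sensitivity still meeting the target — is chosen,
    without interpolation.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    best = None
    for thr in np.unique(s)[::-1]:  # descending: loosest qualifying cutoff first
        pred = s >= thr
        sens = float((pred & (y == 1)).sum()) / n_pos
        if sens >= target:
            spec = float((~pred & (y == 0)).sum()) / n_neg
            best = (spec, float(thr))
            break
    if best is None:  # unreachable for finite scores: thr=min gives sens 1
        raise ValueError("target sensitivity unreachable")
    return best


def confusion_f1(scores, labels, threshold: float = 0.5):
    """Confusion matrix, accuracy, and F1 on the abnormal (positive) class.

    Zero-denominator F1 (no predicted or true positives) is defined as 0.
    """
    y = np.asarray(labels)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    cm = confusion_matrix(y, pred, labels=[0, 1])
    tn, fp, fn, tp = cm.ravel()
    accuracy = float(tp + tn) / max(cm.sum(), 1)
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return {"confusion": cm, "accuracy": accuracy, "f1": float(f1)}


def fold_metrics(scores, labels, threshold: float = 0.5, sens_target: float = 0.90) -> dict:
    """All per-fold metrics from one test fold's scores."""
    curves = roc_pr_curves(scores, labels)
    cf = confusion_f1(scores, labels, threshold)
    spec90, thr90 = specificity_at_sensitivity(scores, labels, sens_target)
    tn, fp, fn, tp = cf["confusion"].ravel()
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    return {
        "accuracy": cf["accuracy"],
        "sensitivity": float(sensitivity),
        "specificity_at_90sens": float(spec90),
        "threshold_at_90sens": float(thr90),
        "roc_auc": curves["roc_auc"],
        "pr_auc": curves["pr_auc"],
        "f1": cf["f1"],
        "confusion": cf["confusion"].tolist(),
    }


def mean_ci(values, confidence: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Mean and t-interval across folds; degenerate sd gives a point interval."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two folds")
    m = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        return m, (m, m)
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, v.size - 1))
    half = tcrit * sd / np.sqrt(v.size)
    return m, (m - half, m + half)


def paired_mean_difference_ci(
    arm_metric_by_fold, baseline_metric_by_fold, confidence: float = 0.95
) -> dict:
    """Paired per-fold differences with a 95% t-interval and the CI-zero call."""
    a = np.asarray(arm_metric_by_fold, dtype=float)
    b = np.asarray(baseline_metric_by_fold, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fold counts must match")
    diff = a - b
    m, (lo, hi) = mean_ci(diff, confidence)
    if lo > 0:
        call = "improvement"
    elif hi < 0:
        call = "worsening"
    else:
        call = "no difference"
    return {"mean_difference": m, "ci": (lo, hi), "call": call}


@dataclass
class ArmResult:
    """Per-fold metrics and across-fold summaries for one augmentation arm."""

    arm: str
    per_fold: list = field(default_factory=list)  # list of fold_metrics dicts
    fold_plan_hash: str = ""
    model_hash: str = ""
    fold_scores: list = field(default_factory=list, repr=False)  # (scores, labels) per fold

    def metric_values(self, metric: str) -> list[float]:
        return [fold[metric] for fold in self.per_fold]

    def summary(self) -> dict:
        out = {}
        for metric in METRICS:
            m, ci = mean_ci(self.metric_values(metric))
            out[metric] = {"mean": m, "ci": ci}
        return out


def compare_to_baseline(arm: ArmResult, baseline: ArmResult) -> dict:
    """Per-metric paired mean-difference CIs of an arm against the baseline."""
    if arm.fold_plan_hash != baseline.fold_plan_hash:
        raise ValueError("arms were evaluated under different fold plans")
    return {
        metric: paired_mean_difference_ci(
            arm.metric_values(metric), baseline.metric_values(metric)
        )
        for metric in METRICS
    }
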
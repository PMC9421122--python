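"""Cross-validation machinery: stratification, AUC oracles, the fixed-
sensitivity operating point, and paired confidence intervals."""

import numpy as np
import pytest

from pcgbench.evaluate import (
    ArmResult,
    compare_to_baseline,
    confusion_f1,
    fold_metrics,
    mean_ci,
    paired_mean_difference_ci,
    roc_pr_curves,
    specificity_at_sensitivity,
    stratified_folds,
)


def test_stratified_folds_exact_proportions():
    ids = [f"r{i}" for i in range(20)]
    labels = [0] * 15 + [1] * 5
    plan = stratified_folds(ids, labels, k=5, seed=1)
    label_of = dict(zip(ids, labels))
    all_test = []
    for train, test in plan.folds:
        assert sorted(train + test) == sorted(ids)
        assert sum(label_of[i] for i in test) == 1  # one abnormal per test fold
        assert len(test) == 4
        all_test.extend(test)
    assert sorted(all_test) == sorted(ids)  # test folds partition the data


def test_stratified_folds_determinism():
    ids = [f"r{i}" for i in range(30)]
    labels = ([0] * 24) + ([1] * 6)
    a = stratified_folds(ids, labels, 3, seed=5)
    b = stratified_folds(ids, labels, 3, seed=5)
    c = stratified_folds(ids, labels, 3, seed=6)
    assert a.plan_hash() == b.plan_hash()
    assert a.plan_hash() != c.plan_hash()
    with pytest.raises(ValueError):
        stratified_folds(ids, labels, 7, seed=0)  # minority class smaller than k


def _concordance_oracle(scores, labels):
    """Brute force over all (positive, negative) pairs: concordant + half ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def test_roc_auc_examples():
    perfect = roc_pr_curves([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
    assert perfect["roc_auc"] == 1.0
    assert perfect["pr_auc"] == 1.0
    mixed = roc_pr_curves([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0])
    assert mixed["roc_auc"] == pytest.approx(0.75)
    anti = roc_pr_curves([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1])
    assert anti["roc_auc"] == 0.0
    with pytest.raises(ValueError):
        roc_pr_curves([0.5, 0.6], [1, 1])


def test_roc_auc_equals_concordance_on_random_sets():
    rng = np.random.default_rng(17)
    for _ in range(100):
        n = int(rng.integers(6, 25))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 2)  # rounding forces score ties
        auc = roc_pr_curves(scores, labels)["roc_auc"]
        assert auc == pytest.approx(_concordance_oracle(scores, labels), abs=1e-12)


def _spec_at_sens_oracle(scores, labels, target):
    best = None
    for thr in sorted(set(scores), reverse=True):
        pred = np.asarray(scores) >= thr
        y = np.asarray(labels)
        sens = (pred & (y == 1)).sum() / (y == 1).sum()
        spec = (~pred & (y == 0)).sum() / (y == 0).sum()
        if sens >= target and best is None:
            best = spec
    return best


def test_specificity_at_sensitivity():
    spec, thr = specificity_at_sensitivity([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 0.90)
    assert spec == 1.0 and 0.2 < thr <= 0.8
    spec, _ = specificity_at_sensitivity([0.5] * 6, [0, 0, 0, 0, 1, 1], 0.90)
    assert spec == 0.0  # all-identical scores: only (sens 1, spec 0) qualifies
    rng = np.random.default_rng(3)
    for _ in range(50):
        scores = np.round(rng.random(10), 1)
        labels = rng.integers(0, 2, 10)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        got, _ = specificity_at_sensitivity(scores, labels, 0.90)
        assert got == pytest.approx(_spec_at_sens_oracle(scores, labels, 0.90))


def test_confusion_f1_examples():
    out = confusion_f1([0.1, 0.9], [0, 1])
    assert out["f1"] == 1.0 and out["accuracy"] == 1.0
    assert out["confusion"][0][1] == 0 and out["confusion"][1][0] == 0
    # TP=8 FP=2 FN=2 TN=8 -> precision = recall = F1 = 0.8
    scores = [0.9] * 8 + [0.9] * 2 + [0.1] * 2 + [0.1] * 8
    labels = [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8
    out = confusion_f1(scores, labels)
    assert out["f1"] == pytest.approx(0.8)
    assert out["accuracy"] == pytest.approx(0.8)
    # no predicted positives: F1 defined as 0
    out = confusion_f1([0.1, 0.2, 0.3], [0, 1, 1])
    assert out["f1"] == 0.0


def test_paired_ci_examples():
    same = paired_mean_difference_ci([0.8, 0.9, 0.85], [0.8, 0.9, 0.85])
    assert same["mean_difference"] == 0.0 and same["ci"] == (0.0, 0.0)
    assert same["call"] == "no difference"
    const = paired_mean_difference_ci([0.8, 0.9, 0.85], [0.75, 0.85, 0.80])
    assert const["ci"] == pytest.approx((0.05, 0.05))
    assert const["call"] == "improvement"
    # hand-computed t-interval: mean 0.03, sd 0.0158, t_(0.975,4) = 2.776
    diffs = [0.01, 0.03, 0.02, 0.04, 0.05]
    out = paired_mean_difference_ci(diffs, [0.0] * 5)
    sd = np.std(diffs, ddof=1)
    half = 2.7764451 * sd / np.sqrt(5)
    assert out["mean_difference"] == pytest.approx(0.03)
    assert out["ci"] == pytest.approx((0.03 - half, 0.03 + half), abs=1e-6)
    with pytest.raises(ValueError):
        paired_mean_difference_ci([0.1], [0.2])


def test_fold_metrics_bounded():
    rng = np.random.default_rng(2)
    scores = rng.random(40)
    labels = rng.integers(0, 2, 40)
    labels[:2] = [0, 1]
    m = fold_metrics(scores, labels)
    for key in ("accuracy", "sensitivity", "specificity_at_90sens", "roc_auc", "pr_auc", "f1"):
        assert 0.0 <= m[key] <= 1.0
    assert np.sum(m["confusion"]) == 40


def test_compare_requires_same_fold_plan():
    a = ArmResult(arm="1", per_fold=[], fold_plan_hash="x")
    b = ArmResult(arm="0", per_fold=[], fold_plan_hash="y")
    with pytest.raises(ValueError):
        compare_to_baseline(a, b)


def test_mean_ci_degenerate_sd():
    m, ci = mean_ci([0.5, 0.5, 0.5])
    assert (m, ci) == (0.5, (0.5, 0.5))
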
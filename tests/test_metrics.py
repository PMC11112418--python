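"""Metric correctness against brute-force oracles and worked examples."""

import numpy as np
import pytest

from tganet import (MetricSet, accuracy, auc_ovr, confusion,
                    precision_recall_f1, summarize_cv)


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def brute_counts(yt, yp, c):
    tp = sum(1 for t, p in zip(yt, yp) if t == c and p == c)
    fp = sum(1 for t, p in zip(yt, yp) if t != c and p == c)
    fn = sum(1 for t, p in zip(yt, yp) if t == c and p != c)
    tn = len(yt) - tp - fp - fn
    return tp, fp, fn, tn


def brute_auc_binary(scores, labels):
    """Pairwise enumeration of positive-negative score comparisons."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------

def test_confusion_hand_tally():
    c = confusion([0, 0, 1, 1], [0, 1, 1, 1], 2)
    assert (c.tp[1], c.fp[1], c.fn[1], c.tn[1]) == (2, 1, 0, 1)
    assert c.n_total == 4 and c.n_correct == 3
    assert accuracy(c) == 0.75


def test_accuracy_ratio():
    c = confusion([0] * 9 + [1] * 3, [0] * 9 + [0] * 3, 2)
    assert accuracy(c) == 9 / 12 == 0.75


def test_precision_recall_f1_single_class():
    """TP=3, FP=1, FN=2 -> P=0.75, R=0.6, F1=2*0.75*0.6/1.35."""
    from tganet.metrics import ConfusionCounts
    counts = ConfusionCounts(tp=np.array([3]), fp=np.array([1]), fn=np.array([2]),
                             tn=np.array([0]), n_total=6, n_correct=3)
    p, r, f1 = precision_recall_f1(counts)
    assert p == 0.75 and r == 0.6
    assert f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35, abs=1e-12)
    assert f1 == pytest.approx(0.6667, abs=5e-5)


def test_auc_worked_example():
    """Scores [0.1,0.4,0.35,0.8], labels [0,0,1,1] -> AUC 0.75."""
    scores = np.array([0.1, 0.4, 0.35, 0.8])
    probs = np.stack([1 - scores, scores], axis=1)
    assert auc_ovr([0, 0, 1, 1], probs) == 0.75
    assert brute_auc_binary(scores, [0, 0, 1, 1]) == 0.75


def test_auc_degenerate_conventions():
    perfect = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9]])
    assert auc_ovr([0, 0, 1], perfect) == 1.0
    ties = np.full((4, 2), 0.5)
    assert auc_ovr([0, 1, 0, 1], ties) == 0.5


def test_perfect_prediction_all_ones():
    y = [0, 1, 2, 1, 0, 2]
    c = confusion(y, y, 3)
    assert (c.fp == 0).all() and (c.fn == 0).all()
    p, r, f1 = precision_recall_f1(c)
    assert p == r == f1 == 1.0


def test_absent_class_contributes_zero():
    # class 2 never true and never predicted -> P=R=F1=0 for it (macro pulls down)
    c = confusion([0, 1, 0, 1], [0, 1, 0, 1], 3)
    p, r, f1 = precision_recall_f1(c)
    assert p == pytest.approx(2 / 3) and r == pytest.approx(2 / 3)


def test_validation_errors():
    with pytest.raises(ValueError):
        confusion([], [], 2)
    with pytest.raises(ValueError):
        confusion([0, 3], [0, 1], 2)
    with pytest.raises(ValueError):
        auc_ovr([0, 0], np.array([[0.6, 0.4], [0.7, 0.3]]))  # no positives, binary
    with pytest.raises(ValueError):
        summarize_cv([MetricSet(1, 1, 1, 1, 1)])


# ---------------------------------------------------------------------------
# randomized oracle equivalence
# ---------------------------------------------------------------------------

def test_oracle_equivalence_random_cases():
    """All metrics match brute-force tallies/pair enumeration on 1000 random
    small problems to 1e-12."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n = int(rng.integers(3, 15))
        k = int(rng.integers(2, 5))
        yt = rng.integers(0, k, n)
        yp = rng.integers(0, k, n)
        c = confusion(yt, yp, k)
        ps, rs, f1s = [], [], []
        for cls in range(k):
            tp, fp, fn, tn = brute_counts(yt, yp, cls)
            assert (c.tp[cls], c.fp[cls], c.fn[cls], c.tn[cls]) == (tp, fp, fn, tn)
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            ps.append(p)
            rs.append(r)
            f1s.append(2 * p * r / (p + r) if p + r else 0.0)
        p, r, f1 = precision_recall_f1(c)
        assert p == pytest.approx(np.mean(ps), abs=1e-12)
        assert r == pytest.approx(np.mean(rs), abs=1e-12)
        assert f1 == pytest.approx(np.mean(f1s), abs=1e-12)
        assert accuracy(c) == pytest.approx(np.mean(yt == yp), abs=1e-12)


def test_auc_matches_pair_enumeration():
    rng = np.random.default_rng(7)
    for _ in range(300):
        n = int(rng.integers(4, 20))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        scores = np.round(rng.random(n), 2)     # rounded to force ties
        probs = np.stack([1 - scores, scores], axis=1)
        assert auc_ovr(labels, probs) == pytest.approx(
            brute_auc_binary(scores, labels), abs=1e-12)


def test_auc_matches_sklearn_multiclass():
    sklearn = pytest.importorskip("sklearn")
    from sklearn.metrics import roc_auc_score
    rng = np.random.default_rng(11)
    for _ in range(50):
        n, k = int(rng.integers(12, 30)), 3
        y = rng.integers(0, k, n)
        if len(np.unique(y)) < k:
            continue
        p = rng.dirichlet(np.ones(k), n)
        assert auc_ovr(y, p) == pytest.approx(
            roc_auc_score(y, p, multi_class="ovr", average="macro"), abs=1e-10)


def test_permutation_invariance():
    rng = np.random.default_rng(5)
    y = rng.integers(0, 3, 30)
    yp = rng.integers(0, 3, 30)
    p = rng.dirichlet(np.ones(3), 30)
    perm = rng.permutation(30)
    c1, c2 = confusion(y, yp, 3), confusion(y[perm], yp[perm], 3)
    assert accuracy(c1) == accuracy(c2)
    assert precision_recall_f1(c1) == precision_recall_f1(c2)
    assert auc_ovr(y, p) == pytest.approx(auc_ovr(y[perm], p[perm]), abs=1e-12)


def test_summarize_cv_closed_form():
    folds = [MetricSet(0.8, 0.8, 0.8, 0.8, 0.8), MetricSet(1.0, 1.0, 1.0, 1.0, 1.0)]
    s = summarize_cv(folds)
    assert s["acc"][0] == pytest.approx(0.9)
    assert s["acc"][1] == pytest.approx(np.sqrt(((0.8 - 0.9) ** 2 + (1.0 - 0.9) ** 2) / 1))
    assert s["acc"][1] == pytest.approx(0.1414, abs=5e-5)
    same = [MetricSet(0.9, 0.9, 0.9, 0.9, 0.9)] * 5
    s2 = summarize_cv(same)
    assert s2["f1"] == (pytest.approx(0.9), pytest.approx(0.0))
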
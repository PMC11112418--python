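"""Classification metrics: accuracy, macro precision/recall/F1, one-vs-rest
AUC, and mean ± sd summarization across cross-validation folds.

Per class c (one-vs-rest): P_c = TP/(TP+FP), R_c = TP/(TP+FN),
F1_c = 2 P_c R_c / (P_c + R_c), with the convention that a zero denominator
yields 0.  Macro metrics are unweighted means over classes (a weighted
variant is available).  AUC is computed per class as the Mann-Whitney
pairwise-ranking probability (ties count 0.5) — exactly the area under the
ROC curve — and macro-averaged over classes with both outcomes present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class one-vs-rest tallies plus total and correct counts."""
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    n_total: int
    n_correct: int


@dataclass(frozen=True)
class MetricSet:
    acc: float
    precision: float
    recall: float
    f1: float
    auc: float


def confusion(y_true, y_pred, n_classes: int) -> ConfusionCounts:
    """One-vs-rest confusion tallies for integer labels in [0, n_classes)."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.size == 0:
        raise ValueError("empty label arrays")
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if yt.min() < 0 or yt.max() >= n_classes or yp.min() < 0 or yp.max() >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes})")
    n = yt.size
    tp = np.zeros(n_classes, dtype=int)
    fp = np.zeros(n_classes, dtype=int)
    fn = np.zeros(n_classes, dtype=int)
    for c in range(n_classes):
        tp[c] = int(((yt == c) & (yp == c)).sum())
        fp[c] = int(((yt != c) & (yp == c)).sum())
        fn[c] = int(((yt == c) & (yp != c)).sum())
    tn = n - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn,
                           n_total=n, n_correct=int(tp.sum()))


def accuracy(counts: ConfusionCounts) -> float:
    """Fraction of correctly predicted samples, N_c / N_t."""
    if counts.n_total == 0:
        raise ValueError("no samples")
    return counts.n_correct / counts.n_total


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=den > 0)
    return out


def precision_recall_f1(counts: ConfusionCounts,
                        averaging: str = "macro") -> tuple[float, float, float]:
    """Per-class precision/recall/F1 reduced by macro (default) or weighted
    averaging; zero denominators yield 0."""
    p = _safe_div(counts.tp, counts.tp + counts.fp)
    r = _safe_div(counts.tp, counts.tp + counts.fn)
    f1 = _safe_div(2.0 * p * r, p + r)
    if averaging == "macro":
        w = np.full(p.size, 1.0 / p.size)
    elif averaging == "weighted":
        support = counts.tp + counts.fn
        w = support / support.sum()
    else:
        raise ValueError(f"unknown averaging {averaging!r}")
    return float(p @ w), float(r @ w), float(f1 @ w)


def _binary_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Mann-Whitney U probability: P(score_pos > score_neg) + 0.5 P(tie)."""
    # rank-based evaluation: O((n_p + n_n) log) instead of pair enumeration
    scores = np.concatenate([pos_scores, neg_scores])
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(scores.size, dtype=float)
    ranks[order] = np.arange(1, scores.size + 1)
    # average ranks over ties
    sorted_scores = scores[order]
    i = 0
    while i < scores.size:
        j = i
        while j + 1 < scores.size and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        if j > i:
            ranks[order[i:j + 1]] = 0.5 * (i + 1 + j + 1)
        i = j + 1
    n_pos = pos_scores.size
    n_neg = neg_scores.size
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_ovr(y_true, probs) -> float:
    """Macro one-vs-rest AUC from class-probability rows.

    Binary inputs with a degenerate class raise; in the multiclass (macro)
    case classes missing a positive or negative sample are skipped with a
    warning.
    """
    yt = np.asarray(y_true, dtype=int)
    p = np.asarray(probs, dtype=float)
    if p.ndim != 2 or p.shape[0] != yt.size:
        raise ValueError("probs must be (n_samples, n_classes)")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-5):
        raise ValueError("probability rows must sum to 1")
    n_classes = p.shape[1]
    aucs = []
    for c in range(n_classes):
        pos = p[yt == c, c]
        neg = p[yt != c, c]
        if pos.size == 0 or neg.size == 0:
            if n_classes == 2:
                raise ValueError(f"class {c} has no positives or no negatives")
            warnings.warn(f"class {c} lacks positives or negatives; skipped "
                          f"from macro AUC", stacklevel=2)
            continue
        aucs.append(_binary_auc(pos, neg))
        if n_classes == 2:
            break   # the two one-vs-rest problems are mirror images
    if not aucs:
        raise ValueError("no class had both positives and negatives")
    return float(np.mean(aucs))


def evaluate_predictions(y_true, y_pred, probs, n_classes: int) -> MetricSet:
    """All metrics for one validation fold."""
    counts = confusion(y_true, y_pred, n_classes)
    p, r, f1 = precision_recall_f1(counts)
    return MetricSet(acc=accuracy(counts), precision=p, recall=r, f1=f1,
                     auc=auc_ovr(y_true, probs))


def summarize_cv(per_fold: list[MetricSet]) -> dict[str, tuple[float, float]]:
    """Mean and sample standard deviation (n-1) of each metric over folds."""
    if len(per_fold) < 2:
        raise ValueError("need at least 2 folds to summarize")
    out = {}
    for f in fields(MetricSet):
        vals = np.array([getattr(m, f.name) for m in per_fold], dtype=float)
        out[f.name] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out
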
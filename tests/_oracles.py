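"""Brute-force metric oracles, independent of the package implementation.

Everything here is computed from first principles with explicit loops over
the confusion matrix or over score pairs, so the tests can compare the
package's metric outputs against an implementation that shares no code
path with them.
"""

from __future__ import annotations

import numpy as np


def confusion_counts(y_true, y_pred, labels):
    cm = {(a, b): 0 for a in labels for b in labels}
    for t, p in zip(y_true, y_pred):
        cm[(t, p)] += 1
    return cm


def brute_accuracy(y_true, y_pred) -> float:
    return sum(int(t == p) for t, p in zip(y_true, y_pred)) / len(y_true) * 100.0


def brute_weighted_recall(y_true, y_pred, labels) -> float:
    n = len(y_true)
    total = 0.0
    for c in labels:
        support = sum(int(t == c) for t in y_true)
        if support == 0:
            continue
        tp = sum(int(t == c and p == c) for t, p in zip(y_true, y_pred))
        total += (support / n) * (tp / support)
    return total * 100.0


def brute_weighted_precision(y_true, y_pred, labels) -> float:
    n = len(y_true)
    total = 0.0
    for c in labels:
        support = sum(int(t == c) for t in y_true)
        if support == 0:
            continue
        predicted = sum(int(p == c) for p in y_pred)
        tp = sum(int(t == c and p == c) for t, p in zip(y_true, y_pred))
        prec = tp / predicted if predicted else 0.0
        total += (support / n) * prec
    return total * 100.0


def brute_weighted_f1(y_true, y_pred, labels) -> float:
    n = len(y_true)
    total = 0.0
    for c in labels:
        support = sum(int(t == c) for t in y_true)
        if support == 0:
            continue
        predicted = sum(int(p == c) for p in y_pred)
        tp = sum(int(t == c and p == c) for t, p in zip(y_true, y_pred))
        prec = tp / predicted if predicted else 0.0
        rec = tp / support
        f = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
        total += (support / n) * f
    return total


def brute_mcc(y_true, y_pred, labels) -> float:
    """Generalized (multiclass) Matthews correlation from raw sums."""
    n = len(y_true)
    c = sum(int(t == p) for t, p in zip(y_true, y_pred))
    t_k = {k: sum(int(t == k) for t in y_true) for k in labels}
    p_k = {k: sum(int(p == k) for p in y_pred) for k in labels}
    cov = c * n - sum(p_k[k] * t_k[k] for k in labels)
    denom_p = n * n - sum(p_k[k] ** 2 for k in labels)
    denom_t = n * n - sum(t_k[k] ** 2 for k in labels)
    if denom_p == 0 or denom_t == 0:
        return 0.0
    return cov / np.sqrt(float(denom_p) * float(denom_t))


def mann_whitney_auc(y_true, scores) -> float:
    """ROC-AUC as the normalized Mann-Whitney U statistic."""
    pos = [s for t, s in zip(y_true, scores) if t == 1]
    neg = [s for t, s in zip(y_true, scores) if t == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def ovr_weighted_auc(y_true, score_matrix) -> float:
    """One-vs-rest ROC-AUC, weighted by class support."""
    y_true = np.asarray(y_true)
    n = len(y_true)
    total = 0.0
    for c in range(score_matrix.shape[1]):
        support = int(np.sum(y_true == c))
        if support in (0, n):
            continue
        binary = (y_true == c).astype(int)
        total += (support / n) * mann_whitney_auc(binary, score_matrix[:, c])
    return total
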
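"""Independent naive-reference implementations used only by the tests.

Everything here is deliberately written with explicit scalar loops and
exhaustive enumeration — no shared code with the package — so the
vectorized implementations are checked against a genuinely independent
route.
"""

from __future__ import annotations

import numpy as np


def naive_objective(A, X, Y, Sd, Se, mu, lam):
    """Term-by-term scalar expansion of the regularized objective."""
    n, m = A.shape
    k = X.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(m):
            pred = sum(X[r, i] * Y[r, j] for r in range(k))
            total += (A[i, j] - pred) ** 2
    for r in range(k):
        for i in range(n):
            total += mu * X[r, i] ** 2
        for j in range(m):
            total += mu * Y[r, j] ** 2
    for i in range(n):
        for j in range(n):
            gram = sum(X[r, i] * X[r, j] for r in range(X.shape[0]))
            total += lam * (gram - Sd[i, j]) ** 2
    for i in range(m):
        for j in range(m):
            gram = sum(Y[r, i] * Y[r, j] for r in range(Y.shape[0]))
            total += lam * (gram - Se[i, j]) ** 2
    return total


def naive_update_x(A, X, Y, Sd, mu, lam, eps):
    """Scalar double loop over (r, i) evaluating the X update rule."""
    k, n = X.shape
    m = A.shape[1]
    out = np.zeros_like(X)
    for r in range(k):
        for i in range(n):
            numer = sum(Y[r, j] * A[i, j] for j in range(m))
            numer += 2.0 * lam * sum(X[r, l] * Sd[l, i] for l in range(n))
            denom = sum(
                sum(Y[r, j] * Y[s, j] for j in range(m)) * X[s, i] for s in range(k)
            )
            denom += mu * X[r, i]
            denom += 2.0 * lam * sum(
                sum(X[r, l] * X[s, l] for l in range(n)) * X[s, i] for s in range(k)
            )
            out[r, i] = X[r, i] * numer / (denom + eps)
    return out


def naive_update_y(A, X, Y, Se, mu, lam, eps):
    """Scalar double loop over (r, j) evaluating the Y update rule."""
    k, m = Y.shape
    n = A.shape[0]
    out = np.zeros_like(Y)
    for r in range(k):
        for j in range(m):
            numer = sum(X[r, i] * A[i, j] for i in range(n))
            numer += 2.0 * lam * sum(Y[r, l] * Se[l, j] for l in range(m))
            denom = sum(
                sum(X[r, i] * X[s, i] for i in range(n)) * Y[s, j] for s in range(k)
            )
            denom += mu * Y[r, j]
            denom += 2.0 * lam * sum(
                sum(Y[r, l] * Y[s, l] for l in range(m)) * Y[s, j] for s in range(k)
            )
            out[r, j] = Y[r, j] * numer / (denom + eps)
    return out


def naive_matmul(X, Y):
    """Scalar triple-loop product X.T @ Y."""
    k, n = X.shape
    m = Y.shape[1]
    out = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            out[i, j] = sum(X[r, i] * Y[r, j] for r in range(k))
    return out


def pairs_auc(scores, labels):
    """All-pairs Mann-Whitney count: ties contribute half credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def enum_aupr(scores, labels):
    """Exhaustive threshold enumeration of the PR step curve area."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    thresholds = sorted(set(scores), reverse=True)
    area = 0.0
    prev_recall = 0.0
    for t in thresholds:
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        precision = tp / int(pred.sum())
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def confusion_tally(scores, labels, threshold):
    """Direct enumeration of TP/FP/TN/FN at a fixed threshold."""
    tp = fp = tn = fn = 0
    for s, y in zip(scores, labels):
        if s >= threshold:
            if y == 1:
                tp += 1
            else:
                fp += 1
        else:
            if y == 1:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn


def brute_rank(score_row, assoc_row, disease_ids, top_k):
    """Brute-force sort-and-filter candidate ranking for one drug."""
    pool = [
        (disease_ids[j], float(score_row[j]))
        for j in range(len(disease_ids))
        if assoc_row[j] == 0
    ]
    pool.sort(key=lambda t: (-t[1], t[0]))
    return pool[:top_k]
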
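"""Deliberately naive reference implementations used as independent oracles.

Everything here is written as plain loops straight from the defining formulas
and stays independent of the package's vectorised code paths.
"""

import math


def naive_corr_dist(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return 1.0
    return 1.0 - sxy / math.sqrt(sxx * syy)


def naive_centers(X, assignment, K):
    m = len(X[0])
    centers = []
    for k in range(K):
        members = [X[i] for i in range(len(X)) if assignment[i] == k]
        centers.append([sum(row[j] for row in members) / len(members) for j in range(m)])
    return centers


def naive_qc_w(X, assignment, centers):
    total = 0.0
    for i, row in enumerate(X):
        total += naive_corr_dist(row, centers[assignment[i]])
    return total / len(X)


def naive_qc_b(centers):
    K = len(centers)
    total = 0.0
    for i in range(K - 1):
        for j in range(i + 1, K):
            total += naive_corr_dist(centers[i], centers[j])
    return 2.0 * total / (K * (K - 1))


def naive_qc_int(X, assignment):
    K = max(assignment) + 1
    N = len(X)
    centers = naive_centers(X, assignment, K)
    w = naive_qc_w(X, assignment, centers)
    b = naive_qc_b(centers)
    return K * (K - 1) * w * w / ((N - K) * b * b)


def naive_metrics(tp, fn, fp, tn):
    total = tp + fn + fp + tn
    ac = (tp + tn) / total
    pr = tp / (tp + fp) if tp + fp else 0.0
    rc = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * pr * rc / (pr + rc) if pr + rc else 0.0
    d = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(d) if d else 0.0
    return ac, pr, rc, f, mcc


def naive_auc(y_true, scores):
    pos = [s for y, s in zip(y_true, scores) if y == 1]
    neg = [s for y, s in zip(y_true, scores) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def trapezoid_centroid(a, b, c, d):
    """Mass center of a full-height trapezoid membership function."""
    area = 0.0
    moment = 0.0
    if b > a:  # rising ramp: centroid at a + 2/3 (b - a)
        area += (b - a) / 2
        moment += (b - a) / 2 * (a + 2 * (b - a) / 3)
    if c > b:  # plateau
        area += c - b
        moment += (c - b) * (b + c) / 2
    if d > c:  # falling ramp: centroid at c + 1/3 (d - c)
        area += (d - c) / 2
        moment += (d - c) / 2 * (c + (d - c) / 3)
    return moment / area
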
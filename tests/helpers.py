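"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain element-by-element loops or exhaustive
enumeration, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def loop_mse(y, yhat):
    return sum((p - t) ** 2 for t, p in zip(y, yhat)) / len(y)


def loop_mae(y, yhat):
    return sum(abs(p - t) for t, p in zip(y, yhat)) / len(y)


def loop_mre(y, yhat):
    return sum(abs(p - t) / t for t, p in zip(y, yhat)) / len(y)


def loop_customized(y, yhat, tau):
    total = 0.0
    for t, p in zip(y, yhat):
        if t >= tau and p >= tau:
            total += 0.0
        elif t >= tau and p < tau:
            total += abs(p - tau)
        else:
            total += abs(p - t)
    return total / len(y)


def enumerate_cutoffs(scores, prolonged, target):
    """All (cutoff, short_sens, prolonged_sens) triples at distinct operating points.

    Candidate cutoffs are every distinct score plus one value above the
    maximum (classify nothing prolonged) when that is still a probability.
    Returns the full table plus the best feasible operating point under the
    short-sensitivity constraint, or None when infeasible.
    """
    scores = list(map(float, scores))
    prolonged = list(map(bool, prolonged))
    cands = sorted(set(scores))
    above = math.nextafter(max(scores), math.inf)
    if above <= 1.0:
        cands.append(above)
    n_short = prolonged.count(False)
    n_long = prolonged.count(True)
    table = []
    for c in cands:
        tp = sum(1 for s, p in zip(scores, prolonged) if p and s >= c)
        tn = sum(1 for s, p in zip(scores, prolonged) if not p and s < c)
        table.append((c, tn / n_short, tp / n_long))
    feasible = [row for row in table if row[1] >= target]
    best = None
    if feasible:
        best_prolonged = max(row[2] for row in feasible)
        best = min(row for row in feasible if row[2] == best_prolonged)
    return table, best


def pair_count_auc(scores, labels):
    """AUC by exhaustive positive/negative pair counting, ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def step_ap(scores, labels):
    """Average precision as sum((R_k - R_{k-1}) * P_k) over distinct thresholds."""
    n_pos = sum(labels)
    thresholds = sorted(set(scores), reverse=True)
    ap, prev_recall = 0.0, 0.0
    for t in thresholds:
        tp = sum(1 for s, l in zip(scores, labels) if l and s >= t)
        fp = sum(1 for s, l in zip(scores, labels) if not l and s >= t)
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def random_pair(rng, max_n=50):
    """A random prediction pair with strictly positive truths (MRE-safe)."""
    n = int(rng.integers(1, max_n + 1))
    y = rng.uniform(0.1, 40.0, n)
    yhat = np.maximum(y + rng.normal(0, 5.0, n), 0.0)
    return y, yhat
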
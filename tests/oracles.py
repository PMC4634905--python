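"""Independent brute-force oracles used to verify the package implementations.

Everything here is written from the printed definitions with plain Python
loops — no shared code with the package internals — so agreement between the
two routes is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------- MLKNN ----


def brute_mlknn_scores(X, Y, Xq, k, s):
    """Direct evaluation of the MLKNN estimator equations with explicit loops.

    Neighbor ties are broken toward the lower training-row index; a training
    instance is never its own neighbor during count estimation.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=int)
    Xq = np.asarray(Xq, dtype=float)
    n, q = Y.shape

    def neighbors(x, exclude=None):
        cand = []
        for j in range(n):
            if j == exclude:
                continue
            d = sum((x[a] - X[j][a]) ** 2 for a in range(X.shape[1]))
            cand.append((d, j))
        cand.sort()
        return [j for _, j in cand[:k]]

    priors = [(s + sum(Y[i][l] for i in range(n))) / (s * 2 + n) for l in range(q)]

    C_train = np.zeros((n, q), dtype=int)
    for i in range(n):
        nb = neighbors(X[i], exclude=i)
        for l in range(q):
            C_train[i][l] = sum(Y[a][l] for a in nb)

    post_pos = np.zeros((q, k + 1))
    post_neg = np.zeros((q, k + 1))
    for l in range(q):
        c = [0] * (k + 1)
        cp = [0] * (k + 1)
        for i in range(n):
            if Y[i][l] == 1:
                c[C_train[i][l]] += 1
            else:
                cp[C_train[i][l]] += 1
        for j in range(k + 1):
            post_pos[l][j] = (s + c[j]) / (s * (k + 1) + sum(c))
            post_neg[l][j] = (s + cp[j]) / (s * (k + 1) + sum(cp))

    scores = np.zeros((Xq.shape[0], q))
    for t in range(Xq.shape[0]):
        nb = neighbors(Xq[t])
        for l in range(q):
            ct = sum(Y[a][l] for a in nb)
            num = priors[l] * post_pos[l][ct]
            den = num + (1 - priors[l]) * post_neg[l][ct]
            scores[t][l] = num / den
    return scores


def brute_knn(X_train, X_query, k, exclude_self=False):
    X_train = np.asarray(X_train, dtype=float)
    X_query = np.asarray(X_query, dtype=float)
    out = []
    for i, x in enumerate(X_query):
        cand = []
        for j in range(X_train.shape[0]):
            if exclude_self and j == i:
                continue
            d = float(np.sum((x - X_train[j]) ** 2))
            cand.append((d, j))
        cand.sort()
        out.append([j for _, j in cand[:k]])
    return np.array(out)


# -------------------------------------------------------------- metrics ----


def brute_aupr(scores, truth):
    """Step AUPR over distinct thresholds (tied scores enter together)."""
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth).ravel()
    n_pos = truth.sum()
    assert n_pos > 0
    area = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int((pred & (truth == 1)).sum())
        precision = tp / int(pred.sum())
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def brute_auc(scores, truth):
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth).ravel()
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    total = 0.0
    for p in pos:
        for ng in neg:
            if p > ng:
                total += 1.0
            elif p == ng:
                total += 0.5
    return total / (len(pos) * len(neg))


def _rank_max(s, l):
    return sum(1 for v in s if v >= s[l])


def _rank_avg(s, l):
    greater = sum(1 for v in s if v > s[l])
    ties = sum(1 for v in s if v == s[l])
    return greater + (ties + 1) / 2


def brute_ranking_metrics(S, Y):
    S = np.asarray(S, dtype=float)
    Y = np.asarray(Y, dtype=int)
    one_errors, coverages, rlosses, aps = [], [], [], []
    for s, y in zip(S, Y):
        rel = [l for l in range(len(y)) if y[l] == 1]
        if not rel:
            coverages.append(0.0)
            continue
        coverages.append(max(_rank_max(s, l) for l in rel) - 1)
        best = max(range(len(s)), key=lambda l: (s[l], -l))
        one_errors.append(0.0 if y[best] == 1 else 1.0)
        irr = [l for l in range(len(y)) if y[l] == 0]
        if irr:
            wrong = 0.0
            for a in rel:
                for b in irr:
                    if s[a] < s[b]:
                        wrong += 1.0
                    elif s[a] == s[b]:
                        wrong += 0.5
            rlosses.append(wrong / (len(rel) * len(irr)))
        terms = []
        for l in rel:
            r = _rank_avg(s, l)
            terms.append(sum(1 for m in rel if _rank_avg(s, m) <= r) / r)
        aps.append(sum(terms) / len(terms))
    mean = lambda xs: sum(xs) / len(xs) if xs else 0.0
    return mean(one_errors), mean(coverages), mean(rlosses), mean(aps)


def brute_hamming(P, Y):
    P = np.asarray(P, dtype=int)
    Y = np.asarray(Y, dtype=int)
    wrong = sum(int(P[i][l] != Y[i][l]) for i in range(P.shape[0]) for l in range(P.shape[1]))
    return wrong / (P.shape[0] * P.shape[1])


def brute_topn_recall(S, Y, n_top):
    S = np.asarray(S, dtype=float)
    Y = np.asarray(Y, dtype=int)
    per_drug = []
    for s, y in zip(S, Y):
        rel = {l for l in range(len(y)) if y[l] == 1}
        if not rel:
            per_drug.append(float("nan"))
            continue
        order = sorted(range(len(s)), key=lambda l: (-s[l], l))
        top = set(order[:n_top])
        per_drug.append(len(rel & top) / len(rel))
    defined = [r for r in per_drug if not math.isnan(r)]
    return per_drug, (sum(defined) / len(defined) if defined else float("nan"))


def brute_mi_bits(x, y):
    """Plug-in MI of two binary vectors from the 2x2 contingency table, in bits."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    n = len(x)
    total = 0.0
    for a in (0, 1):
        for b in (0, 1):
            nab = int(((x == a) & (y == b)).sum())
            if nab == 0:
                continue
            na = int((x == a).sum())
            nb = int((y == b).sum())
            total += (nab / n) * math.log2(nab * n / (na * nb))
    return total
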
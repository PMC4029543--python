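"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the library's own code paths: AUC by explicit
pair counting, average linkage by recomputing every cross-cluster mean from
the raw similarity matrix at every step, descriptors by dense double loops.
"""

from __future__ import annotations

import numpy as np


def auc_pair_counting(scores, labels) -> float:
    """Fraction of (positive, negative) pairs with score_pos > score_neg, ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels > 0]
    neg = scores[labels < 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def tanimoto_direct(a, b) -> float:
    sa = set(np.flatnonzero(a))
    sb = set(np.flatnonzero(b))
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)


def average_linkage_oracle(fingerprints) -> list[float]:
    """Merge heights by O(n^3) re-averaging of the leaf similarity matrix.

    Uses the same deterministic tie rule as the implementation (highest mean
    similarity first, ties by lexicographically smallest min-member-ID pair)
    so that heights are comparable merge by merge.
    """
    ids = list(fingerprints.entity_ids)
    dense = fingerprints.to_dense()
    n = len(ids)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            sim[i, j] = 1.0 if i == j else tanimoto_direct(dense[i], dense[j])
    clusters: list[list[int]] = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                cross = [sim[i, j] for i in clusters[a] for j in clusters[b]]
                s = float(np.mean(cross))
                tie = tuple(
                    sorted(
                        (
                            min(ids[i] for i in clusters[a]),
                            min(ids[i] for i in clusters[b]),
                        )
                    )
                )
                cand = (-s, tie, a, b)
                if best is None or cand < best:
                    best = cand
        s, _, a, b = -best[0], best[1], best[2], best[3]
        heights.append(s)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return heights


def clusters_at_threshold_oracle(fingerprints, threshold: float) -> set[frozenset[str]]:
    """Cluster memberships from a from-scratch run cut at ``threshold``."""
    ids = list(fingerprints.entity_ids)
    dense = fingerprints.to_dense()
    n = len(ids)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            sim[i, j] = 1.0 if i == j else tanimoto_direct(dense[i], dense[j])
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                cross = [sim[i, j] for i in clusters[a] for j in clusters[b]]
                s = float(np.mean(cross))
                tie = tuple(
                    sorted(
                        (
                            min(ids[i] for i in clusters[a]),
                            min(ids[i] for i in clusters[b]),
                        )
                    )
                )
                cand = (-s, tie, a, b)
                if best is None or cand < best:
                    best = cand
        s, _, a, b = -best[0], best[1], best[2], best[3]
        if s < threshold:
            break
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return {frozenset(ids[i] for i in c) for c in clusters}


def tensor_positions_double_loop(d, p) -> set[int]:
    d = np.asarray(d)
    p = np.asarray(p)
    N = len(p)
    out = set()
    for i in range(len(d)):
        for j in range(N):
            if d[i] == 1 and p[j] == 1:
                out.add(i * N + j)
    return out


def combined_positions_double_loop(d, p) -> set[int]:
    d = np.asarray(d)
    p = np.asarray(p)
    M, N = len(d), len(p)
    out = tensor_positions_double_loop(d, p)
    for i in range(M):
        if d[i] == 1:
            out.add(M * N + i)
    for j in range(N):
        if p[j] == 1:
            out.add(M * N + M + j)
    return out


def grid_minimum_2d(X, y, penalty, C, lo=-5.0, hi=5.0, step=1e-2) -> float:
    """Minimum objective of a 2-feature logistic problem on a dense weight grid."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.arange(lo, hi + step / 2, step)
    W1, W2 = np.meshgrid(w, w, indexing="ij")
    Z = X @ np.stack([W1.ravel(), W2.ravel()])
    loss = np.logaddexp(0.0, -(y[:, None] * Z)).sum(axis=0)
    if penalty == "L1":
        reg = np.abs(W1.ravel()) + np.abs(W2.ravel())
    else:
        reg = W1.ravel() ** 2 + W2.ravel() ** 2
    return float((reg + C * loss).min())
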
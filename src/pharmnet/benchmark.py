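"""Similarity-thresholded benchmark construction.

Gold-standard interaction sets contain clumps of nearly identical drugs from
shared lead series; splitting such twins across training and test folds makes
cross-validation trivially easy. To control this, drugs are clustered by the
Tanimoto (Jaccard) coefficient of their chemical fingerprints under average
linkage, the dendrogram is cut at a similarity threshold, one representative
per cluster is retained, and the interaction dataset is restricted to the
representatives. Sweeping the threshold from 0.2 to 1.0 in steps of 0.1
yields nine benchmarks of increasing chemical redundancy (proteins are kept
in full throughout).

Average linkage is implemented directly (Lance-Williams update on the
similarity matrix) so that merge ties — common with binary fingerprints —
break deterministically on the lexicographically smallest member-ID pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import InteractionDataset, ProfileMatrix

__all__ = [
    "Dendrogram",
    "BenchmarkSeries",
    "DEFAULT_THRESHOLDS",
    "tanimoto",
    "tanimoto_matrix",
    "average_linkage",
    "cut_and_select",
    "build_series",
]

DEFAULT_THRESHOLDS: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


def tanimoto(fp_a: Sequence[int], fp_b: Sequence[int]) -> float:
    """|A & B| / |A | B| over on-bit sets; 0.0 (with a warning) if both empty."""
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint lengths differ: {a.shape} vs {b.shape}")
    union = int(np.sum(a | b))
    if union == 0:
        warnings.warn("both fingerprints empty; Tanimoto defined as 0.0", stacklevel=2)
        return 0.0
    return float(np.sum(a & b)) / union


def tanimoto_matrix(fingerprints: ProfileMatrix) -> np.ndarray:
    """All-pairs Tanimoto similarity (dense, n x n)."""
    A = fingerprints.values.astype(np.int64)
    inter = np.asarray((A @ A.T).todense(), dtype=np.float64)
    sizes = np.asarray(A.sum(axis=1)).ravel().astype(np.float64)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    if np.any((sizes == 0)):
        warnings.warn("empty fingerprints present; their similarities are 0.0", stacklevel=2)
    np.fill_diagonal(sim, 1.0)
    return sim


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage merge history on similarity (distance = 1 - similarity).

    ``merges`` lists, in order, (members of cluster a, members of cluster b,
    merge similarity); similarities are non-increasing along the sequence
    (average linkage admits no inversions).
    """

    leaf_ids: tuple[str, ...]
    merges: tuple[tuple[tuple[str, ...], tuple[str, ...], float], ...]


def average_linkage(fingerprints: ProfileMatrix) -> Dendrogram:
    """Agglomerate by highest mean cross-pair Tanimoto similarity.

    Ties break on the lexicographically smallest (min member ID of a, min
    member ID of b) pair, so the merge order is deterministic.
    """
    ids = list(fingerprints.entity_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("average_linkage requires at least 2 entities")
    sim = tanimoto_matrix(fingerprints)

    # active clusters: key -> member row indices; mean similarities as dict-of-dict
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    minid = {i: ids[i] for i in range(n)}
    merges = []
    next_key = n
    simd = {
        i: {j: float(sim[i, j]) for j in range(n) if j != i} for i in range(n)
    }

    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b, s in simd[a].items():
                if b <= a:
                    continue
                tie_key = tuple(sorted((minid[a], minid[b])))
                cand = (-s, tie_key, a, b)
                if best is None or cand < best:
                    best = cand
        s_best, _, a, b = -best[0], best[1], best[2], best[3]
        members_a = tuple(sorted(ids[r] for r in clusters[a]))
        members_b = tuple(sorted(ids[r] for r in clusters[b]))
        merges.append((members_a, members_b, float(s_best)))
        # Lance-Williams: mean similarity is the size-weighted average
        na, nb = sizes[a], sizes[b]
        new = next_key
        next_key += 1
        simd[new] = {}
        for c in clusters:
            if c in (a, b):
                continue
            s_new = (na * simd[a][c] + nb * simd[b][c]) / (na + nb)
            simd[new][c] = s_new
            simd[c][new] = s_new
            del simd[c][a], simd[c][b]
        clusters[new] = clusters.pop(a) + clusters.pop(b)
        sizes[new] = na + nb
        minid[new] = min(minid.pop(a), minid.pop(b))
        del simd[a], simd[b]
    return Dendrogram(tuple(ids), tuple(merges))


def cut_and_select(
    dendrogram: Dendrogram,
    threshold: float,
    dataset: InteractionDataset,
) -> tuple[list[tuple[str, ...]], list[str]]:
    """Cut at similarity ``threshold`` and pick one representative per cluster.

    Merges with similarity >= threshold are applied; the representative is
    the cluster member with the most known interactions in ``dataset``, ties
    by lexicographic ID. Returns (clusters, representatives), both ordered by
    each cluster's smallest member ID.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    parent = {e: e for e in dendrogram.leaf_ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for members_a, members_b, s in dendrogram.merges:
        if s >= threshold:
            parent[find(members_a[0])] = find(members_b[0])
    groups: dict[str, list[str]] = {}
    for e in dendrogram.leaf_ids:
        groups.setdefault(find(e), []).append(e)
    clusters = sorted((tuple(sorted(g)) for g in groups.values()), key=lambda c: c[0])
    counts = dataset.interactions_per_drug()
    representatives = [
        min(cluster, key=lambda d: (-counts.get(d, 0), d)) for cluster in clusters
    ]
    return clusters, representatives


@dataclass(frozen=True)
class BenchmarkSeries:
    """Per-threshold representative drug sets and filtered interaction data."""

    thresholds: tuple[float, ...]
    representatives: dict[float, tuple[str, ...]]
    datasets: dict[float, InteractionDataset]
    cluster_counts: dict[float, int]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "threshold": t,
                    "n_clusters": self.cluster_counts[t],
                    "n_drugs": len(self.representatives[t]),
                    "n_positives": len(self.datasets[t].positive_pairs),
                }
                for t in self.thresholds
            ]
        )

    def save_summary(self, path: str | Path) -> None:
        self.summary().to_csv(path, sep="\t", index=False)


def build_series(
    dataset: InteractionDataset,
    fingerprints: ProfileMatrix,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    n_folds_warning: int = 5,
) -> BenchmarkSeries:
    """One benchmark per threshold: representatives only, proteins kept.

    Warns when a benchmark retains fewer drugs than ``n_folds_warning`` —
    such a set cannot support 5-fold cross-validation (at a very permissive
    threshold only a handful of clusters may survive).
    """
    if not thresholds:
        raise ValueError("threshold list must be non-empty")
    missing = set(dataset.drug_ids) - set(fingerprints.entity_ids)
    if missing:
        raise ValueError(f"fingerprints missing for drugs: {sorted(missing)}")
    fp = fingerprints.subset(list(dataset.drug_ids))
    dend = average_linkage(fp)
    reps: dict[float, tuple[str, ...]] = {}
    datasets: dict[float, InteractionDataset] = {}
    counts: dict[float, int] = {}
    for t in thresholds:
        clusters, representatives = cut_and_select(dend, t, dataset)
        if len(representatives) < n_folds_warning:
            warnings.warn(
                f"threshold {t}: only {len(representatives)} representative drugs "
                f"(fewer than {n_folds_warning} folds)",
                stacklevel=2,
            )
        reps[t] = tuple(d for d in dataset.drug_ids if d in set(representatives))
        datasets[t] = dataset.subset_drugs(reps[t])
        counts[t] = len(clusters)
    return BenchmarkSeries(tuple(thresholds), reps, datasets, counts)
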
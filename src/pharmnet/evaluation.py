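"""ROC/AUC and the two cross-validation protocols.

Pair-wise CV partitions the drug-target *pairs* into folds: test pairs share
drugs and proteins with the training set, matching the scenario of filling in
missing interactions among characterised entities. Block-wise CV partitions
*drugs* and *proteins* independently into folds and, per round, trains on
(training drugs x training proteins) only, then scores three disjoint test
blocks: TestDrug-TrainProtein (new drug, known protein), TrainDrug-TestProtein
(known drug, orphan protein) and TestDrug-TestProtein (both unseen) — the
cold-start scenarios. Reported AUCs are *pooled*: one ROC over all held-out
scores of a category across the five rounds, not a mean of per-fold AUCs (a
mean-of-folds variant is available for sensitivity checks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import InteractionDataset, ProfileMatrix
from .descriptors import DescriptorSpec, build_design
from .model import FitConfig, fit, score_design

__all__ = [
    "FoldAssignment",
    "CVResult",
    "roc_auc",
    "make_folds",
    "run_pairwise_cv",
    "run_blockwise_cv",
    "BLOCKWISE_CATEGORIES",
]

BLOCKWISE_CATEGORIES = (
    "TestDrug-TrainProtein",
    "TrainDrug-TestProtein",
    "TestDrug-TestProtein",
)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    Equals the fraction of (positive, negative) pairs where the positive
    outscores the negative, ties counted one half. Labels are +-1.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels > 0
    n_pos = int(pos.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires at least one positive and one negative")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of the CV universe into folds.

    ``pairwise``: ``pair_folds`` maps each pair index (drug-major over the
    dataset universe) to a fold. ``blockwise``: drugs and proteins carry
    independent partitions drawn from sub-seeds of the master seed.
    """

    protocol: str
    n_folds: int
    seed: int
    pair_folds: np.ndarray | None = None
    drug_folds: Mapping[str, int] | None = None
    protein_folds: Mapping[str, int] | None = None


def make_folds(
    dataset: InteractionDataset,
    protocol: str,
    n_folds: int = 5,
    seed: int = 0,
) -> FoldAssignment:
    """Uniform random fold assignment, reproducible from ``seed``.

    Fold sizes differ by at most one. Blockwise drug and protein partitions
    use independent sub-streams of the master seed.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    ss = np.random.SeedSequence(seed)
    if protocol == "pairwise":
        n = dataset.n_pairs
        if n_folds > n:
            raise ValueError(f"n_folds={n_folds} exceeds pair count {n}")
        rng = np.random.default_rng(ss.spawn(1)[0])
        perm = rng.permutation(n)
        folds = np.empty(n, dtype=np.int64)
        folds[perm] = np.arange(n) % n_folds
        return FoldAssignment("pairwise", n_folds, seed, pair_folds=folds)
    if protocol == "blockwise":
        if n_folds > dataset.n_drugs or n_folds > dataset.n_proteins:
            raise ValueError("n_folds exceeds drug or protein count")
        drug_ss, prot_ss = ss.spawn(2)
        drug_folds = _partition(dataset.drug_ids, n_folds, drug_ss)
        protein_folds = _partition(dataset.protein_ids, n_folds, prot_ss)
        return FoldAssignment(
            "blockwise", n_folds, seed, drug_folds=drug_folds, protein_folds=protein_folds
        )
    raise ValueError(f"unknown protocol {protocol!r}")


def _partition(ids, n_folds, seed_seq) -> dict[str, int]:
    rng = np.random.default_rng(seed_seq)
    perm = rng.permutation(len(ids))
    return {ids[perm[i]]: i % n_folds for i in range(len(ids))}


@dataclass
class CVResult:
    """Pooled held-out scores and AUCs, one entry per test category."""

    protocol: str
    scores: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]
    aucs: dict[str, float]
    fold_metadata: list[dict] = field(default_factory=list)

    def pooled_auc_all_categories(self) -> float:
        """AUC over the union of every category's held-out scores."""
        s = np.concatenate([self.scores[c] for c in self.scores])
        y = np.concatenate([self.labels[c] for c in self.labels])
        return roc_auc(s, y)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "category": c,
                "n_test": len(self.scores[c]),
                "n_test_positive": int((self.labels[c] > 0).sum()),
                "auc_pooled": self.aucs[c],
            }
            for c in self.aucs
        ]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "protocol": self.protocol,
            "aucs": self.aucs,
            "n_test": {c: int(len(v)) for c, v in self.scores.items()},
            "folds": self.fold_metadata,
        }

    def save_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def run_pairwise_cv(
    dataset: InteractionDataset,
    drug_profiles: ProfileMatrix,
    protein_profiles: ProfileMatrix,
    spec: DescriptorSpec,
    config: FitConfig,
    folds: FoldAssignment | None = None,
    n_folds: int = 5,
    seed: int = 0,
    mean_of_folds: bool = False,
) -> CVResult:
    """Train on four pair folds, score the fifth, pool over folds."""
    if folds is None:
        folds = make_folds(dataset, "pairwise", n_folds=n_folds, seed=seed)
    if folds.protocol != "pairwise":
        raise ValueError("fold assignment protocol mismatch")
    X, y = build_design(dataset, drug_profiles, protein_profiles, spec)
    assignment = folds.pair_folds
    all_scores = np.empty(dataset.n_pairs, dtype=np.float64)
    all_labels = y.astype(np.int8)
    fold_meta = []
    per_fold_auc = []
    for t in range(folds.n_folds):
        test = assignment == t
        train = ~test
        y_train = y[train]
        if len(np.unique(y_train)) < 2:
            raise ValueError(f"fold {t}: training labels are single-class")
        model = fit(X[train], y_train, spec, config)
        s = score_design(model, X[test])
        all_scores[test] = s
        fold_meta.append(
            {
                "fold": t,
                "n_train": int(train.sum()),
                "n_test": int(test.sum()),
                "nonzero_features": model.nonzero_count(),
                "converged": model.fit_metadata["converged"],
            }
        )
        per_fold_auc.append(roc_auc(s, y[test]))
    auc = float(np.mean(per_fold_auc)) if mean_of_folds else roc_auc(all_scores, all_labels)
    return CVResult(
        "pairwise",
        {"pairwise": all_scores},
        {"pairwise": all_labels},
        {"pairwise": auc},
        fold_meta,
    )


def run_blockwise_cv(
    dataset: InteractionDataset,
    drug_profiles: ProfileMatrix,
    protein_profiles: ProfileMatrix,
    spec: DescriptorSpec,
    config: FitConfig,
    folds: FoldAssignment | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Drug fold t x protein fold t held out per round; three test categories.

    Per round the model trains on (training drugs x training proteins) only,
    so no test drug or test protein contributes any training pair. Categories
    pool over the rounds; each pair lands in a category at most once across
    the whole run (TestDrug-TestProtein exactly when its drug and protein
    share a fold index).
    """
    if folds is None:
        folds = make_folds(dataset, "blockwise", n_folds=n_folds, seed=seed)
    if folds.protocol != "blockwise":
        raise ValueError("fold assignment protocol mismatch")
    dfolds, pfolds = folds.drug_folds, folds.protein_folds
    cat_scores: dict[str, list[np.ndarray]] = {c: [] for c in BLOCKWISE_CATEGORIES}
    cat_labels: dict[str, list[np.ndarray]] = {c: [] for c in BLOCKWISE_CATEGORIES}
    fold_meta = []
    for t in range(folds.n_folds):
        test_drugs = [d for d in dataset.drug_ids if dfolds[d] == t]
        train_drugs = [d for d in dataset.drug_ids if dfolds[d] != t]
        test_prots = [p for p in dataset.protein_ids if pfolds[p] == t]
        train_prots = [p for p in dataset.protein_ids if pfolds[p] != t]
        train_pairs = [(d, p) for d in train_drugs for p in train_prots]
        X_train, y_train = build_design(
            dataset, drug_profiles, protein_profiles, spec, pairs=train_pairs
        )
        if len(np.unique(y_train)) < 2:
            raise ValueError(f"round {t}: training labels are single-class")
        model = fit(X_train, y_train, spec, config)
        blocks = {
            "TestDrug-TrainProtein": [(d, p) for d in test_drugs for p in train_prots],
            "TrainDrug-TestProtein": [(d, p) for d in train_drugs for p in test_prots],
            "TestDrug-TestProtein": [(d, p) for d in test_drugs for p in test_prots],
        }
        meta = {
            "fold": t,
            "n_train": len(train_pairs),
            "nonzero_features": model.nonzero_count(),
            "converged": model.fit_metadata["converged"],
        }
        for cat, pairs in blocks.items():
            if not pairs:
                continue
            X_test, y_test = build_design(
                dataset, drug_profiles, protein_profiles, spec, pairs=pairs
            )
            cat_scores[cat].append(score_design(model, X_test))
            cat_labels[cat].append(y_test.astype(np.int8))
            meta[f"n_{cat}"] = len(pairs)
        fold_meta.append(meta)
    scores = {c: np.concatenate(v) for c, v in cat_scores.items() if v}
    labels = {c: np.concatenate(v) for c, v in cat_labels.items() if v}
    aucs = {c: roc_auc(scores[c], labels[c]) for c in scores}
    return CVResult("blockwise", scores, labels, aucs, fold_meta)
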
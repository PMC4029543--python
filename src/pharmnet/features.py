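"""Pharmacogenomic feature extraction, ranking, comparison and prediction.

A *pharmacogenomic feature* is a (side effect, protein domain) pair whose
tensor-block descriptor position carries a strictly positive weight in a
trained pair classifier — an inferred association between a drug phenotype and
a protein domain. (With substructure profiles the same machinery yields
*chemogenomic* features.) Drug-block and protein-block weights of combined
models describe single entities, not associations, and are never features.
Negative weights are discarded rather than reported as anti-associations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import InteractionDataset, ProfileMatrix
from .descriptors import build_design
from .model import TrainedModel, score_design

__all__ = [
    "PharmacoFeature",
    "FeatureSetComparison",
    "extract_features",
    "rank_views",
    "compare_methods",
    "predict_novel",
]


@dataclass(frozen=True)
class PharmacoFeature:
    """One (side effect, protein domain) association with its model weight."""

    side_effect: str
    domain: str
    weight: float

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ValueError("pharmacogenomic features carry positive weights only")

    @property
    def identity(self) -> tuple[str, str]:
        return (self.side_effect, self.domain)


def _feature_sort_key(f: PharmacoFeature):
    return (-f.weight, f.side_effect, f.domain)


def extract_features(model: TrainedModel) -> list[PharmacoFeature]:
    """Positively weighted tensor-block positions, decoded to name pairs.

    Sorted by descending weight, ties by (side_effect, domain) lexicographic.
    """
    spec = model.descriptor_spec
    N = spec.n_protein_features
    tensor = model.weights[: spec.tensor_dimension]
    out = []
    for k in np.flatnonzero(tensor > 0):
        out.append(
            PharmacoFeature(
                side_effect=spec.drug_feature_names[k // N],
                domain=spec.protein_feature_names[k % N],
                weight=float(tensor[k]),
            )
        )
    out.sort(key=_feature_sort_key)
    return out


def rank_views(
    features: Sequence[PharmacoFeature],
    domain_definitions: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Three ranked tables over the same features.

    (a) global ranking by weight; (b) grouped by side effect, domains ranked
    within; (c) grouped by domain, side effects ranked within. Groups are
    ordered by their top weight (descending, ties by group name); rows within
    a group by descending weight with the usual tie rule. An optional
    ``domain_definitions`` map adds a definition column.
    """
    defs = domain_definitions or {}
    ordered = sorted(features, key=_feature_sort_key)

    def _row(rank, f):
        return {
            "rank": rank,
            "weight": f.weight,
            "side_effect": f.side_effect,
            "domain": f.domain,
            "domain_definition": defs.get(f.domain, ""),
        }

    global_view = pd.DataFrame(
        [_row(r + 1, f) for r, f in enumerate(ordered)],
        columns=["rank", "weight", "side_effect", "domain", "domain_definition"],
    )

    def _grouped(key_attr: str) -> pd.DataFrame:
        groups: dict[str, list[PharmacoFeature]] = {}
        for f in ordered:
            groups.setdefault(getattr(f, key_attr), []).append(f)
        order = sorted(groups, key=lambda g: (-groups[g][0].weight, g))
        rows = []
        for rank, g in enumerate(order, start=1):
            for f in groups[g]:  # already weight-sorted
                rows.append({**_row(rank, f), "group": g})
        return pd.DataFrame(
            rows,
            columns=["rank", "group", "weight", "side_effect", "domain", "domain_definition"],
        )

    return global_view, _grouped("side_effect"), _grouped("domain")


@dataclass(frozen=True)
class FeatureSetComparison:
    """Feature-set sizes and overlaps between methods.

    Membership is the (side effect, domain) identity; weights are ignored.
    """

    feature_sets: dict[str, frozenset[tuple[str, str]]]
    counts: dict[str, int]
    pairwise_intersections: dict[tuple[str, str], int]
    common_to_all: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"method_a": a, "method_b": b, "intersection": n}
            for (a, b), n in sorted(self.pairwise_intersections.items())
        ]
        return pd.DataFrame(rows, columns=["method_a", "method_b", "intersection"])


def compare_methods(models: Mapping[str, TrainedModel]) -> FeatureSetComparison:
    """Set comparison of the features inferred by several methods."""
    names = list(models)
    if len(names) < 2:
        raise ValueError("need at least two models to compare")
    vocab = None
    for name, m in models.items():
        v = (
            m.descriptor_spec.drug_feature_names,
            m.descriptor_spec.protein_feature_names,
        )
        if vocab is None:
            vocab = v
        elif v != vocab:
            raise ValueError(
                f"model {name!r} uses a different drug/protein feature vocabulary"
            )
    sets = {
        name: frozenset(f.identity for f in extract_features(m))
        for name, m in models.items()
    }
    pairwise = {
        (a, b): len(sets[a] & sets[b])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    common = len(frozenset.intersection(*sets.values()))
    return FeatureSetComparison(
        feature_sets=sets,
        counts={n: len(s) for n, s in sets.items()},
        pairwise_intersections=pairwise,
        common_to_all=common,
    )


def predict_novel(
    model: TrainedModel,
    dataset: InteractionDataset,
    drug_profiles: ProfileMatrix,
    protein_profiles: ProfileMatrix,
    top_k: int = 1000,
) -> pd.DataFrame:
    """Rank candidate interactions among pairs not already known to interact.

    Scores every (drug, protein) pair outside the positive set and returns
    the ``top_k`` by descending score, ties broken by (drug_id, protein_id).
    """
    if top_k <= 0:
        raise ValueError(f"top_k must be positive, got {top_k}")
    candidates = [
        (d, p)
        for d in dataset.drug_ids
        for p in dataset.protein_ids
        if (d, p) not in dataset.positive_pairs
    ]
    if not candidates:
        return pd.DataFrame(columns=["rank", "drug_id", "protein_id", "score"])
    X, _ = build_design(
        dataset, drug_profiles, protein_profiles, model.descriptor_spec, pairs=candidates
    )
    s = score_design(model, X)
    order = sorted(range(len(candidates)), key=lambda i: (-s[i], candidates[i]))
    top = order[:top_k]
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(top) + 1),
            "drug_id": [candidates[i][0] for i in top],
            "protein_id": [candidates[i][1] for i in top],
            "score": [float(s[i]) for i in top],
        }
    )
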
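"""Pair descriptors for drug-protein pairs.

A drug is an M-dimensional binary feature vector (its side-effect or
substructure profile) and a protein an N-dimensional one (its domain profile).
A pair is described either by the *tensor product descriptor* — the M*N vector
of all products d_i * p_j, laid out row-major by drug feature
(d1p1,...,d1pN,...,dMp1,...,dMpN) — or by the *combined descriptor*, the
tensor block followed by the raw drug vector and the raw protein vector
(dimension M*N + M + N).

The DescriptorSpec owns the mapping between descriptor positions and
(drug-feature, protein-feature) semantics, so saved models stay portable and
user-facing reports can always translate positions back to feature names.
Designs are materialised sparsely and only for requested pairs — a dense
design over hundreds of drugs, proteins and hundreds of thousands of
descriptor positions would be infeasible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .data import InteractionDataset, ProfileMatrix

__all__ = [
    "DescriptorSpec",
    "PairVector",
    "build_tensor",
    "build_combined",
    "build_pair",
    "decode_position",
    "build_design",
]


@dataclass(frozen=True)
class DescriptorSpec:
    """Layout of a pair descriptor over named drug and protein features."""

    kind: str  # "tensor" | "combined"
    drug_feature_names: tuple[str, ...]
    protein_feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("tensor", "combined"):
            raise ValueError(f"unknown descriptor kind {self.kind!r}")
        if not self.drug_feature_names or not self.protein_feature_names:
            raise ValueError("feature name lists must be non-empty")

    @property
    def n_drug_features(self) -> int:
        return len(self.drug_feature_names)

    @property
    def n_protein_features(self) -> int:
        return len(self.protein_feature_names)

    @property
    def tensor_dimension(self) -> int:
        return self.n_drug_features * self.n_protein_features

    @property
    def dimension(self) -> int:
        if self.kind == "tensor":
            return self.tensor_dimension
        return self.tensor_dimension + self.n_drug_features + self.n_protein_features

    def encode_pair(self, i: int, j: int) -> int:
        """Descriptor position of the (drug feature i, protein feature j) product."""
        N = self.n_protein_features
        if not (0 <= i < self.n_drug_features and 0 <= j < N):
            raise IndexError(f"feature indices ({i}, {j}) out of range")
        return i * N + j

    # -- serialization --------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "drug_feature_names": list(self.drug_feature_names),
                "protein_feature_names": list(self.protein_feature_names),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DescriptorSpec":
        d = json.loads(text)
        return cls(
            d["kind"],
            tuple(d["drug_feature_names"]),
            tuple(d["protein_feature_names"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "DescriptorSpec":
        return cls.from_json(Path(path).read_text())

    @classmethod
    def for_profiles(
        cls, kind: str, drug_profiles: ProfileMatrix, protein_profiles: ProfileMatrix
    ) -> "DescriptorSpec":
        return cls(
            kind,
            tuple(drug_profiles.feature_names),
            tuple(protein_profiles.feature_names),
        )


@dataclass(frozen=True)
class PairVector:
    """Sparse realised descriptor for one drug-protein pair (all values 1)."""

    spec: DescriptorSpec
    nonzero_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(k < 0 or k >= self.spec.dimension for k in self.nonzero_positions):
            raise ValueError("descriptor position out of range for spec")

    def to_dense(self) -> np.ndarray:
        v = np.zeros(self.spec.dimension, dtype=np.int8)
        v[list(self.nonzero_positions)] = 1
        return v


def _check_lengths(drug_vec: np.ndarray, prot_vec: np.ndarray, spec: DescriptorSpec) -> None:
    if len(drug_vec) != spec.n_drug_features:
        raise ValueError(
            f"drug vector length {len(drug_vec)} != spec M={spec.n_drug_features}"
        )
    if len(prot_vec) != spec.n_protein_features:
        raise ValueError(
            f"protein vector length {len(prot_vec)} != spec N={spec.n_protein_features}"
        )


def _tensor_positions(drug_vec: np.ndarray, prot_vec: np.ndarray, N: int) -> np.ndarray:
    di = np.flatnonzero(drug_vec)
    pj = np.flatnonzero(prot_vec)
    return (di[:, None] * N + pj[None, :]).ravel()


def build_tensor(
    drug_vec: Sequence[int], prot_vec: Sequence[int], spec: DescriptorSpec
) -> PairVector:
    """Tensor product descriptor: position i*N+j is on iff d_i=1 and p_j=1."""
    if spec.kind != "tensor":
        raise ValueError("spec.kind must be 'tensor'")
    d = np.asarray(drug_vec)
    p = np.asarray(prot_vec)
    _check_lengths(d, p, spec)
    pos = _tensor_positions(d, p, spec.n_protein_features)
    return PairVector(spec, tuple(int(k) for k in np.sort(pos)))


def build_combined(
    drug_vec: Sequence[int], prot_vec: Sequence[int], spec: DescriptorSpec
) -> PairVector:
    """Combined descriptor: tensor block, then raw drug block, then raw protein block."""
    if spec.kind != "combined":
        raise ValueError("spec.kind must be 'combined'")
    d = np.asarray(drug_vec)
    p = np.asarray(prot_vec)
    _check_lengths(d, p, spec)
    M, N = spec.n_drug_features, spec.n_protein_features
    pos = np.concatenate(
        [
            _tensor_positions(d, p, N),
            M * N + np.flatnonzero(d),
            M * N + M + np.flatnonzero(p),
        ]
    )
    return PairVector(spec, tuple(int(k) for k in np.sort(pos)))


def build_pair(
    drug_vec: Sequence[int], prot_vec: Sequence[int], spec: DescriptorSpec
) -> PairVector:
    """Dispatch on spec.kind."""
    if spec.kind == "tensor":
        return build_tensor(drug_vec, prot_vec, spec)
    return build_combined(drug_vec, prot_vec, spec)


def decode_position(spec: DescriptorSpec, k: int) -> tuple:
    """Inverse of the descriptor layout.

    Returns ``("pair", i, j)`` for tensor-block positions, ``("drug", i)`` for
    drug-block positions of a combined spec, ``("protein", j)`` for
    protein-block positions.
    """
    if not (0 <= k < spec.dimension):
        raise IndexError(f"position {k} out of range for dimension {spec.dimension}")
    M, N = spec.n_drug_features, spec.n_protein_features
    if k < M * N:
        return ("pair", k // N, k % N)
    k -= M * N
    if k < M:
        return ("drug", k)
    return ("protein", k - M)


def build_design(
    dataset: InteractionDataset,
    drug_profiles: ProfileMatrix,
    protein_profiles: ProfileMatrix,
    spec: DescriptorSpec,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sparse design matrix and +-1 label vector for the requested pairs.

    ``pairs`` defaults to every pair of the dataset universe in drug-major
    order. One row per requested pair, in input order.
    """
    if pairs is None:
        pairs = [(d, p) for d in dataset.drug_ids for p in dataset.protein_ids]
    known_drugs = set(dataset.drug_ids)
    known_prots = set(dataset.protein_ids)

    M, N = spec.n_drug_features, spec.n_protein_features
    if drug_profiles.n_features != M or protein_profiles.n_features != N:
        raise ValueError("profile dimensions do not match descriptor spec")

    drug_on = {d: drug_profiles.on_indices(d) for d in dataset.drug_ids}
    prot_on = {p: protein_profiles.on_indices(p) for p in dataset.protein_ids}

    indptr = [0]
    index_chunks: list[np.ndarray] = []
    y = np.empty(len(pairs), dtype=np.int8)
    for r, (d, p) in enumerate(pairs):
        if d not in known_drugs:
            raise KeyError(f"unknown drug {d!r} in requested pairs")
        if p not in known_prots:
            raise KeyError(f"unknown protein {p!r} in requested pairs")
        di = drug_on[d]
        pj = prot_on[p]
        pos = (di[:, None] * N + pj[None, :]).ravel()
        if spec.kind == "combined":
            pos = np.concatenate([pos, M * N + di, M * N + M + pj])
        pos.sort()
        index_chunks.append(pos)
        indptr.append(indptr[-1] + len(pos))
        y[r] = dataset.label(d, p)

    indices = (
        np.concatenate(index_chunks) if index_chunks else np.empty(0, dtype=np.int64)
    )
    X = sp.csr_matrix(
        (np.ones(len(indices), dtype=np.float64), indices, np.asarray(indptr)),
        shape=(len(pairs), spec.dimension),
    )
    return X, y
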
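"""Core data containers and on-disk formats.

Two kinds of objects flow through the pipeline: binary *profile matrices*
(drugs-by-side-effects, drugs-by-substructures, drugs-by-fingerprint-bits,
proteins-by-domains) and an *interaction dataset* — the gold standard of known
drug-target pairs over a fixed drug and protein universe. Every (drug, protein)
pair absent from the positive list is treated as a negative; this complement
convention is a dataset-level constant, not an option.

On-disk formats are plain TSV:

* profile matrix — header ``id<TAB>f1<TAB>f2...``, rows of 0/1;
* pair list — two columns ``entity_id<TAB>feature_name``, presence-only;
* interactions — two columns ``drug_id<TAB>protein_id``;
* edge list — ``side_effect<TAB>domain<TAB>weight`` (or SIF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ProfileMatrix",
    "InteractionDataset",
    "read_profile_matrix",
    "write_profile_matrix",
    "read_interactions",
    "write_interactions",
    "write_edge_list",
]


class DataFormatError(ValueError):
    """Raised when an input file violates a format contract."""


@dataclass
class ProfileMatrix:
    """Named binary feature vectors for a set of entities.

    Rows follow ``entity_ids`` order, columns follow ``feature_names`` order,
    and every stored value is exactly 0 or 1. Values are held as a CSR sparse
    matrix; the profiles this models (side effects, PFAM domains, fingerprint
    bits) are sparse in practice.
    """

    entity_ids: list[str]
    feature_names: list[str]
    values: sp.csr_matrix

    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.entity_ids) == 0:
            raise DataFormatError("ProfileMatrix requires at least one entity")
        if len(self.feature_names) == 0:
            raise DataFormatError("ProfileMatrix requires at least one feature")
        if len(set(self.entity_ids)) != len(self.entity_ids):
            dup = _first_duplicate(self.entity_ids)
            raise DataFormatError(f"duplicate entity ID: {dup!r}")
        if len(set(self.feature_names)) != len(self.feature_names):
            dup = _first_duplicate(self.feature_names)
            raise DataFormatError(f"duplicate feature name: {dup!r}")
        values = sp.csr_matrix(self.values, dtype=np.int8, copy=True)
        values.eliminate_zeros()
        if values.shape != (len(self.entity_ids), len(self.feature_names)):
            raise DataFormatError(
                f"values shape {values.shape} does not match "
                f"{len(self.entity_ids)} entities x {len(self.feature_names)} features"
            )
        if values.nnz and not np.all(values.data == 1):
            bad = np.flatnonzero(values.data != 1)[0]
            raise DataFormatError(
                f"non-binary value {values.data[bad]} in profile matrix"
            )
        self.values = values
        self._index = {e: i for i, e in enumerate(self.entity_ids)}

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_dense(
        cls,
        entity_ids: Sequence[str],
        feature_names: Sequence[str],
        array: np.ndarray,
    ) -> "ProfileMatrix":
        return cls(list(entity_ids), list(feature_names), sp.csr_matrix(array))

    # -- queries --------------------------------------------------------------

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def row(self, entity_id: str) -> np.ndarray:
        """Dense 0/1 vector for one entity."""
        return np.asarray(
            self.values[self._index[entity_id]].todense(), dtype=np.int8
        ).ravel()

    def on_indices(self, entity_id: str) -> np.ndarray:
        """Sorted column indices of the entity's on-bits."""
        r = self._index[entity_id]
        return np.sort(self.values.indices[self.values.indptr[r] : self.values.indptr[r + 1]])

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense(), dtype=np.int8)

    def subset(self, entity_ids: Sequence[str]) -> "ProfileMatrix":
        """Row-subset preserving the given order; features unchanged."""
        rows = [self._index[e] for e in entity_ids]
        return ProfileMatrix(list(entity_ids), list(self.feature_names), self.values[rows])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProfileMatrix):
            return NotImplemented
        return (
            self.entity_ids == other.entity_ids
            and self.feature_names == other.feature_names
            and (self.values != other.values).nnz == 0
        )


@dataclass(frozen=True)
class InteractionDataset:
    """Gold-standard drug-target interactions over a fixed pair universe.

    The label of pair ``(i, j)`` is +1 if ``(drug_ids[i], protein_ids[j])`` is
    in ``positive_pairs`` and -1 otherwise; the full label matrix is implied,
    never stored densely by contract.
    """

    drug_ids: tuple[str, ...]
    protein_ids: tuple[str, ...]
    positive_pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        drugs = set(self.drug_ids)
        prots = set(self.protein_ids)
        if len(drugs) != len(self.drug_ids) or len(prots) != len(self.protein_ids):
            raise DataFormatError("duplicate IDs in InteractionDataset universe")
        for d, p in self.positive_pairs:
            if d not in drugs:
                raise DataFormatError(f"positive pair references unknown drug {d!r}")
            if p not in prots:
                raise DataFormatError(f"positive pair references unknown protein {p!r}")

    @classmethod
    def build(
        cls,
        drug_ids: Iterable[str],
        protein_ids: Iterable[str],
        positive_pairs: Iterable[tuple[str, str]],
    ) -> "InteractionDataset":
        return cls(tuple(drug_ids), tuple(protein_ids), frozenset(positive_pairs))

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_pairs(self) -> int:
        return self.n_drugs * self.n_proteins

    def label(self, drug_id: str, protein_id: str) -> int:
        return 1 if (drug_id, protein_id) in self.positive_pairs else -1

    def label_matrix(self) -> np.ndarray:
        """Dense +-1 matrix, drugs by proteins."""
        y = -np.ones((self.n_drugs, self.n_proteins), dtype=np.int8)
        di = {d: i for i, d in enumerate(self.drug_ids)}
        pj = {p: j for j, p in enumerate(self.protein_ids)}
        for d, p in self.positive_pairs:
            y[di[d], pj[p]] = 1
        return y

    def interactions_per_drug(self) -> dict[str, int]:
        counts = {d: 0 for d in self.drug_ids}
        for d, _ in self.positive_pairs:
            counts[d] += 1
        return counts

    def subset_drugs(self, drug_ids: Sequence[str]) -> "InteractionDataset":
        """Restrict the drug universe (proteins kept in full)."""
        keep = set(drug_ids)
        unknown = keep - set(self.drug_ids)
        if unknown:
            raise DataFormatError(f"unknown drug IDs: {sorted(unknown)}")
        return InteractionDataset(
            tuple(d for d in self.drug_ids if d in keep),
            self.protein_ids,
            frozenset((d, p) for d, p in self.positive_pairs if d in keep),
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_profile_matrix(path: str | Path, dialect: str = "tsv_matrix") -> ProfileMatrix:
    """Read a binary profile matrix.

    ``tsv_matrix``: header row of feature names, first column of entity IDs,
    0/1 cells. ``pair_list``: two header-less columns (entity_id,
    feature_name), presence-only; features become the union of observed names
    sorted lexicographically so runs are deterministic.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise DataFormatError(f"empty file: {path}")
    if dialect == "tsv_matrix":
        return _read_tsv_matrix(path)
    if dialect == "pair_list":
        return _read_pair_list(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv_matrix(path: Path) -> ProfileMatrix:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise DataFormatError(f"no feature columns in {path}")
    entity_ids = [str(e) for e in df.index]
    if len(set(entity_ids)) != len(entity_ids):
        raise DataFormatError(
            f"duplicate entity ID {_first_duplicate(entity_ids)!r} in {path}"
        )
    feature_names = [str(c) for c in df.columns]
    arr = np.empty(df.shape, dtype=np.int8)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            if cell not in ("0", "1"):
                raise DataFormatError(
                    f"non-binary cell {cell!r} at row {entity_ids[i]!r}, "
                    f"column {feature_names[j]!r} in {path}"
                )
            arr[i, j] = int(cell)
    return ProfileMatrix.from_dense(entity_ids, feature_names, arr)


def _read_pair_list(path: Path) -> ProfileMatrix:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise DataFormatError(f"pair_list needs exactly 2 columns, got {df.shape[1]}")
    entities: list[str] = []
    seen = set()
    for e in df[0]:
        if e not in seen:
            entities.append(e)
            seen.add(e)
    features = sorted(set(df[1]))
    eidx = {e: i for i, e in enumerate(entities)}
    fidx = {f: j for j, f in enumerate(features)}
    rows = [eidx[e] for e in df[0]]
    cols = [fidx[f] for f in df[1]]
    values = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(entities), len(features)),
    )
    values.data[:] = 1  # collapse duplicate (entity, feature) lines
    return ProfileMatrix(entities, features, values)


def write_profile_matrix(matrix: ProfileMatrix, path: str | Path) -> None:
    """Write in ``tsv_matrix`` dialect (round-trips exactly)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id\t" + "\t".join(matrix.feature_names) + "\n")
        dense = matrix.to_dense()
        for e, row in zip(matrix.entity_ids, dense):
            fh.write(e + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_interactions(
    path: str | Path, drugs: ProfileMatrix, proteins: ProfileMatrix
) -> InteractionDataset:
    """Read a two-column (drug_id, protein_id) positive-pair list.

    The resulting dataset adopts the profile matrices' entity orders as its
    drug/protein universe; duplicate pairs collapse to one.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise DataFormatError(f"empty file: {path}")
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise DataFormatError(f"interactions need exactly 2 columns, got {df.shape[1]}")
    known_drugs = set(drugs.entity_ids)
    known_prots = set(proteins.entity_ids)
    pairs = set()
    for d, p in zip(df[0], df[1]):
        if d not in known_drugs:
            raise DataFormatError(f"unknown drug ID {d!r} in {path}")
        if p not in known_prots:
            raise DataFormatError(f"unknown protein ID {p!r} in {path}")
        pairs.add((d, p))
    if not pairs:
        raise DataFormatError(f"no positive pairs in {path}")
    return InteractionDataset.build(drugs.entity_ids, proteins.entity_ids, pairs)


def write_interactions(dataset: InteractionDataset, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for d, p in sorted(dataset.positive_pairs):
            fh.write(f"{d}\t{p}\n")


def write_edge_list(
    features: Sequence,
    path: str | Path,
    top_n: int | str = "all",
    sif: bool = False,
) -> None:
    """Export side-effect/domain associations as a weighted edge list.

    Features are written in descending weight (ties broken by the
    (side_effect, domain) pair, lexicographically) and truncated to ``top_n``
    edges; weights print with 4 decimal places. With ``sif=True`` the SIF form
    ``side_effect<TAB>assoc<TAB>domain`` is written instead.
    """
    if top_n != "all":
        if int(top_n) <= 0:
            raise ValueError(f"top_n must be positive, got {top_n}")
        top_n = int(top_n)
    ordered = sorted(features, key=lambda f: (-f.weight, f.side_effect, f.domain))
    if top_n != "all":
        ordered = ordered[:top_n]
    with Path(path).open("w") as fh:
        for f in ordered:
            if sif:
                fh.write(f"{f.side_effect}\tassoc\t{f.domain}\n")
            else:
                fh.write(f"{f.side_effect}\t{f.domain}\t{f.weight:.4f}\n")


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""
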
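"""Core domain types for multi-label membrane protein type prediction.

Human membrane proteins are conventionally divided into six types according
to their intramolecular arrangement and position in the cell: GPI-anchor,
lipid-anchor, multi-pass, peripheral, single-pass type I and single-pass
type II.  A single protein may carry more than one of these types at once
(in curated data never more than three), so a protein's annotation is a
*set* of types, encoded where convenient as a 6-component 0/1 label vector.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "MembraneType",
    "ProteinRecord",
    "Dataset",
    "InteractionTable",
    "Prediction",
    "encode_labels",
    "decode_labels",
    "average_type_count",
    "top_t",
    "STANDARD_AMINO_ACIDS",
    "NONSTANDARD_RESIDUES",
]

#: The 20 standard amino acids, alphabetical one-letter order.
STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity/rare codes that may appear in curated sequences.  They are
#: preserved on ingest but flagged, and excluded from composition statistics.
NONSTANDARD_RESIDUES = frozenset("BZXUO*")


class MembraneType(enum.IntEnum):
    """The six membrane protein types, in the fixed 1..6 order.

    The integer value doubles as the 1-based index used in label vectors
    and in index-coded annotation files.
    """

    GPI_ANCHOR = 1
    LIPID_ANCHOR = 2
    MULTI_PASS = 3
    PERIPHERAL = 4
    SINGLE_PASS_I = 5
    SINGLE_PASS_II = 6

    @property
    def display_name(self) -> str:
        return _TYPE_NAMES[self]

    @classmethod
    def from_token(cls, token: str) -> "MembraneType":
        """Resolve a type from a 1-based index or a (case-insensitive) name."""
        tok = token.strip()
        if not tok:
            raise ValueError("empty membrane type token")
        if tok.isdigit():
            idx = int(tok)
            try:
                return cls(idx)
            except ValueError:
                raise ValueError(f"no membrane type with index {idx}") from None
        key = _normalize_name(tok)
        try:
            return _NAME_LOOKUP[key]
        except KeyError:
            raise ValueError(f"unknown membrane type name: {token!r}") from None


_TYPE_NAMES: dict[MembraneType, str] = {
    MembraneType.GPI_ANCHOR: "GPI-anchor",
    MembraneType.LIPID_ANCHOR: "lipid-anchor",
    MembraneType.MULTI_PASS: "multi-pass",
    MembraneType.PERIPHERAL: "peripheral",
    MembraneType.SINGLE_PASS_I: "single-pass type I",
    MembraneType.SINGLE_PASS_II: "single-pass type II",
}


def _normalize_name(name: str) -> str:
    return "".join(c for c in name.lower() if c.isalnum())


_NAME_LOOKUP: dict[str, MembraneType] = {}
for _t, _n in _TYPE_NAMES.items():
    _NAME_LOOKUP[_normalize_name(_n)] = _t
    _NAME_LOOKUP[_normalize_name(_t.name)] = _t
# common shorthand seen in annotation exports
_NAME_LOOKUP[_normalize_name("GPI anchor")] = MembraneType.GPI_ANCHOR
_NAME_LOOKUP[_normalize_name("lipid anchor")] = MembraneType.LIPID_ANCHOR
_NAME_LOOKUP[_normalize_name("single-pass I")] = MembraneType.SINGLE_PASS_I
_NAME_LOOKUP[_normalize_name("single-pass II")] = MembraneType.SINGLE_PASS_II
_NAME_LOOKUP[_normalize_name("type I")] = MembraneType.SINGLE_PASS_I
_NAME_LOOKUP[_normalize_name("type II")] = MembraneType.SINGLE_PASS_II


def encode_labels(types: Iterable[MembraneType]) -> np.ndarray:
    """Encode a non-empty set of membrane types as a 6-component 0/1 vector.

    Component k-1 is 1 exactly when the protein carries type k.
    """
    members = frozenset(MembraneType(t) for t in types)
    if not members:
        raise ValueError("label set must be non-empty")
    vec = np.zeros(6, dtype=np.int8)
    for t in members:
        vec[t - 1] = 1
    return vec


def decode_labels(vector: np.ndarray) -> frozenset[MembraneType]:
    """Inverse of :func:`encode_labels`."""
    vec = np.asarray(vector)
    if vec.shape != (6,):
        raise ValueError(f"label vector must have 6 components, got {vec.shape}")
    if not np.isin(vec, (0, 1)).all():
        raise ValueError("label vector components must be 0 or 1")
    return frozenset(MembraneType(k + 1) for k in range(6) if vec[k])


@dataclass(frozen=True)
class ProteinRecord:
    """A protein: accession, amino-acid sequence, and optional type labels.

    ``sequence`` may be empty when only network evidence exists for the
    protein; sequence-based operations reject such records explicitly.
    ``labels`` is ``None`` for unannotated queries and a non-empty frozenset
    for training proteins.
    """

    id: str
    sequence: str = ""
    labels: frozenset[MembraneType] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if self.labels is not None:
            if not self.labels:
                raise ValueError(f"protein {self.id}: labels, when given, must be non-empty")
            object.__setattr__(self, "labels", frozenset(MembraneType(t) for t in self.labels))
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def has_nonstandard_residues(self) -> bool:
        return any(c in NONSTANDARD_RESIDUES for c in self.sequence)

    @property
    def label_vector(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError(f"protein {self.id} is unlabelled")
        return encode_labels(self.labels)

    def with_labels(self, labels: Iterable[MembraneType] | None) -> "ProteinRecord":
        return ProteinRecord(self.id, self.sequence,
                             None if labels is None else frozenset(labels))


class Dataset:
    """A named collection of :class:`ProteinRecord` with unique ids."""

    def __init__(self, proteins: Iterable[ProteinRecord] = (), name: str = "dataset"):
        self.name = name
        self._records: dict[str, ProteinRecord] = {}
        for rec in proteins:
            self.add(rec)

    def add(self, record: ProteinRecord) -> None:
        if record.id in self._records:
            raise ValueError(f"duplicate protein id: {record.id}")
        self._records[record.id] = record

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self._records.values())

    def __contains__(self, pid: str) -> bool:
        return pid in self._records

    def __getitem__(self, pid: str) -> ProteinRecord:
        return self._records[pid]

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def labelled(self) -> "Dataset":
        """Subset of records that carry labels."""
        return Dataset((r for r in self if r.labels is not None), name=self.name)

    def annotate(self, labels: Mapping[str, Iterable[MembraneType]],
                 strict: bool = True) -> "Dataset":
        """Return a copy with labels attached from an id -> types mapping."""
        missing = set(labels) - set(self._records)
        if strict and missing:
            raise KeyError(f"annotations for unknown proteins: {sorted(missing)[:5]}")
        out = Dataset(name=self.name)
        for rec in self:
            if rec.id in labels:
                out.add(rec.with_labels(frozenset(labels[rec.id])))
            else:
                out.add(rec)
        return out

    def without(self, pid: str) -> "Dataset":
        """Copy of the dataset with one protein removed (leave-one-out)."""
        return Dataset((r for r in self if r.id != pid), name=self.name)

    def hide_labels(self, pid: str) -> tuple[ProteinRecord, "Dataset"]:
        """Split into (query with labels hidden, remaining labelled training set)."""
        query = self[pid]
        return query.with_labels(None), self.without(pid)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self._records == other._records

    def __repr__(self) -> str:
        return f"Dataset({self.name!r}, n={len(self)})"


@dataclass(frozen=True)
class Prediction:
    """A predicted label set together with the method/stage that produced it.

    ``fallback`` marks predictions produced by a last-resort rule (e.g. the
    most-frequent-type fallback for proteins unreachable in the interaction
    graph) so evaluations can segregate them.  ``diagnostics`` carries
    method-specific evidence: the best alignment hit, the type-probability
    vector, or the nearest graph neighbour.
    """

    labels: frozenset[MembraneType]
    method: str
    fallback: bool = False
    diagnostics: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("a prediction must carry at least one type")
        object.__setattr__(self, "labels", frozenset(MembraneType(t) for t in self.labels))

    @property
    def stage(self) -> str:
        return self.method


def average_type_count(dataset: Dataset) -> float:
    """Mean number of type labels per protein over a fully labelled dataset."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    sizes = []
    for rec in dataset:
        if rec.labels is None:
            raise ValueError(f"protein {rec.id} is unlabelled")
        sizes.append(len(rec.labels))
    return float(np.mean(sizes))


def top_t(dataset: Dataset) -> int:
    """Smallest integer >= the mean labels-per-protein of the dataset.

    This is the number of top-probability types retained by the
    network-voting predictor.  On curated human membrane protein sets the
    mean is slightly above 1, giving t = 2.
    """
    return math.ceil(average_type_count(dataset))


class InteractionTable:
    """Symmetric pairwise interaction confidence scores, STRING 0-1000 scale.

    Two proteins are considered interactive exactly when their combined
    confidence score is greater than zero, so only positive scores are
    stored; absence of an entry means "not interactive".  Self-interactions
    are excluded.
    """

    def __init__(self) -> None:
        self._scores: dict[tuple[str, str], float] = {}
        self._neighbors: dict[str, dict[str, float]] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, score: float) -> None:
        if a == b:
            raise ValueError(f"self-interaction not allowed: {a}")
        if not (0 < score <= 1000):
            raise ValueError(f"confidence score must be in (0, 1000], got {score} for ({a},{b})")
        self._scores[self._key(a, b)] = float(score)
        self._neighbors.setdefault(a, {})[b] = float(score)
        self._neighbors.setdefault(b, {})[a] = float(score)

    def score(self, a: str, b: str) -> float:
        """Confidence score, 0.0 when the pair is not interactive."""
        if a == b:
            return 0.0
        return self._scores.get(self._key(a, b), 0.0)

    def neighbors(self, pid: str) -> dict[str, float]:
        return dict(self._neighbors.get(pid, {}))

    def proteins(self) -> set[str]:
        return set(self._neighbors)

    def __len__(self) -> int:
        return len(self._scores)

    def __iter__(self) -> Iterator[tuple[str, str, float]]:
        for (a, b), w in sorted(self._scores.items()):
            yield a, b, w

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionTable):
            return NotImplemented
        return self._scores == other._scores

    def __repr__(self) -> str:
        return f"InteractionTable(n_edges={len(self)}, n_proteins={len(self._neighbors)})"
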
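"""Guilt-by-association voting over direct interaction partners.

Interacting proteins tend to share membrane types, and the STRING combined
confidence score quantifies how much an interaction should be trusted.  The
type-probability of a query is therefore the confidence-weighted fraction
of its interactive training partners carrying each type:

    p_k = sum_q w_q * l_qk / sum_q w_q

where w_q is the confidence score between the query and the q-th training
protein (0 when they do not interact) and l_qk the 0/1 label of that
partner for type k.  The t types with highest positive probability form the
prediction, t being the ceiling of the dataset's mean labels-per-protein.
With no interactive partner at all, every p_k is zero and the method
abstains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import (
    Dataset,
    InteractionTable,
    MembraneType,
    Prediction,
    ProteinRecord,
)

__all__ = [
    "TypeProbabilityVector",
    "interaction_scores",
    "type_probabilities",
    "predict_by_network",
]


@dataclass(frozen=True)
class TypeProbabilityVector:
    """Per-type assignment probabilities and the confidence mass behind them."""

    p: np.ndarray  # shape (6,)
    support: float  # total confidence mass of interactive partners

    def __post_init__(self) -> None:
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        if self.p.shape != (6,):
            raise ValueError("probability vector must have 6 components")

    @property
    def is_zero(self) -> bool:
        return bool(np.all(self.p == 0))


def interaction_scores(query: ProteinRecord | str, training: Dataset,
                       interactions: InteractionTable) -> tuple[list[str], np.ndarray]:
    """Confidence scores between the query and each training protein.

    Returns the training ids (in stable sorted order) and the aligned
    weight vector; absent interactions contribute 0 and the query itself is
    always excluded.
    """
    qid = query if isinstance(query, str) else query.id
    ids = sorted(pid for pid in training.ids if pid != qid)
    neighbors = interactions.neighbors(qid)
    weights = np.array([neighbors.get(pid, 0.0) for pid in ids], dtype=float)
    return ids, weights


def type_probabilities(weights: np.ndarray,
                       label_vectors: np.ndarray,
                       normalize: str = "sum") -> TypeProbabilityVector:
    """Confidence-weighted type vote over training partners.

    ``label_vectors`` is an (n, 6) 0/1 matrix aligned with ``weights``.
    ``normalize`` is ``"sum"`` (divide by the total confidence mass, the
    default, making each p_k a probability-like fraction) or ``"none"``
    (raw weighted counts, for sensitivity checks).
    """
    weights = np.asarray(weights, dtype=float)
    label_vectors = np.asarray(label_vectors, dtype=float)
    if np.any(weights < 0):
        raise ValueError("interaction confidence weights must be non-negative")
    if label_vectors.ndim != 2 or label_vectors.shape[1] != 6:
        raise ValueError("label matrix must be (n, 6)")
    if len(weights) != len(label_vectors):
        raise ValueError("weights and label vectors must be aligned")
    if normalize not in ("sum", "none"):
        raise ValueError(f"unknown normalizer: {normalize!r}")
    support = float(weights.sum())
    if support == 0:
        return TypeProbabilityVector(np.zeros(6), 0.0)
    votes = weights @ label_vectors
    p = votes / support if normalize == "sum" else votes
    return TypeProbabilityVector(p, support)


def select_top_types(p: np.ndarray, t: int) -> frozenset[MembraneType]:
    """The t highest-probability types with strictly positive support.

    Ties at the t-th rank are broken toward the smaller type index, so the
    result does not depend on storage order.  Fewer than t types are
    returned when fewer have positive probability.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if t > 6:
        raise ValueError("t cannot exceed the six membrane types")
    order = sorted(range(6), key=lambda k: (-p[k], k))
    chosen = [k for k in order[:t] if p[k] > 0]
    return frozenset(MembraneType(k + 1) for k in chosen)


def predict_by_network(query: ProteinRecord | str, training: Dataset,
                       interactions: InteractionTable, t: int,
                       normalize: str = "sum") -> Prediction | None:
    """Top-t confidence-weighted vote; None (abstention) when no partner exists."""
    ids, weights = interaction_scores(query, training, interactions)
    labels = np.array([training[pid].label_vector for pid in ids]) \
        if ids else np.zeros((0, 6))
    tpv = type_probabilities(weights, labels, normalize=normalize)
    if tpv.is_zero:
        return None
    chosen = select_top_types(tpv.p, t)
    return Prediction(labels=chosen, method="network",
                      diagnostics={"probabilities": tpv})
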
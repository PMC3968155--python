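"""Pseudo amino acid composition (PseAAC) and the nearest-neighbor baseline.

PseAAC extends plain amino-acid composition with tiered sequence-order
correlation factors.  For a property profile F over the sequence, the
tier-j factor is the mean squared property difference between residues j
positions apart:

    theta_j = 1/(L-j) * sum_{i=1..L-j} (F(P_{i+j}) - F(P_i))^2

Five physicochemical/biochemical property scales are used (polarity,
secondary structure, molecular volume, codon diversity, electrostatic
charge), each contributing lambda = 50 tiers, so a sequence maps to a
20 + 5*50 = 270-component vector

    x_u = f_u / D           (u <= 20, amino-acid frequencies)
    x_u = w * theta_(u-20) / D   (u > 20)

with D = sum f + w * sum theta, hence sum_u x_u = 1.  The sequence-order
weight w defaults to 0.15, the canonical choice of the original PseAAC
scheme.  The nearest-neighbor baseline transfers the label set of the
training protein whose PseAAC vector is closest to the query's (Euclidean
by default, cosine available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import (
    STANDARD_AMINO_ACIDS,
    Dataset,
    Prediction,
    ProteinRecord,
)

__all__ = [
    "PROPERTY_NAMES",
    "property_table",
    "standardize_property",
    "correlation_factors",
    "encode_pseaac",
    "PseAACEncoder",
    "predict_by_nna",
]

#: Property block order: polarity, secondary structure, molecular volume,
#: codon diversity, electrostatic charge.
PROPERTY_NAMES = (
    "polarity",
    "secondary_structure",
    "molecular_volume",
    "codon_diversity",
    "electrostatic_charge",
)

# Original (unstandardized) property values for the 20 amino acids, in
# alphabetical one-letter order A C D E F G H I K L M N P Q R S T V W Y.
# These are the five Atchley-style factor scores commonly used for PseAAC.
_RAW_PROPERTIES: dict[str, dict[str, float]] = {
    "polarity": {
        "A": -0.591, "C": -1.343, "D": 1.05, "E": 1.357, "F": -1.006,
        "G": -0.384, "H": 0.336, "I": -1.239, "K": 1.831, "L": -1.019,
        "M": -0.663, "N": 0.945, "P": 0.189, "Q": 0.931, "R": 1.538,
        "S": -0.228, "T": -0.032, "V": -1.337, "W": -0.595, "Y": 0.26,
    },
    "secondary_structure": {
        "A": -1.302, "C": 0.465, "D": 0.302, "E": -1.453, "F": -0.59,
        "G": 1.652, "H": -0.417, "I": -0.547, "K": -0.561, "L": -0.987,
        "M": -1.524, "N": 0.828, "P": 2.081, "Q": -0.179, "R": -0.055,
        "S": 1.399, "T": 0.326, "V": -0.279, "W": 0.009, "Y": 0.83,
    },
    "molecular_volume": {
        "A": -0.733, "C": -0.862, "D": -3.656, "E": 1.477, "F": 1.891,
        "G": 1.33, "H": -1.673, "I": 2.131, "K": 0.533, "L": -1.505,
        "M": 2.219, "N": 1.299, "P": -1.628, "Q": -3.005, "R": 1.502,
        "S": -4.76, "T": 2.213, "V": -0.544, "W": 0.672, "Y": 3.097,
    },
    "codon_diversity": {
        "A": 1.57, "C": -1.02, "D": -0.259, "E": 0.113, "F": -0.397,
        "G": 1.045, "H": -1.474, "I": 0.393, "K": -0.277, "L": 1.266,
        "M": -1.005, "N": -0.169, "P": 0.421, "Q": -0.503, "R": 0.44,
        "S": 0.67, "T": 0.908, "V": 1.242, "W": -2.128, "Y": -0.838,
    },
    "electrostatic_charge": {
        "A": -0.146, "C": -0.255, "D": -3.242, "E": -0.837, "F": 0.412,
        "G": 2.064, "H": -0.078, "I": 0.816, "K": 1.648, "L": -0.912,
        "M": 1.212, "N": 0.933, "P": -1.392, "Q": -1.853, "R": 2.897,
        "S": -2.647, "T": 1.313, "V": -1.262, "W": -0.184, "Y": 1.512,
    },
}


def property_table(standardize: bool = False) -> np.ndarray:
    """The five property columns as a (5, 20) array.

    Rows follow :data:`PROPERTY_NAMES`; columns follow the alphabetical
    amino-acid order of :data:`STANDARD_AMINO_ACIDS`.  With
    ``standardize=True`` each row is zero-mean/unit-variance over the 20
    amino acids (the published scales are already near-standardized; the
    two paths differ only by an affine map per property).
    """
    table = np.array([[_RAW_PROPERTIES[name][aa] for aa in STANDARD_AMINO_ACIDS]
                      for name in PROPERTY_NAMES])
    if standardize:
        table = np.array([standardize_property(row) for row in table])
    return table


def standardize_property(values: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance rescaling of a 20-value property column."""
    values = np.asarray(values, dtype=float)
    if values.shape != (20,):
        raise ValueError("a property column has exactly 20 amino-acid values")
    sd = values.std()  # population standard deviation over the 20 amino acids
    if sd == 0:
        raise ValueError("property column has zero variance")
    return (values - values.mean()) / sd


_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AMINO_ACIDS)}


def _clean_sequence(sequence: str) -> str:
    seq = sequence.upper()
    kept = [c for c in seq if c in _AA_INDEX]
    dropped = len(seq) - len(kept)
    if dropped:
        warnings.warn(f"dropped {dropped} non-standard residue(s) from sequence "
                      "before PseAAC encoding")
    return "".join(kept)


def correlation_factors(sequence: str, profile: np.ndarray, lam: int) -> np.ndarray:
    """Tiered correlation factors theta_1..theta_lam for one property profile.

    ``profile`` maps the 20 amino acids (alphabetical order) to property
    values.  The sequence must be strictly longer than ``lam`` so every
    tier averages at least one pair.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (20,):
        raise ValueError("property profile must have 20 values")
    idx = np.array([_AA_INDEX[c] for c in sequence], dtype=np.intp)
    L = len(idx)
    if L <= lam:
        raise ValueError(
            f"sequence of effective length {L} too short for lambda={lam} "
            "(need length > lambda)")
    f = profile[idx]
    theta = np.empty(lam)
    for j in range(1, lam + 1):
        diffs = f[j:] - f[:-j]
        theta[j - 1] = float(np.mean(diffs * diffs))
    return theta


def encode_pseaac(sequence: str, table: np.ndarray | None = None,
                  lam: int = 50, w: float = 0.15,
                  standardize: bool = True) -> np.ndarray:
    """Encode a sequence as a (20 + 5*lam)-component PseAAC vector.

    The first 20 components are relative amino-acid frequencies; the
    remaining 5*lam are the correlation factors of the five property
    blocks, in :data:`PROPERTY_NAMES` order, all jointly normalized to sum
    to 1.  Non-standard residues are dropped (with a warning) before both
    the frequency and the correlation computation.
    """
    if w < 0:
        raise ValueError("sequence-order weight w must be non-negative")
    seq = _clean_sequence(sequence)
    if table is None:
        table = property_table(standardize=standardize)
    table = np.asarray(table, dtype=float)
    if table.shape != (5, 20):
        raise ValueError("property table must be (5 properties, 20 amino acids)")

    counts = np.zeros(20)
    for c in seq:
        counts[_AA_INDEX[c]] += 1
    if counts.sum() == 0:
        raise ValueError("sequence has no standard residues")
    freqs = counts / counts.sum()

    thetas = np.concatenate([correlation_factors(seq, row, lam) for row in table])
    denom = freqs.sum() + w * thetas.sum()
    return np.concatenate([freqs, w * thetas]) / denom


@dataclass
class PseAACEncoder:
    """Configured encoder, convenient for encoding whole datasets once."""

    lam: int = 50
    w: float = 0.15
    standardize: bool = True

    def __post_init__(self) -> None:
        self.table = property_table(standardize=self.standardize)

    @property
    def n_components(self) -> int:
        return 20 + 5 * self.lam

    def encode(self, sequence: str) -> np.ndarray:
        return encode_pseaac(sequence, table=self.table, lam=self.lam, w=self.w)

    def encode_dataset(self, dataset: Dataset) -> tuple[list[str], np.ndarray]:
        ids = sorted(dataset.ids)
        return ids, np.array([self.encode(dataset[pid].sequence) for pid in ids])


def vector_distance(x: np.ndarray, y: np.ndarray, metric: str = "euclidean") -> float:
    if metric == "euclidean":
        return float(np.linalg.norm(x - y))
    if metric == "cosine":
        nx_, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx_ == 0 or ny == 0:
            raise ValueError("cosine distance undefined for zero vectors")
        return float(1.0 - np.dot(x, y) / (nx_ * ny))
    raise ValueError(f"unknown metric: {metric!r}")


def predict_by_nna(query: ProteinRecord, training: Dataset,
                   encoder: PseAACEncoder | None = None,
                   metric: str = "euclidean") -> Prediction:
    """Nearest-neighbor label transfer in PseAAC space.

    Copies the label set of the training protein whose encoding is closest
    to the query's; ties are broken by lexicographic id.
    """
    encoder = encoder or PseAACEncoder()
    if not query.sequence:
        raise ValueError(f"query {query.id} has no sequence")
    qvec = encoder.encode(query.sequence)
    best: tuple[float, str] | None = None
    for rec in training:
        if rec.id == query.id:
            continue
        d = vector_distance(qvec, encoder.encode(rec.sequence), metric)
        if best is None or (d, rec.id) < best:
            best = (d, rec.id)
    if best is None:
        raise ValueError("empty training set")
    rec = training[best[1]]
    if rec.labels is None:
        raise ValueError(f"training protein {rec.id} is unlabelled")
    return Prediction(labels=rec.labels, method="nna",
                      diagnostics={"nearest": best[1], "distance": best[0]})
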
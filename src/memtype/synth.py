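"""Synthetic benchmark generator: homologous families in a label-assortative
interaction network.

The generator emulates the structure of a curated multi-label membrane
protein study: proteins fall into homologous families (each family a set of
point-mutated copies of a random ancestor sequence) sharing a family label
set of 1-3 of the six types, with a label-multiplicity distribution whose
default mean (1.033 labels/protein) sits in the range observed for curated
human membrane protein sets, so the top-t voting rule resolves to t = 2.
The interaction network is label-assortative: pairs sharing at least one
type are connected with probability ``p_same``, others with ``p_diff``,
and every edge carries a STRING-style confidence score drawn uniformly
from [150, 999].  Optional decoy homologs — heavily diverged copies of a family
ancestor carrying a label set disjoint from the family's — plant the
false-homology hazard that a loose E-value gate admits.

Everything is reproducible from the seed, and a truth object records
family membership so tests can verify planted structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import (
    STANDARD_AMINO_ACIDS,
    Dataset,
    InteractionTable,
    MembraneType,
    ProteinRecord,
)
from .io import write_annotations, write_fasta, write_interactions

__all__ = ["SynthConfig", "SynthTruth", "generate_dataset", "write_fixture"]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic benchmark."""

    n_proteins: int = 120
    n_families: int = 30
    sequence_length: int = 120          # > lambda = 50, so PseAAC is defined
    mutation_rate: float = 0.05         # per-site substitution within a family
    #: probability of carrying 1, 2 or 3 types; mean 1.033 labels/protein
    labels_per_family: dict[int, float] = field(
        default_factory=lambda: {1: 0.970, 2: 0.027, 3: 0.003})
    p_same: float = 0.8                 # edge probability, label-sharing pair
    p_diff: float = 0.02                # edge probability otherwise
    confidence_low: int = 150           # confidence scores uniform on
    confidence_high: int = 999          # [low, high], STRING 0-1000 scale
    decoy_fraction: float = 0.0         # fraction of families given a decoy
    decoy_divergence: float = 0.9       # per-site substitution for decoys
    seed: int = 0

    def validate(self) -> None:
        if self.n_families > self.n_proteins:
            raise ValueError("more families than proteins")
        if self.n_families < 1:
            raise ValueError("need at least one family")
        if self.sequence_length <= 50:
            raise ValueError("sequence_length must exceed 50")
        for p in (self.mutation_rate, self.p_same, self.p_diff,
                  self.decoy_fraction, self.decoy_divergence):
            if not (0 <= p <= 1):
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.p_same < self.p_diff:
            raise ValueError("p_same must be >= p_diff (label assortativity)")
        if not (0 < self.confidence_low <= self.confidence_high <= 1000):
            raise ValueError("confidence bounds must satisfy 0 < low <= high <= 1000")
        sizes, probs = zip(*sorted(self.labels_per_family.items()))
        if set(sizes) - {1, 2, 3}:
            raise ValueError("label multiplicities must be in {1, 2, 3}")
        if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
            raise ValueError("labels_per_family must be a probability distribution")


@dataclass
class SynthTruth:
    """Planted structure: which family each protein came from."""

    family_of: dict[str, int]
    family_labels: dict[int, frozenset[MembraneType]]
    decoys: set[str] = field(default_factory=set)

    def members(self, family: int) -> list[str]:
        return sorted(p for p, f in self.family_of.items() if f == family)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(STANDARD_AMINO_ACIDS), size=length))


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    if rate == 0:
        return sequence
    seq = list(sequence)
    hits = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hits):
        choices = [a for a in STANDARD_AMINO_ACIDS if a != seq[i]]
        seq[i] = rng.choice(choices)
    return "".join(seq)


def generate_dataset(config: SynthConfig) -> tuple[Dataset, InteractionTable, SynthTruth]:
    """Generate a labelled dataset, its interaction network, and the truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # family sizes: distribute proteins round-robin so every family is non-empty
    sizes = np.full(config.n_families, config.n_proteins // config.n_families)
    sizes[: config.n_proteins % config.n_families] += 1

    mult_values, mult_probs = zip(*sorted(config.labels_per_family.items()))
    all_types = list(MembraneType)

    dataset = Dataset(name=f"synth-seed{config.seed}")
    truth = SynthTruth(family_of={}, family_labels={})
    ancestors: dict[int, str] = {}
    counter = 0
    for fam in range(config.n_families):
        k = int(rng.choice(mult_values, p=mult_probs))
        labels = frozenset(MembraneType(int(t))
                           for t in rng.choice(all_types, size=k, replace=False))
        truth.family_labels[fam] = labels
        ancestors[fam] = _random_sequence(rng, config.sequence_length)
        for _ in range(sizes[fam]):
            pid = f"SYN{counter:04d}"
            counter += 1
            seq = _mutate(rng, ancestors[fam], config.mutation_rate)
            dataset.add(ProteinRecord(pid, seq, labels))
            truth.family_of[pid] = fam

    # decoys: diverged copies of a family ancestor with a disjoint label set,
    # attached to the smallest families (those least protected by a true homolog)
    n_decoys = int(round(config.decoy_fraction * config.n_families))
    for fam in range(config.n_families - n_decoys, config.n_families):
        pid = f"DEC{fam:04d}"
        seq = _mutate(rng, ancestors[fam], config.decoy_divergence)
        remaining = [t for t in all_types if t not in truth.family_labels[fam]]
        labels = frozenset({MembraneType(int(rng.choice(remaining)))})
        dataset.add(ProteinRecord(pid, seq, labels))
        truth.family_of[pid] = -1 - fam  # decoys get their own pseudo-family
        truth.decoys.add(pid)

    interactions = InteractionTable()
    ids = dataset.ids
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            share = bool(dataset[a].labels & dataset[b].labels)
            p_edge = config.p_same if share else config.p_diff
            if rng.random() < p_edge:
                w = int(rng.integers(config.confidence_low, config.confidence_high + 1))
                interactions.set(a, b, w)
    return dataset, interactions, truth


def write_fixture(directory: str | Path, dataset: Dataset,
                  interactions: InteractionTable) -> dict[str, Path]:
    """Write FASTA + annotation table + edge list; round-trips exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": directory / "proteins.fasta",
        "annotations": directory / "annotations.tsv",
        "interactions": directory / "interactions.tsv",
    }
    write_fasta(paths["fasta"], dataset)
    write_annotations(paths["annotations"], dataset)
    write_interactions(paths["interactions"], interactions)
    return paths
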
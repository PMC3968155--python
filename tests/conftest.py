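from __future__ import annotations

import numpy as np
import pytest

from memtype import (
    Dataset,
    InteractionTable,
    MembraneType,
    ProteinRecord,
)

T = MembraneType


def make_dataset(*records: tuple) -> Dataset:
    """Build a Dataset from (id, sequence, labels) tuples; labels may be None."""
    return Dataset(
        ProteinRecord(pid, seq, None if labels is None else frozenset(labels))
        for pid, seq, labels in records
    )


def make_interactions(*edges: tuple[str, str, float]) -> InteractionTable:
    table = InteractionTable()
    for a, b, w in edges:
        table.set(a, b, w)
    return table


@pytest.fixture
def toy_training() -> Dataset:
    """Four labelled proteins with distinctive sequences."""
    return make_dataset(
        ("A1", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", {T.MULTI_PASS}),
        ("B2", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVA", {T.MULTI_PASS}),
        ("C3", "GGGGGSSSSSPPPPPLLLLLKKKKKDDDDDEEE", {T.PERIPHERAL}),
        ("D4", "WWWWWYYYYYFFFFFHHHHHCCCCCNNNNNQQQ", {T.GPI_ANCHOR, T.LIPID_ANCHOR}),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_protein_sequence(rng: np.random.Generator, length: int) -> str:
    from memtype.datamodel import STANDARD_AMINO_ACIDS

    return "".join(rng.choice(list(STANDARD_AMINO_ACIDS), size=length))
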
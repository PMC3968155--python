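"""Readers and writers for the package's plain-text interchange formats.

Three formats are supported: FASTA for sequences (via Biopython), a
tab-delimited annotation table (protein id, semicolon-joined membrane types
given as names or 1-based indices), and a 3-column whitespace-delimited
interaction edge list in the style of STRING ``protein.links`` files
(idA, idB, combined score).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datamodel import (
    Dataset,
    InteractionTable,
    MembraneType,
    ProteinRecord,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "write_annotations",
    "read_interactions",
    "write_interactions",
]


def read_fasta(path: str | Path, name: str | None = None) -> Dataset:
    """Read a FASTA file into a :class:`Dataset` of unlabelled records.

    The header token up to the first whitespace is the protein id;
    sequences are uppercased.  Non-standard residues (B, Z, X, U, O, ``*``)
    are preserved but flagged with a warning.
    """
    path = Path(path)
    dataset = Dataset(name=name or path.stem)
    for seqrec in SeqIO.parse(str(path), "fasta"):
        rec = ProteinRecord(id=seqrec.id, sequence=str(seqrec.seq))
        if rec.has_nonstandard_residues:
            warnings.warn(f"protein {rec.id}: sequence contains non-standard residues")
        dataset.add(rec)  # raises on duplicate id, naming it
    if len(dataset) == 0:
        raise ValueError(f"no FASTA entries found in {path}")
    return dataset


def write_fasta(path: str | Path, dataset: Dataset) -> None:
    records = [SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in dataset]
    SeqIO.write(records, str(path), "fasta")


def read_annotations(path: str | Path, delimiter: str = "\t",
                     type_sep: str = ";") -> dict[str, frozenset[MembraneType]]:
    """Read a per-protein type table: one row per protein, id then types.

    Types may be given as names ("single-pass type I") or 1-based indices
    ("5"), several of them joined by ``type_sep``.  Every row must decode to
    a non-empty label set.
    """
    path = Path(path)
    out: dict[str, frozenset[MembraneType]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected id{delimiter!r}types, got {line!r}")
            pid = parts[0].strip()
            tokens = [t for t in parts[1].split(type_sep) if t.strip()]
            if not pid or not tokens:
                raise ValueError(f"{path}:{lineno}: row with no recognizable types")
            try:
                labels = frozenset(MembraneType.from_token(t) for t in tokens)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if pid in out:
                raise ValueError(f"{path}:{lineno}: duplicate annotation for {pid}")
            out[pid] = labels
    if not out:
        raise ValueError(f"no annotation rows found in {path}")
    return out


def write_annotations(path: str | Path,
                      labels: Mapping[str, Iterable[MembraneType]] | Dataset,
                      type_sep: str = ";") -> None:
    if isinstance(labels, Dataset):
        labels = {rec.id: rec.labels for rec in labels if rec.labels is not None}
    with open(path, "w") as fh:
        for pid in labels:
            names = type_sep.join(t.display_name for t in sorted(labels[pid]))
            fh.write(f"{pid}\t{names}\n")


def read_interactions(path: str | Path, scale: str = "auto") -> InteractionTable:
    """Read a 3-column edge list of pairwise interaction confidence scores.

    ``scale`` is one of:

    - ``raw1000``: scores already on the STRING 0-1000 scale;
    - ``unit``: scores in (0, 1], multiplied by 1000 on ingest;
    - ``auto``: ``unit`` when every score is <= 1, else ``raw1000``.

    Rows with score <= 0 are dropped (a pair is interactive only when its
    confidence is greater than zero).  Duplicate (a,b)/(b,a) rows must
    agree; otherwise the maximum is kept with a warning.
    """
    if scale not in ("auto", "raw1000", "unit"):
        raise ValueError(f"unknown scale: {scale!r}")
    path = Path(path)
    rows: list[tuple[int, str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, raw = parts
            try:
                w = float(raw)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric score {raw!r}") from None
            rows.append((lineno, a, b, w))

    if scale == "auto":
        positive = [w for _, _, _, w in rows if w > 0]
        scale = "unit" if positive and max(positive) <= 1.0 else "raw1000"

    table = InteractionTable()
    seen: dict[tuple[str, str], float] = {}
    for lineno, a, b, w in rows:
        if scale == "unit":
            if w > 1.0:
                raise ValueError(f"{path}:{lineno}: score {w} > 1 under unit scale")
            w *= 1000.0
        elif w > 1000.0:
            raise ValueError(f"{path}:{lineno}: score {w} > 1000 under raw1000 scale")
        if w <= 0:
            continue  # non-interactive pair
        if a == b:
            raise ValueError(f"{path}:{lineno}: self-interaction {a}")
        key = InteractionTable._key(a, b)
        if key in seen and seen[key] != w:
            warnings.warn(
                f"{path}:{lineno}: conflicting scores for ({a},{b}): "
                f"{seen[key]} vs {w}; keeping the maximum")
            w = max(w, seen[key])
        seen[key] = w
        table.set(a, b, w)
    return table


def write_interactions(path: str | Path, table: InteractionTable) -> None:
    with open(path, "w") as fh:
        for a, b, w in table:
            fh.write(f"{a}\t{b}\t{w:g}\n")
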
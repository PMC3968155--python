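"""Homology-based annotation transfer.

A query is annotated by copying the full label set of its best-scoring
homolog in the training set, provided the hit is statistically significant
(E-value at most 0.01 by default).  If no hit passes the gate the method
abstains — homology transfer deliberately trades coverage for accuracy.

Alignment scores come through a provider contract so that externally
computed BLAST/PSI-BLAST tabular reports and the built-in Smith-Waterman
aligner are interchangeable.  The built-in aligner (Biopython's
``PairwiseAligner``, local mode, BLOSUM62, affine gaps 11/1) attaches an
approximate E-value via the Karlin-Altschul formula
``E = K * m * n * exp(-lambda * S)`` with the standard gapped
BLOSUM62(11,1) parameters lambda = 0.267, K = 0.041; m and n are the query
and subject lengths.  These constants only gate the significance decision;
the transferred labels depend on score ranking alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, runtime_checkable

from Bio import Align
from Bio.Align import substitution_matrices

from .datamodel import Dataset, Prediction, ProteinRecord

__all__ = [
    "AlignmentHit",
    "HomologyProvider",
    "BuiltinAligner",
    "BlastTabularProvider",
    "parse_blast_tabular",
    "local_align_score",
    "predict_by_homology",
    "KARLIN_ALTSCHUL_LAMBDA",
    "KARLIN_ALTSCHUL_K",
]

# Gapped Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1.
KARLIN_ALTSCHUL_LAMBDA = 0.267
KARLIN_ALTSCHUL_K = 0.041

#: Residue substitutions applied before alignment: selenocysteine scores as
#: cysteine, pyrrolysine as lysine; stop marks are removed.  B, Z and X are
#: present in BLOSUM62 and pass through unchanged.
_SANITIZE = str.maketrans({"U": "C", "O": "K", "*": None})


@dataclass(frozen=True)
class AlignmentHit:
    """One query-subject alignment: bit score and E-value."""

    query_id: str
    subject_id: str
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("E-value must be non-negative")
        if not math.isfinite(self.score):
            raise ValueError("alignment score must be finite")
        if self.query_id == self.subject_id:
            raise ValueError(f"self-hit not allowed: {self.query_id}")


@runtime_checkable
class HomologyProvider(Protocol):
    """Anything that can score a query against a training set.

    Implementations must never return a hit whose subject is the query
    itself; this is what makes leave-one-out evaluation safe.
    """

    def hits(self, query: ProteinRecord, training: Dataset) -> list[AlignmentHit]:
        ...


def parse_blast_tabular(path: str | Path,
                        query_ids: Iterable[str] | None = None,
                        subject_ids: Iterable[str] | None = None) -> list[AlignmentHit]:
    """Parse a standard 12-column BLAST tabular report (``-outfmt 6``).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Only (qseqid, sseqid, evalue, bitscore)
    are retained; multiple HSPs for a pair collapse to the best bit score
    (smaller E-value breaking ties); self-hits are discarded.
    """
    path = Path(path)
    qset = set(query_ids) if query_ids is not None else None
    sset = set(subject_ids) if subject_ids is not None else None
    best: dict[tuple[str, str], AlignmentHit] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            qid, sid = fields[0], fields[1]
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric evalue/bitscore "
                    f"({fields[10]!r}, {fields[11]!r})") from None
            if qid == sid:
                continue
            if qset is not None and qid not in qset:
                raise ValueError(f"{path}:{lineno}: unknown query id {qid!r}")
            if sset is not None and sid not in sset:
                raise ValueError(f"{path}:{lineno}: unknown subject id {sid!r}")
            hit = AlignmentHit(qid, sid, score=bitscore, evalue=evalue)
            key = (qid, sid)
            if key not in best or (hit.score, -hit.evalue) > (best[key].score, -best[key].evalue):
                best[key] = hit
    return list(best.values())


def _make_aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # first gap residue costs open+extend, matching BLAST's 11/1 convention
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align_score(seq_a: str, seq_b: str, matrix: str = "BLOSUM62",
                      gap_open: float = 11, gap_extend: float = 1) -> tuple[float, float]:
    """Optimal Smith-Waterman local alignment score and approximate E-value.

    Returns ``(raw_score, evalue)``.  The E-value uses the Karlin-Altschul
    form with the module-level lambda and K constants (calibrated for the
    default BLOSUM62 11/1 scoring; other matrices reuse them as a rough
    guide).
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    a = seq_a.upper().translate(_SANITIZE)
    b = seq_b.upper().translate(_SANITIZE)
    if not a or not b:
        raise ValueError("sequences empty after removing stop marks")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    raw = float(aligner.score(a, b))
    evalue = KARLIN_ALTSCHUL_K * len(a) * len(b) * math.exp(-KARLIN_ALTSCHUL_LAMBDA * raw)
    return raw, evalue


def raw_to_bit_score(raw: float) -> float:
    """Normalized (bit) score for a raw alignment score."""
    return (KARLIN_ALTSCHUL_LAMBDA * raw - math.log(KARLIN_ALTSCHUL_K)) / math.log(2)


class BuiltinAligner:
    """Smith-Waterman provider over a training set, with pairwise caching.

    Scores are symmetric, so each unordered sequence pair is aligned once
    and reused across leave-one-out rounds.
    """

    def __init__(self, matrix: str = "BLOSUM62", gap_open: float = 11,
                 gap_extend: float = 1):
        self.matrix = matrix
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self._aligner = _make_aligner(matrix, gap_open, gap_extend)
        self._cache: dict[tuple[str, str], float] = {}

    def _raw_score(self, seq_a: str, seq_b: str) -> float:
        key = (seq_a, seq_b) if seq_a <= seq_b else (seq_b, seq_a)
        raw = self._cache.get(key)
        if raw is None:
            raw = float(self._aligner.score(key[0], key[1]))
            self._cache[key] = raw
        return raw

    def hits(self, query: ProteinRecord, training: Dataset) -> list[AlignmentHit]:
        if not query.sequence:
            raise ValueError(f"query {query.id} has no sequence")
        qseq = query.sequence.translate(_SANITIZE)
        out: list[AlignmentHit] = []
        for subject in training:
            if subject.id == query.id or not subject.sequence:
                continue
            sseq = subject.sequence.translate(_SANITIZE)
            raw = self._raw_score(qseq, sseq)
            evalue = (KARLIN_ALTSCHUL_K * len(qseq) * len(sseq)
                      * math.exp(-KARLIN_ALTSCHUL_LAMBDA * raw))
            out.append(AlignmentHit(query.id, subject.id,
                                    score=raw_to_bit_score(raw), evalue=evalue))
        return out


class BlastTabularProvider:
    """Provider backed by a pre-parsed BLAST/PSI-BLAST tabular report."""

    def __init__(self, hits: Iterable[AlignmentHit] | str | Path):
        if isinstance(hits, (str, Path)):
            hits = parse_blast_tabular(hits)
        self._by_query: dict[str, list[AlignmentHit]] = {}
        for hit in hits:
            self._by_query.setdefault(hit.query_id, []).append(hit)

    def hits(self, query: ProteinRecord, training: Dataset) -> list[AlignmentHit]:
        return [h for h in self._by_query.get(query.id, ())
                if h.subject_id in training and h.subject_id != query.id]


def best_hit(hits: Iterable[AlignmentHit],
             evalue_cutoff: float | None = None) -> AlignmentHit | None:
    """Best hit: maximal score, ties by smaller E-value then subject id."""
    passing = [h for h in hits
               if evalue_cutoff is None or h.evalue <= evalue_cutoff]
    if not passing:
        return None
    return min(passing, key=lambda h: (-h.score, h.evalue, h.subject_id))


def predict_by_homology(query: ProteinRecord, training: Dataset,
                        provider: HomologyProvider,
                        evalue_cutoff: float = 0.01) -> Prediction | None:
    """Transfer the label set of the best significant homolog; None = abstain.

    A sequence-less query is an error, distinct from abstention: abstention
    means the search ran and found nothing significant.
    """
    if not query.sequence:
        raise ValueError(f"query {query.id} has no sequence; homology transfer impossible")
    hit = best_hit(provider.hits(query, training), evalue_cutoff)
    if hit is None:
        return None
    subject = training[hit.subject_id]
    if subject.labels is None:
        raise ValueError(f"training protein {subject.id} is unlabelled")
    return Prediction(labels=subject.labels, method="homology",
                      diagnostics={"best_hit": hit})
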
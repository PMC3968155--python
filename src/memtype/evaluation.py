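"""Multi-label evaluation metrics and the leave-one-out harness.

With L_i the actual and L_i* the predicted label set of the i-th protein,
the per-record precision is |L_i ∩ L_i*| / |L_i*| and the recall
|L_i ∩ L_i*| / |L_i|, averaged over annotated proteins.  Neither is usable
alone: predicting every type makes recall 1, and predicting any non-empty
subset of the truth makes precision 1.  The accuracy used here rewards
coverage of the true types and penalizes spurious ones:

    Acc = 1/n * sum_i [ |L_i ∩ L_i*| / |L_i|  -  |L_i* \\ L_i| / |L_i*| ]

The first term is close to recall; the second vanishes exactly when the
prediction equals the truth and grows with each incorrectly predicted
type.  A Jaccard variant (mean |L_i ∩ L_i*| / |L_i ∪ L_i*|) is reported
alongside; the two agree at the extremes (1 for exact matches, and
minimal — -1 resp. 0 — for disjoint predictions).

Leave-one-out hides one protein's labels at a time and predicts them from
the remaining labelled proteins.  Network topology stays intact (only
label knowledge is removed) and the homology provider excludes self-hits.
Methods that can abstain leave proteins unannotated (NU); their accuracy
is computed over annotated proteins only, with NU reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    Dataset,
    InteractionTable,
    MembraneType,
    Prediction,
)
from .graphdist import build_weighted_graph, predict_by_shortest_distance
from .homology import BuiltinAligner, HomologyProvider, predict_by_homology
from .integrated import CascadeConfig, predict_by_rwc, predict_integrated
from .network import predict_by_network
from .pseaac import PseAACEncoder

__all__ = [
    "PredictionRecord",
    "EvaluationReport",
    "precision_recall",
    "multilabel_accuracy",
    "breakdown_by_type_count",
    "loo_evaluate",
    "evalue_sweep",
    "METHODS",
]

METHODS = ("integrated", "homology", "network", "shortest", "nna", "rwc")

ACC_VARIANTS = ("recall_minus_penalty", "jaccard")


@dataclass(frozen=True)
class PredictionRecord:
    """Actual vs predicted label sets for one protein.

    ``predicted`` is ``None`` when the method abstained; ``stage`` names
    the method (or cascade stage) that produced the prediction.
    """

    id: str
    actual: frozenset[MembraneType]
    predicted: frozenset[MembraneType] | None
    stage: str = ""
    fallback: bool = False

    def __post_init__(self) -> None:
        if not self.actual:
            raise ValueError(f"{self.id}: actual label set must be non-empty")
        if self.predicted is not None and not self.predicted:
            raise ValueError(f"{self.id}: predicted label set, when present, must be non-empty")

    @property
    def annotated(self) -> bool:
        return self.predicted is not None


def _annotated(records: Iterable[PredictionRecord]) -> list[PredictionRecord]:
    out = [r for r in records if r.annotated]
    if not out:
        raise ValueError("no annotated prediction records")
    return out


def precision_recall(records: Iterable[PredictionRecord]) -> tuple[float, float]:
    """Mean per-record multi-label precision and recall over annotated records."""
    recs = _annotated(records)
    precision = float(np.mean([len(r.actual & r.predicted) / len(r.predicted) for r in recs]))
    recall = float(np.mean([len(r.actual & r.predicted) / len(r.actual) for r in recs]))
    return precision, recall


def record_accuracy(record: PredictionRecord, variant: str = "recall_minus_penalty") -> float:
    """Per-record accuracy contribution under either variant."""
    if record.predicted is None:
        raise ValueError(f"{record.id}: abstention has no accuracy contribution")
    inter = len(record.actual & record.predicted)
    if variant == "recall_minus_penalty":
        wrong = len(record.predicted - record.actual)
        return inter / len(record.actual) - wrong / len(record.predicted)
    if variant == "jaccard":
        return inter / len(record.actual | record.predicted)
    raise ValueError(f"unknown accuracy variant: {variant!r}")


def multilabel_accuracy(records: Iterable[PredictionRecord],
                        variant: str = "recall_minus_penalty") -> float:
    recs = _annotated(records)
    return float(np.mean([record_accuracy(r, variant) for r in recs]))


@dataclass(frozen=True)
class CPECounts:
    """Completely correct / partly correct / entirely wrong counts."""

    c: int
    p: int
    e: int

    @property
    def total(self) -> int:
        return self.c + self.p + self.e


def breakdown_by_type_count(records: Iterable[PredictionRecord]) -> dict[int, CPECounts]:
    """c/p/e counts grouped by the number of actual types (1, 2, 3, ...).

    c: prediction equals the truth; p: overlapping but not equal;
    e: disjoint.  Abstentions are excluded.
    """
    groups: dict[int, list[PredictionRecord]] = {}
    for r in records:
        if r.annotated:
            groups.setdefault(len(r.actual), []).append(r)
    out: dict[int, CPECounts] = {}
    for mult, recs in sorted(groups.items()):
        c = sum(1 for r in recs if r.predicted == r.actual)
        e = sum(1 for r in recs if not (r.predicted & r.actual))
        out[mult] = CPECounts(c=c, p=len(recs) - c - e, e=e)
    return out


@dataclass
class StageStats:
    na: int
    accuracy: float | None
    accuracy_jaccard: float | None


@dataclass
class EvaluationReport:
    """Aggregate leave-one-out results for one method."""

    method: str
    n_total: int
    records: list[PredictionRecord]
    nu: int
    accuracy: float | None
    accuracy_jaccard: float | None
    precision: float | None
    recall: float | None
    per_stage: dict[str, StageStats] = field(default_factory=dict)
    breakdown: dict[int, CPECounts] = field(default_factory=dict)

    @property
    def n_annotated(self) -> int:
        return self.n_total - self.nu

    def stage_table(self) -> pd.DataFrame:
        rows = [{"stage": s, "NA": st.na, "Acc": st.accuracy,
                 "Acc_jaccard": st.accuracy_jaccard}
                for s, st in self.per_stage.items()]
        return pd.DataFrame(rows)


def _aggregate(method: str, n_total: int,
               records: Sequence[PredictionRecord]) -> EvaluationReport:
    annotated = [r for r in records if r.annotated]
    nu = n_total - len(annotated)
    if annotated:
        precision, recall = precision_recall(annotated)
        acc = multilabel_accuracy(annotated)
        accj = multilabel_accuracy(annotated, "jaccard")
    else:
        precision = recall = acc = accj = None
    per_stage: dict[str, StageStats] = {}
    for stage in sorted({r.stage for r in annotated}):
        recs = [r for r in annotated if r.stage == stage]
        per_stage[stage] = StageStats(
            na=len(recs),
            accuracy=multilabel_accuracy(recs),
            accuracy_jaccard=multilabel_accuracy(recs, "jaccard"))
    return EvaluationReport(
        method=method, n_total=n_total, records=list(records), nu=nu,
        accuracy=acc, accuracy_jaccard=accj, precision=precision, recall=recall,
        per_stage=per_stage, breakdown=breakdown_by_type_count(records))


def loo_evaluate(dataset: Dataset,
                 interactions: InteractionTable | None = None,
                 method: str = "integrated",
                 config: CascadeConfig = CascadeConfig(),
                 provider: HomologyProvider | None = None) -> EvaluationReport:
    """Leave-one-out evaluation of one prediction method.

    Every protein in ``dataset`` must be labelled.  For each protein its
    labels are hidden, the chosen method predicts them from the remaining
    n-1 labelled proteins (the query's interactions stay in the network;
    only its label knowledge is removed), and metrics are aggregated.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    for rec in dataset:
        if rec.labels is None:
            raise ValueError(f"protein {rec.id} is unlabelled")
    interactions = interactions if interactions is not None else InteractionTable()
    graph = build_weighted_graph(interactions, transform=config.distance_transform)
    needs_alignment = method in ("integrated", "homology", "rwc")
    if provider is None and needs_alignment:
        provider = BuiltinAligner()
    t = config.resolve_t(dataset)  # fixed dataset-level t, as in a real study

    nna_ids: list[str] = []
    nna_matrix: np.ndarray | None = None
    if method == "nna":
        encoder = PseAACEncoder()
        nna_ids, nna_matrix = encoder.encode_dataset(dataset)

    records: list[PredictionRecord] = []
    for pid in dataset.ids:
        query, training = dataset.hide_labels(pid)
        actual = dataset[pid].labels
        pred: Prediction | None
        if method == "integrated":
            pred = predict_integrated(query, training, provider=provider,
                                      interactions=interactions, config=config,
                                      graph=graph)
        elif method == "homology":
            pred = predict_by_homology(query, training, provider,
                                       evalue_cutoff=config.evalue_cutoff)
        elif method == "network":
            pred = predict_by_network(query, training, interactions, t=t,
                                      normalize=config.network_normalize)
        elif method == "shortest":
            pred = predict_by_shortest_distance(query, training, graph)
        elif method == "rwc":
            pred = predict_by_rwc(query, training, provider=provider,
                                  interactions=interactions, graph=graph,
                                  weights=config.rwc_weights)
        else:  # nna, on the precomputed matrix
            qi = nna_ids.index(pid)
            dists = np.linalg.norm(nna_matrix - nna_matrix[qi], axis=1)
            order = sorted((j for j in range(len(nna_ids)) if j != qi),
                           key=lambda j: (dists[j], nna_ids[j]))
            nearest = nna_ids[order[0]]
            pred = Prediction(labels=dataset[nearest].labels, method="nna",
                              diagnostics={"nearest": nearest,
                                           "distance": float(dists[order[0]])})
        records.append(PredictionRecord(
            id=pid, actual=actual,
            predicted=None if pred is None else pred.labels,
            stage=pred.stage if pred is not None else "",
            fallback=pred.fallback if pred is not None else False))
    return _aggregate(method, len(dataset), records)


def evalue_sweep(dataset: Dataset, provider: HomologyProvider | None = None,
                 cutoffs: Sequence[float] = (1e-10, 1e-5, 0.01, 1.0, 10.0),
                 ) -> pd.DataFrame:
    """Homology-only leave-one-out accuracy/coverage across E-value gates.

    Loosening the gate can only annotate more proteins, so NU is
    non-increasing in the cutoff; accuracy typically falls once weak,
    potentially spurious hits start to pass.  Returns a DataFrame with
    columns cutoff, Acc, Acc_jaccard, NU, NA (Acc is NaN when nothing is
    annotated).
    """
    if len(cutoffs) < 2:
        raise ValueError("need at least two cutoffs to sweep")
    provider = provider or BuiltinAligner()
    rows = []
    for cutoff in cutoffs:
        report = loo_evaluate(dataset, method="homology",
                              config=CascadeConfig(evalue_cutoff=cutoff),
                              provider=provider)
        rows.append({"cutoff": cutoff,
                     "Acc": np.nan if report.accuracy is None else report.accuracy,
                     "Acc_jaccard": (np.nan if report.accuracy_jaccard is None
                                     else report.accuracy_jaccard),
                     "NU": report.nu, "NA": report.n_annotated})
    return pd.DataFrame(rows)
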
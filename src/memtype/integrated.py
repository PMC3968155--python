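"""The three-stage integrated predictor and the RWC comparison method.

The cascade tries, in order:

1. **homology** — if the training set contains a significant homolog
   (E-value at most the gate, 0.01 by default), its labels are transferred
   and nothing else runs;
2. **network** — otherwise, if the query has at least one interactive
   training partner, the confidence-weighted top-t vote decides;
3. **shortest_distance** — otherwise label transfer from the nearest
   training protein in the distance-weighted interaction graph, which
   never abstains.

Exactly one stage fires per query, so per-stage annotation counts always
partition a dataset.

RWC (real weighted combination) is the flat alternative: one fused
closeness score per training candidate,

    S = alpha * s_hat + beta * w_hat + gamma * (1 - d_hat)

where s_hat, w_hat, d_hat are the alignment score, interaction confidence
and shortest distance, each min-max normalized over the candidate set, and
the weights default to (1/3, 1/3, 1/3).  The candidate with maximal S
donates its labels.  A component that is undefined for a candidate (no
alignment, no edge, unreachable) contributes its worst normalized value.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .datamodel import (
    Dataset,
    InteractionTable,
    Prediction,
    ProteinRecord,
    top_t,
)
from .graphdist import build_weighted_graph, predict_by_shortest_distance, shortest_distance
from .homology import BuiltinAligner, HomologyProvider, predict_by_homology
from .network import predict_by_network

__all__ = [
    "CascadeConfig",
    "CascadePrediction",
    "predict_integrated",
    "rwc_scores",
    "predict_by_rwc",
]

#: CascadePrediction is a Prediction whose ``stage`` names the cascade
#: stage that fired: homology, network, or shortest_distance.
CascadePrediction = Prediction


@dataclass(frozen=True)
class CascadeConfig:
    """Knobs of the integrated predictor and its comparison methods."""

    evalue_cutoff: float = 0.01
    t: int | None = None  # None: ceiling of the training set's mean label count
    distance_transform: str = "linear"  # confidence -> edge length
    network_normalize: str = "sum"
    rwc_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if self.evalue_cutoff < 0:
            raise ValueError("E-value cutoff must be non-negative")
        if any(w < 0 for w in self.rwc_weights):
            raise ValueError("RWC weights must be non-negative")

    def resolve_t(self, training: Dataset) -> int:
        return self.t if self.t is not None else top_t(training)


def predict_integrated(query: ProteinRecord, training: Dataset,
                       provider: HomologyProvider | None = None,
                       interactions: InteractionTable | None = None,
                       config: CascadeConfig = CascadeConfig(),
                       graph: nx.Graph | None = None) -> CascadePrediction:
    """Run the cascade for one query; exactly one stage produces the labels.

    ``graph`` may be passed pre-built (it must match ``interactions`` and
    the configured distance transform) to avoid rebuilding per query.
    """
    interactions = interactions if interactions is not None else InteractionTable()
    provider = provider or BuiltinAligner()

    if query.sequence:
        pred = predict_by_homology(query, training, provider,
                                   evalue_cutoff=config.evalue_cutoff)
        if pred is not None:
            return pred

    pred = predict_by_network(query, training, interactions,
                              t=config.resolve_t(training),
                              normalize=config.network_normalize)
    if pred is not None:
        return pred

    if graph is None:
        graph = build_weighted_graph(interactions, transform=config.distance_transform)
    return predict_by_shortest_distance(query, training, graph)


def _minmax(values: dict[str, float], invert: bool = False) -> dict[str, float]:
    """Min-max normalize defined values to [0, 1]; best maps to 1.

    When all defined values are equal they all map to 1 (they are jointly
    at the optimum of the candidate set).  ``invert`` flips orientation so
    that *smaller* raw values (distances) are better.
    """
    if not values:
        return {}
    lo, hi = min(values.values()), max(values.values())
    if hi == lo:
        return {k: 1.0 for k in values}
    out = {k: (v - lo) / (hi - lo) for k, v in values.items()}
    if invert:
        out = {k: 1.0 - v for k, v in out.items()}
    return out


def rwc_scores(query: ProteinRecord, training: Dataset,
               provider: HomologyProvider | None = None,
               interactions: InteractionTable | None = None,
               graph: nx.Graph | None = None,
               weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
               ) -> dict[str, float]:
    """Fused closeness score S for every training candidate.

    Components: alignment score (bit score from the provider), direct
    interaction confidence, and shortest graph distance (inverted after
    normalization so that closer is better).  Missing components score 0.
    """
    alpha, beta, gamma = weights
    if alpha < 0 or beta < 0 or gamma < 0:
        raise ValueError("RWC weights must be non-negative")
    interactions = interactions if interactions is not None else InteractionTable()
    candidates = [pid for pid in training.ids if pid != query.id]
    if not candidates:
        raise ValueError("empty candidate set")

    align_raw: dict[str, float] = {}
    if query.sequence and provider is not None:
        align_raw = {h.subject_id: h.score for h in provider.hits(query, training)}

    conf_raw = {pid: w for pid, w in interactions.neighbors(query.id).items()
                if pid in training and pid != query.id}

    dist_raw: dict[str, float] = {}
    if graph is None:
        graph = build_weighted_graph(interactions)
    if query.id in graph:
        sd = shortest_distance(graph, query.id)
        dist_raw = {pid: sd.distance(pid) for pid in candidates if sd.reachable(pid)}

    if not align_raw and not conf_raw and not dist_raw:
        raise ValueError(
            f"query {query.id}: no alignment, interaction or graph evidence "
            "for any candidate; RWC score undefined")

    s_hat = _minmax(align_raw)
    w_hat = _minmax(conf_raw)
    d_inv = _minmax(dist_raw, invert=True)
    return {pid: alpha * s_hat.get(pid, 0.0)
                 + beta * w_hat.get(pid, 0.0)
                 + gamma * d_inv.get(pid, 0.0)
            for pid in candidates}


def predict_by_rwc(query: ProteinRecord, training: Dataset,
                   provider: HomologyProvider | None = None,
                   interactions: InteractionTable | None = None,
                   graph: nx.Graph | None = None,
                   weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
                   ) -> Prediction:
    """Transfer the labels of the candidate with maximal fused score.

    Ties are broken by lexicographic id.
    """
    scores = rwc_scores(query, training, provider=provider,
                        interactions=interactions, graph=graph, weights=weights)
    best = min(scores, key=lambda pid: (-scores[pid], pid))
    rec = training[best]
    if rec.labels is None:
        raise ValueError(f"training protein {best} is unlabelled")
    return Prediction(labels=rec.labels, method="rwc",
                      diagnostics={"best_candidate": best, "score": scores[best]})
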
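"""Shortest-distance label transfer on the interaction graph.

Confidence scores are turned into edge lengths so that a stronger
interaction means a shorter edge: d = 1000 - w by default (w on the STRING
0-1000 scale), with d = 1000/w available as an alternative transform for
sensitivity analysis.  Dijkstra's algorithm then yields the shortest
distance between any two proteins, and a query inherits the full label set
of the nearest labelled training protein.  Because even indirectly
connected proteins get a finite distance, this method annotates every
protein reachable from the training set; fully disconnected queries fall
back to the most frequent single type in training, flagged as such.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from .datamodel import (
    Dataset,
    InteractionTable,
    MembraneType,
    Prediction,
    ProteinRecord,
)

__all__ = [
    "build_weighted_graph",
    "shortest_distance",
    "ShortestDistanceResult",
    "predict_by_shortest_distance",
    "confidence_to_distance",
]


def confidence_to_distance(w: float, transform: str = "linear") -> float:
    """Edge length for a confidence score w in (0, 1000].

    ``linear``: d = 1000 - w (default); ``inverse``: d = 1000 / w.  Both are
    strictly decreasing in w, so higher confidence always means a shorter
    edge.
    """
    if not (0 < w <= 1000):
        raise ValueError(f"confidence score must be in (0, 1000], got {w}")
    if transform == "linear":
        return 1000.0 - w
    if transform == "inverse":
        return 1000.0 / w
    raise ValueError(f"unknown distance transform: {transform!r}")


def build_weighted_graph(interactions: InteractionTable,
                         transform: str = "linear") -> nx.Graph:
    """Distance-weighted interaction graph.

    An edge exists iff the confidence score is positive (which is all an
    :class:`InteractionTable` stores).  Each edge carries both the distance
    ``weight`` and the original ``confidence``.
    """
    graph = nx.Graph(transform=transform)
    for a, b, w in interactions:
        graph.add_edge(a, b, weight=confidence_to_distance(w, transform), confidence=w)
    return graph


@dataclass
class ShortestDistanceResult:
    """Single-source shortest distances with predecessors for path recovery."""

    source: str
    distances: dict[str, float]
    predecessors: dict[str, list[str]] = field(default_factory=dict)

    def distance(self, target: str) -> float:
        """Shortest distance to ``target``; ``inf`` when unreachable."""
        return self.distances.get(target, math.inf)

    def reachable(self, target: str) -> bool:
        return target in self.distances

    def path(self, target: str) -> list[str]:
        if target not in self.distances:
            raise ValueError(f"{target} is unreachable from {self.source}")
        path = [target]
        while path[-1] != self.source:
            path.append(self.predecessors[path[-1]][0])
        return path[::-1]


def shortest_distance(graph: nx.Graph, source: str) -> ShortestDistanceResult:
    """Exact single-source shortest distances by Dijkstra's algorithm."""
    if source not in graph:
        raise ValueError(f"source {source!r} not in graph")
    pred, dist = nx.dijkstra_predecessor_and_distance(graph, source, weight="weight")
    return ShortestDistanceResult(source=source, distances=dict(dist),
                                  predecessors={k: v for k, v in pred.items() if v})


def _most_frequent_type(training: Dataset) -> MembraneType:
    counts: Counter[MembraneType] = Counter()
    for rec in training:
        if rec.labels is None:
            raise ValueError(f"training protein {rec.id} is unlabelled")
        counts.update(rec.labels)
    # ties toward the smaller type index, for determinism
    return min(counts, key=lambda t: (-counts[t], int(t)))


def predict_by_shortest_distance(query: ProteinRecord | str, training: Dataset,
                                 graph: nx.Graph) -> Prediction:
    """Copy the labels of the training protein nearest in graph distance.

    Never abstains: a query unreachable from every training protein (or
    absent from the graph entirely) receives the most frequent single type
    of the training set, flagged as a fallback.  Ties in distance are broken
    by larger direct confidence with the query, then lexicographic id.
    """
    if len(training) == 0:
        raise ValueError("empty training set")
    qid = query if isinstance(query, str) else query.id

    nearest: str | None = None
    sd: ShortestDistanceResult | None = None
    if qid in graph:
        sd = shortest_distance(graph, qid)
        candidates = [pid for pid in training.ids if pid != qid and sd.reachable(pid)]
        if candidates:
            def rank(pid: str) -> tuple[float, float, str]:
                direct = graph.get_edge_data(qid, pid, default={}).get("confidence", 0.0)
                return (sd.distance(pid), -direct, pid)

            nearest = min(candidates, key=rank)

    if nearest is None or sd is None:
        return Prediction(labels=frozenset({_most_frequent_type(training)}),
                          method="shortest_distance", fallback=True,
                          diagnostics={"reason": "unreachable from training set"})
    rec = training[nearest]
    if rec.labels is None:
        raise ValueError(f"training protein {nearest} is unlabelled")
    return Prediction(labels=rec.labels, method="shortest_distance",
                      diagnostics={"nearest": nearest, "distance": sd.distance(nearest)})
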
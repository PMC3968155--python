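"""Independent brute-force oracles used to validate the fast implementations.

These are deliberately simple and slow: a full Gotoh dynamic-programming
table for local alignment, exhaustive simple-path enumeration for shortest
distances, and a directly indexed double loop for sequence-order
correlation factors.  They share no code with the package paths they check
(the substitution matrix values are the only common input).
"""

from __future__ import annotations

import itertools

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_affine_oracle(a: str, b: str, gap_open: float = 11, gap_extend: float = 1) -> float:
    """Optimal local alignment score, affine gaps, full O(nm) Gotoh DP."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    open_cost = gap_open + gap_extend  # first gap residue pays open + extend
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in sequence a
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in sequence b
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - gap_extend)
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def shortest_distance_oracle(edges: dict[tuple[str, str], float],
                             source: str) -> dict[str, float]:
    """Shortest distances by exhaustive enumeration of all simple paths."""
    adj: dict[str, dict[str, float]] = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w
    best: dict[str, float] = {source: 0.0}

    def walk(node: str, visited: set[str], dist: float) -> None:
        for nbr, w in adj.get(node, {}).items():
            if nbr in visited:
                continue
            d = dist + w
            if d < best.get(nbr, float("inf")):
                best[nbr] = d
            walk(nbr, visited | {nbr}, d)

    if source in adj:
        walk(source, {source}, 0.0)
    return best


def theta_oracle(sequence: str, profile: dict[str, float], lam: int) -> list[float]:
    """Correlation factors via a direct, index-by-index double loop."""
    L = len(sequence)
    out = []
    for j in range(1, lam + 1):
        total = 0.0
        for i in range(L - j):
            diff = profile[sequence[i + j]] - profile[sequence[i]]
            total += diff * diff
        out.append(total / (L - j))
    return out


def all_nonempty_label_subsets(types) -> list[frozenset]:
    """All 63 non-empty subsets of the six membrane types."""
    members = list(types)
    subsets = []
    for r in range(1, len(members) + 1):
        subsets.extend(frozenset(c) for c in itertools.combinations(members, r))
    return subsets
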
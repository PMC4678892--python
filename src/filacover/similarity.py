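"""Partition-similarity measures over edge covers, classical and structure-aware.

Two filament covers of the same graph are two (potentially overlapping)
partitions of its edge set. Classical measures compare all pairs of edges:
the Rand index RI, the Jaccard index JI, and -- for exact covers only --
the variation of information VI. These ignore *where* the edges sit in the
graph, so distant, unrelated edge pairs dominate the counts. The
structure-aware variants RI^d and JI^d restrict the contingency counts to
edge pairs separated by at most d nodes: d = 1 keeps only pairs of adjacent
edges (local perspective) and d = infinity recovers RI and JI exactly
(global perspective).

For overlapping covers, two edges count as "same" in a labelling when their
membership sets intersect (the minimal consistent extension of the exact
case).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .core_model import FilamentCover, FilamentGraph, edge_key
from .errors import CoverConsistencyError, FilacoverError

#: sentinel for pairs of edges in different connected components
INF = math.inf

#: EdgeCoverLabels: map from each edge to the non-empty set of filament ids
EdgeCoverLabels = Mapping[tuple[int, int], frozenset[int]]


def cover_labels(cover: FilamentCover) -> dict[tuple[int, int], frozenset[int]]:
    """Edge-membership labelling of a cover."""
    return cover.edge_membership()


def is_exact_labelling(labels: EdgeCoverLabels) -> bool:
    return all(len(s) == 1 for s in labels.values())


@dataclass(frozen=True)
class ContingencyCounts:
    """Edge-pair agreement counts between two labellings at distance bound d.

    ``same_same`` counts unordered pairs of distinct edges assigned to a
    common filament in both labellings, and so on; only pairs separated by
    at most ``d`` nodes in the graph are admissible.
    """

    same_same: int
    same_diff: int
    diff_same: int
    diff_diff: int
    d: float

    @property
    def total(self) -> int:
        return self.same_same + self.same_diff + self.diff_same + self.diff_diff

    def swapped(self) -> "ContingencyCounts":
        return ContingencyCounts(
            self.same_same, self.diff_same, self.same_diff, self.diff_diff, self.d
        )


def edge_distance(graph: FilamentGraph, e: tuple[int, int], f: tuple[int, int]) -> float:
    """Minimum shortest-path length (in edges) between endpoints of e and f.

    D = 0 for edges sharing a node (and for e = f); edges are "separated by
    at most d nodes" iff D <= d - 1, so d = 1 admits exactly the adjacent
    pairs. Returns ``inf`` for edges in different components.
    """
    g = graph.graph
    for e_ in (e, f):
        if not g.has_edge(*e_):
            raise CoverConsistencyError(f"edge {e_} not in graph")
    if set(e) & set(f):
        return 0.0
    best = INF
    for a in e:
        lengths = nx.single_source_shortest_path_length(g, a)
        for b in f:
            if b in lengths:
                best = min(best, lengths[b])
    return float(best)


def _admissible_pairs(
    graph: FilamentGraph, edges: list[tuple[int, int]], d: float
) -> list[tuple[int, int]]:
    """Index pairs (i < j) of edges separated by at most d nodes."""
    m = len(edges)
    if math.isinf(d):
        return [(i, j) for i in range(m) for j in range(i + 1, m)]
    cutoff = d - 1
    if cutoff < 0:
        return []
    # node-to-node shortest path lengths up to the cutoff, then min over
    # the four endpoint combinations per edge pair
    node_dist = dict(nx.all_pairs_shortest_path_length(graph.graph, cutoff=int(cutoff)))
    pairs = []
    for i in range(m):
        a1, a2 = edges[i]
        da1 = node_dist.get(a1, {})
        da2 = node_dist.get(a2, {})
        for j in range(i + 1, m):
            b1, b2 = edges[j]
            dmin = min(
                da1.get(b1, INF),
                da1.get(b2, INF),
                da2.get(b1, INF),
                da2.get(b2, INF),
            )
            if dmin <= cutoff:
                pairs.append((i, j))
    return pairs


def contingency_counts(
    A: EdgeCoverLabels,
    B: EdgeCoverLabels,
    graph: FilamentGraph,
    d: float = INF,
) -> ContingencyCounts:
    """Count same/different edge-pair agreement restricted to distance d.

    A pair is "same" in a labelling iff the two edges' membership sets
    intersect. Raises :class:`CoverConsistencyError` when the two labellings
    do not cover the same edge set.
    """
    a_keys = {edge_key(*e) for e in A}
    b_keys = {edge_key(*e) for e in B}
    if a_keys != b_keys:
        raise CoverConsistencyError("labellings cover different edge sets")
    edges = sorted(a_keys)
    a_sets = [frozenset(A[e]) for e in edges]
    b_sets = [frozenset(B[e]) for e in edges]
    counts = [[0, 0], [0, 0]]
    for i, j in _admissible_pairs(graph, edges, d):
        same_a = bool(a_sets[i] & a_sets[j])
        same_b = bool(b_sets[i] & b_sets[j])
        counts[0 if same_a else 1][0 if same_b else 1] += 1
    return ContingencyCounts(
        same_same=counts[0][0],
        same_diff=counts[0][1],
        diff_same=counts[1][0],
        diff_diff=counts[1][1],
        d=d,
    )


def rand_index(h: ContingencyCounts) -> float:
    """RI = (h== + h!=) / total agreeing fraction of admissible pairs."""
    if h.total == 0:
        raise FilacoverError("Rand index undefined: no admissible edge pairs")
    return (h.same_same + h.diff_diff) / h.total


def jaccard_index(h: ContingencyCounts) -> float:
    """JI = h_same_same / (h_same_same + h_same_diff + h_diff_same)."""
    if h.total == 0:
        raise FilacoverError("Jaccard index undefined: no admissible edge pairs")
    denom = h.same_same + h.same_diff + h.diff_same
    if denom == 0:
        # neither labelling groups any admissible pair; identical by vacuity
        return 1.0
    return h.same_same / denom


def structure_aware_indices(
    A: EdgeCoverLabels,
    B: EdgeCoverLabels,
    graph: FilamentGraph,
    d: float = 1,
) -> tuple[float, float]:
    """(RI^d, JI^d) in one pass."""
    h = contingency_counts(A, B, graph, d)
    return rand_index(h), jaccard_index(h)


def variation_of_information(A: EdgeCoverLabels, B: EdgeCoverLabels) -> float:
    """VI = H(A) + H(B) - 2 I(A;B), natural logarithm, exact covers only.

    Probabilities are filament edge-count fractions over the common edge
    set. Raises for overlapping labellings, where VI is not well-defined.
    """
    for name, labels in (("first", A), ("second", B)):
        if not is_exact_labelling(labels):
            raise FilacoverError(
                f"variation of information is not well-defined for overlapping "
                f"partitions ({name} labelling has multiply-covered edges)"
            )
    a_keys = {edge_key(*e) for e in A}
    b_keys = {edge_key(*e) for e in B}
    if a_keys != b_keys:
        raise CoverConsistencyError("labellings cover different edge sets")
    n = len(a_keys)
    joint: dict[tuple[int, int], int] = {}
    ca: dict[int, int] = {}
    cb: dict[int, int] = {}
    for e in a_keys:
        (i,) = A[e]
        (j,) = B[e]
        joint[(i, j)] = joint.get((i, j), 0) + 1
        ca[i] = ca.get(i, 0) + 1
        cb[j] = cb.get(j, 0) + 1
    h_a = -sum((c / n) * math.log(c / n) for c in ca.values())
    h_b = -sum((c / n) * math.log(c / n) for c in cb.values())
    mi = sum(
        (c / n) * math.log(c * n / (ca[i] * cb[j]))
        for (i, j), c in joint.items()
    )
    return max(0.0, h_a + h_b - 2.0 * mi)


def match_filaments(
    A: FilamentCover, B: FilamentCover
) -> dict[int, int]:
    """Match filament identities between two covers of the same graph.

    Solves the rectangular linear assignment problem maximising the total
    number of edges shared by matched filament pairs; returns a map from
    A-filament ids to B-filament ids. Surplus filaments on either side stay
    unmatched (absent from the map).
    """
    shared = np.zeros((A.n_filaments, B.n_filaments))
    b_edge_sets = [set(p.edges) for p in B.paths]
    for i, pa in enumerate(A.paths):
        ea = set(pa.edges)
        for j, eb in enumerate(b_edge_sets):
            shared[i, j] = len(ea & eb)
    rows, cols = linear_sum_assignment(shared, maximize=True)
    return {int(i): int(j) for i, j in zip(rows, cols) if shared[i, j] > 0}
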
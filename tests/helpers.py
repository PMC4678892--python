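"""Shared test utilities: tiny random instances and brute-force oracles.

The brute-force cover oracle enumerates every subset of the candidate pool,
checks the covering constraints directly, and minimises the total and the
average roughness by exhaustion. It shares no code with the MILP path it
checks.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from filacover import EdgePath, FilamentGraph
from filacover.path_sampling import CandidatePathSet, canonicalize_path


def chain_graph(weights, spacing=1.0):
    """Straight horizontal chain with the given edge weights."""
    n = len(weights) + 1
    pos = {i: (i * spacing, 0.0) for i in range(n)}
    edges = [(i, i + 1, float(w)) for i, w in enumerate(weights)]
    return FilamentGraph.from_data(pos, edges)


def path_on(graph, nodes):
    path = EdgePath(tuple(nodes))
    path.validate_in(graph)
    return path


def x_graph(angle_deg=40.0, w_a=0.8, w_b=0.3):
    """Two straight 2-edge filaments crossing at the origin.

    Filament A lies along the x-axis with weight ``w_a`` on both edges;
    filament B crosses it at ``angle_deg`` with weight ``w_b``. The centre
    node is 0; A runs 1-0-2, B runs 3-0-4.
    """
    a = np.radians(angle_deg)
    d = np.array([np.cos(a), np.sin(a)])
    pos = {0: (0.0, 0.0), 1: (-1.0, 0.0), 2: (1.0, 0.0),
           3: tuple(-d), 4: tuple(d)}
    edges = [(1, 0, w_a), (0, 2, w_a), (3, 0, w_b), (0, 4, w_b)]
    return FilamentGraph.from_data(pos, edges)


def random_tiny_instance(rng, max_edges=8, max_paths=15):
    """Random small positioned graph plus a covering candidate pool.

    The pool always contains all singletons (hence covers every edge) and is
    padded with randomly chosen simple paths up to ``max_paths`` elements.
    """
    n = int(rng.integers(4, 8))
    g = nx.random_labeled_tree(n, seed=int(rng.integers(2**31 - 1)))
    nodes = list(g.nodes)
    for _ in range(int(rng.integers(0, 3))):
        u, v = rng.choice(nodes, 2, replace=False)
        if u != v and not g.has_edge(u, v) and g.number_of_edges() < max_edges:
            g.add_edge(u, v)
    pos = {i: rng.uniform(0.0, 10.0, 2) for i in g.nodes}
    graph = FilamentGraph.from_data(
        pos, [(u, v, float(rng.uniform(0.05, 1.0))) for u, v in g.edges()]
    )
    paths = {canonicalize_path(EdgePath((u, v))) for u, v in graph.edges}
    candidates = []
    for s in g.nodes:
        for t in g.nodes:
            if s < t:
                for p in nx.all_simple_paths(g, s, t, cutoff=5):
                    if len(p) >= 3:
                        candidates.append(tuple(p))
    order = rng.permutation(len(candidates))
    for idx in order:
        if len(paths) >= max_paths:
            break
        paths.add(canonicalize_path(EdgePath(candidates[idx])))
    ordered = tuple(sorted(paths, key=lambda p: (p.n_edges, p.nodes)))
    return graph, CandidatePathSet(ordered, provenance="bfs")


def brute_force_cover_optimum(program, exact):
    """(min total, min average) roughness over all feasible subsets."""
    n_paths = program.n_variables
    incidence = program.matrix.toarray()
    masks = np.arange(1, 2**n_paths, dtype=np.int64)
    sel = ((masks[:, None] >> np.arange(n_paths)) & 1).astype(bool)
    coverage = sel @ incidence.T
    feasible = (coverage == 1).all(axis=1) if exact else (coverage >= 1).all(axis=1)
    totals = sel[feasible] @ program.costs
    sizes = sel[feasible].sum(axis=1)
    return float(totals.min()), float((totals / sizes).min())
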
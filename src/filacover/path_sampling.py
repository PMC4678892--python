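"""Candidate path pools for the filament cover problem.

The set-cover approximation needs a representative set of candidate
edge-paths. Two samplers are provided:

* ``bfs`` -- breadth-wise extension of partial paths from every starting
  edge, pruning any extension whose newest deflection angle reaches the
  straightness threshold (default 60 deg, strict). Closed loops are admitted
  when a path returns to its own start node and the seam deflection also
  passes the threshold. This enumerates *every* path of the graph whose
  maximal deflection stays below the threshold, so gently curved loops are
  found in their entirety.
* ``rmst`` -- repeated random minimum spanning trees: each repetition draws
  i.i.d. uniform(0,1) auxiliary edge weights, computes the minimum spanning
  tree (per connected component), and contributes the unique tree path
  between every node pair. Trees are loop-free, so closed filaments can only
  be recovered piecewise.

Single-edge paths are always appended, which guarantees that every edge is
coverable and realises the single-edge roughness convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core_model import CoverOptions, EdgePath, FilamentGraph
from .errors import PathEnumerationLimitError
from .roughness import euclidean_angle

#: default safety cap on the number of BFS-enumerated paths
DEFAULT_BFS_PATH_CAP = 1_000_000


def canonicalize_path(path: EdgePath) -> EdgePath:
    """Canonical orientation: a path and its reversal are one object.

    Open paths take the lexicographically smaller of the two node sequences.
    Closed loops are additionally rotated to start at their minimal node id
    before the same comparison, so all traversals of one loop coincide.
    """
    if not path.is_closed:
        fwd = path.nodes
        rev = path.nodes[::-1]
        return path if fwd <= rev else EdgePath(rev)
    cycle = path.nodes[:-1]
    best: tuple[int, ...] | None = None
    for seq in (cycle, cycle[::-1]):
        k = seq.index(min(seq))
        rot = seq[k:] + seq[:k]
        if best is None or rot < best:
            best = rot
    return EdgePath(best + (best[0],))


@dataclass(frozen=True)
class CandidatePathSet:
    """Deduplicated candidate paths in canonical orientation."""

    paths: tuple[EdgePath, ...]
    provenance: str
    includes_singletons: bool = True

    @property
    def n_paths(self) -> int:
        return len(self.paths)


def _finish(
    paths: set[EdgePath], graph: FilamentGraph, provenance: str
) -> CandidatePathSet:
    for u, v in graph.edges:
        paths.add(canonicalize_path(EdgePath((u, v))))
    ordered = tuple(sorted(paths, key=lambda p: (p.n_edges, p.nodes)))
    return CandidatePathSet(ordered, provenance=provenance)


def sample_paths_bfs(
    graph: FilamentGraph,
    angle_max_deg: float = 60.0,
    path_cap: int = DEFAULT_BFS_PATH_CAP,
) -> CandidatePathSet:
    """All edge-paths with maximal deflection strictly below ``angle_max_deg``.

    Partial paths are extended breadth-wise from every starting edge; an
    extension is pruned as soon as its newest deflection angle reaches the
    threshold, which is sound because the maximal deflection of a path never
    decreases under extension. Raises :class:`PathEnumerationLimitError` if
    more than ``path_cap`` paths would be collected.
    """
    g = graph.graph
    pos = {n: graph.position(n) for n in g.nodes}
    found: set[EdgePath] = set()

    def _register(nodes: tuple[int, ...]) -> None:
        found.add(canonicalize_path(EdgePath(nodes)))
        if len(found) > path_cap:
            raise PathEnumerationLimitError(
                f"BFS path enumeration exceeded the safety cap of {path_cap}"
            )

    # frontier entries: (node sequence, set of used edges)
    frontier: list[tuple[tuple[int, ...], frozenset]] = []
    for u, v in graph.edges:
        _register((u, v))
        frontier.append(((u, v), frozenset({(u, v)})))
        frontier.append(((v, u), frozenset({(u, v)})))

    while frontier:
        new_frontier: list[tuple[tuple[int, ...], frozenset]] = []
        for nodes, used in frontier:
            tail = nodes[-1]
            seg_in = pos[tail] - pos[nodes[-2]]
            for nxt in g.neighbors(tail):
                e = (tail, nxt) if tail <= nxt else (nxt, tail)
                if e in used:
                    continue
                seg_out = pos[nxt] - pos[tail]
                if euclidean_angle(seg_in, seg_out) >= angle_max_deg:
                    continue
                if nxt == nodes[0]:
                    # loop closure: seam deflection must also pass
                    seg_first = pos[nodes[1]] - pos[nodes[0]]
                    if len(nodes) >= 3 and euclidean_angle(seg_out, seg_first) < angle_max_deg:
                        _register(nodes + (nxt,))
                    continue
                if nxt in nodes:
                    # node revisit (self-crossing) is allowed; edges stay unique
                    pass
                ext = nodes + (nxt,)
                _register(ext)
                new_frontier.append((ext, used | {e}))
        frontier = new_frontier

    return _finish(found, graph, "bfs")


def sample_paths_rmst(
    graph: FilamentGraph,
    n_trees: int = 100,
    seed: int = 0,
) -> CandidatePathSet:
    """Paths of ``n_trees`` random minimum spanning trees.

    One seeded generator drives the whole call; tree repetitions consume it
    sequentially, so results are reproducible from (graph, n_trees, seed).
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    g = graph.graph
    edge_list = graph.edges
    found: set[EdgePath] = set()
    for _ in range(n_trees):
        aux = rng.uniform(size=len(edge_list))
        work = nx.Graph()
        work.add_nodes_from(g.nodes)
        for (u, v), a in zip(edge_list, aux):
            work.add_edge(u, v, aux=a)
        tree = nx.minimum_spanning_tree(work, weight="aux")
        for comp in nx.connected_components(tree):
            comp = sorted(comp)
            sub = tree.subgraph(comp)
            for i, src in enumerate(comp):
                reached = nx.single_source_shortest_path(sub, src)
                for dst in comp[i + 1:]:
                    seq = reached.get(dst)
                    if seq is not None and len(seq) >= 2:
                        found.add(canonicalize_path(EdgePath(tuple(seq))))
    return _finish(found, graph, "rmst")


def sample_paths(graph: FilamentGraph, options: CoverOptions) -> CandidatePathSet:
    """Sample candidates according to ``options.sampling``."""
    if options.sampling == "bfs":
        return sample_paths_bfs(
            graph, angle_max_deg=options.angle_max_deg, path_cap=options.bfs_path_cap
        )
    return sample_paths_rmst(graph, n_trees=options.n_trees, seed=options.seed)
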
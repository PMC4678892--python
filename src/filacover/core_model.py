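"""Graph, path, and cover data model plus GML/CSV input and output.

A filamentous network is a weighted geometric graph: nodes carry 2D or 3D
positions, edges carry positive weights encoding the local intensity or
thickness of the filament segment they represent. A single filament is an
edge-path -- an ordered run of pairwise-adjacent, non-repeating edges,
possibly closed into a loop -- and a filament cover is a set of edge-paths
covering every edge of the graph at least once (exactly once for an exact
cover).

GML is the interchange format: node coordinates are accepted either as
top-level ``x``/``y``(/``z``) attributes or nested inside a ``graphics``
block; the writer always emits top-level coordinates. Edge weights live in
the ``weight`` attribute. Weights are never rescaled on load -- the
single-edge roughness convention makes results scale-dependent, so
normalisation is the caller's decision (see :func:`normalize_weights`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import (
    CoverConsistencyError,
    GMLFormatError,
    GraphValidationError,
)

#: number of significant digits used when printing floats to GML/CSV
PRINT_SIG_DIGITS = 6


def _sig(value: float) -> float:
    """Round to the declared text-serialisation precision."""
    return float(f"{float(value):.{PRINT_SIG_DIGITS}g}")


def edge_key(u: int, v: int) -> tuple[int, int]:
    """Canonical unordered representation of an edge."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class EdgePath:
    """An ordered sequence of adjacent, non-repeating edges (one filament).

    Stored as the traversed node sequence ``(n_0, ..., n_P)``; the i-th edge
    is ``{n_{i-1}, n_i}``. A closed path (loop filament) repeats its start
    node at the end: ``n_0 == n_P`` with P >= 3.
    """

    nodes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) < 2:
            raise GraphValidationError("an edge-path needs at least one edge")
        for a, b in zip(self.nodes, self.nodes[1:]):
            if a == b:
                raise GraphValidationError("self-loop step in edge-path")
        edges = self.edges
        if len(set(edges)) != len(edges):
            raise GraphValidationError("edge repeated within one edge-path")

    @property
    def n_edges(self) -> int:
        return len(self.nodes) - 1

    @property
    def edges(self) -> tuple[tuple[int, int], ...]:
        return tuple(edge_key(a, b) for a, b in zip(self.nodes, self.nodes[1:]))

    @property
    def is_closed(self) -> bool:
        return len(self.nodes) > 2 and self.nodes[0] == self.nodes[-1]

    def reverse(self) -> "EdgePath":
        return EdgePath(self.nodes[::-1])

    def weights(self, graph: "FilamentGraph") -> np.ndarray:
        """Edge weights in traversal order."""
        return np.array([graph.weight(u, v) for u, v in self.edges], dtype=float)

    def segments(self, graph: "FilamentGraph") -> np.ndarray:
        """Oriented segment vectors (path-start to path-end node per edge)."""
        pos = [graph.position(n) for n in self.nodes]
        return np.diff(np.asarray(pos, dtype=float), axis=0)

    def validate_in(self, graph: "FilamentGraph") -> None:
        for u, v in self.edges:
            if not graph.graph.has_edge(u, v):
                raise CoverConsistencyError(
                    f"path references edge {(u, v)} absent from graph"
                )

    def __len__(self) -> int:
        return self.n_edges


class FilamentGraph:
    """Undirected geometric graph with node positions and positive weights.

    Thin wrapper around :class:`networkx.Graph`; node attribute ``pos`` is a
    float array of uniform dimensionality (2 or 3), edge attribute ``weight``
    a finite positive float.
    """

    def __init__(self, graph: nx.Graph, validate: bool = True):
        if graph.is_multigraph() or graph.is_directed():
            raise GraphValidationError("graph must be simple and undirected")
        self.graph = graph
        if validate:
            self.validate()

    @classmethod
    def from_data(
        cls,
        positions: Mapping[int, Sequence[float]],
        weighted_edges: Iterable[tuple[int, int, float]],
    ) -> "FilamentGraph":
        g = nx.Graph()
        for n, p in positions.items():
            g.add_node(int(n), pos=np.asarray(p, dtype=float))
        for u, v, w in weighted_edges:
            if g.has_edge(u, v):
                raise GraphValidationError(f"parallel edge {(u, v)}")
            g.add_edge(int(u), int(v), weight=float(w))
        return cls(g)

    def validate(self) -> None:
        g = self.graph
        dims = set()
        for n, data in g.nodes(data=True):
            pos = data.get("pos")
            if pos is None:
                raise GraphValidationError(f"node {n} has no position")
            pos = np.asarray(pos, dtype=float)
            if pos.ndim != 1 or pos.size not in (2, 3) or not np.all(np.isfinite(pos)):
                raise GraphValidationError(f"node {n} has invalid position {pos}")
            g.nodes[n]["pos"] = pos
            dims.add(pos.size)
        if len(dims) > 1:
            raise GraphValidationError(f"mixed position dimensionalities {dims}")
        for u, v, data in g.edges(data=True):
            if u == v:
                raise GraphValidationError(f"self-loop at node {u}")
            w = data.get("weight")
            if w is None:
                raise GMLFormatError(f"edge {(u, v)} has no weight")
            w = float(w)
            if not math.isfinite(w) or w <= 0:
                raise GraphValidationError(f"edge {(u, v)} weight {w} not positive")
            data["weight"] = w

    # -- accessors ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def ndim(self) -> int:
        for _, data in self.graph.nodes(data=True):
            return int(np.asarray(data["pos"]).size)
        return 2

    @property
    def edges(self) -> tuple[tuple[int, int], ...]:
        return tuple(sorted(edge_key(u, v) for u, v in self.graph.edges()))

    def position(self, n: int) -> np.ndarray:
        return self.graph.nodes[n]["pos"]

    def weight(self, u: int, v: int) -> float:
        return self.graph.edges[u, v]["weight"]

    def edge_length(self, u: int, v: int) -> float:
        return float(np.linalg.norm(self.position(u) - self.position(v)))

    def copy(self) -> "FilamentGraph":
        return FilamentGraph(self.graph.copy(), validate=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FilamentGraph(N={self.n_nodes}, E={self.n_edges}, dim={self.ndim})"


def normalize_weights(graph: FilamentGraph) -> FilamentGraph:
    """Return a copy with weights rescaled so the maximum weight is 1."""
    out = graph.copy()
    wmax = max(d["weight"] for _, _, d in out.graph.edges(data=True))
    for _, _, d in out.graph.edges(data=True):
        d["weight"] = d["weight"] / wmax
    return out


@dataclass(frozen=True)
class CoverOptions:
    """The categorical option combinations of the filament cover problem.

    ``sampling``  -- candidate path pool: angle-constrained BFS or random
                     minimum spanning trees (RMST).
    ``cover``     -- 'over' allows overlapping filaments (>= 1 covering
                     constraint per edge), 'exact' forbids them (= 1).
    ``roughness`` -- per-path cost: 'pair' (mean absolute adjacent weight
                     difference) or 'all' (mean per-edge maximal difference).
    ``objective`` -- minimise the 'total' or the 'avg' cover roughness.

    All four are categorical, so all 2^4 = 16 combinations can be swept.
    """

    sampling: str = "bfs"
    cover: str = "over"
    roughness: str = "pair"
    objective: str = "total"
    angle_max_deg: float = 60.0
    n_trees: int = 100
    seed: int = 0
    all_roughness_variant: str = "per_edge_max"
    bfs_path_cap: int = 1_000_000

    def __post_init__(self) -> None:
        choices = {
            "sampling": ("bfs", "rmst"),
            "cover": ("over", "exact"),
            "roughness": ("pair", "all"),
            "objective": ("total", "avg"),
            "all_roughness_variant": ("per_edge_max", "range"),
        }
        for name, allowed in choices.items():
            if getattr(self, name) not in allowed:
                raise ValueError(f"{name} must be one of {allowed}")
        if not 0.0 < self.angle_max_deg < 180.0:
            raise ValueError("angle_max_deg must lie in (0, 180)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def label(self) -> str:
        return f"{self.sampling}-{self.cover}-{self.roughness}-{self.objective}"


@dataclass(frozen=True)
class FilamentCover:
    """A set of edge-paths covering a graph, with its aggregate roughness.

    Filament ids are the positional indices into ``paths``.
    """

    paths: tuple[EdgePath, ...]
    total_roughness: float = float("nan")
    options: CoverOptions | None = None

    def __post_init__(self) -> None:
        if not self.paths:
            raise GraphValidationError("a cover needs at least one filament")

    @property
    def n_filaments(self) -> int:
        return len(self.paths)

    def edge_membership(self) -> dict[tuple[int, int], frozenset[int]]:
        """Map each covered edge to the set of filament ids covering it."""
        members: dict[tuple[int, int], set[int]] = {}
        for fid, path in enumerate(self.paths):
            for e in path.edges:
                members.setdefault(e, set()).add(fid)
        return {e: frozenset(s) for e, s in members.items()}

    def covers(self, graph: FilamentGraph, exact: bool = False) -> bool:
        members = self.edge_membership()
        graph_edges = set(graph.edges)
        if set(members) - graph_edges:
            return False
        if set(members) != graph_edges:
            return False
        if exact and any(len(s) != 1 for s in members.values()):
            return False
        return True

    def validate_against(self, graph: FilamentGraph) -> None:
        for path in self.paths:
            path.validate_in(graph)
        uncovered = set(graph.edges) - set(self.edge_membership())
        if uncovered:
            raise CoverConsistencyError(
                f"{len(uncovered)} graph edges uncovered, e.g. {sorted(uncovered)[0]}"
            )


# -- GML input / output ----------------------------------------------------


def _node_position(node: int, attrs: Mapping) -> np.ndarray:
    """Coordinates from top-level x/y(/z) or a nested graphics block."""
    source: Mapping = attrs
    if "x" not in attrs or "y" not in attrs:
        graphics = attrs.get("graphics")
        if isinstance(graphics, Mapping) and "x" in graphics and "y" in graphics:
            source = graphics
        else:
            raise GMLFormatError(
                f"node {node}: missing coordinates (x/y attributes or graphics block)"
            )
    try:
        coords = [float(source["x"]), float(source["y"])]
        if "z" in source:
            coords.append(float(source["z"]))
    except (TypeError, ValueError) as exc:
        raise GMLFormatError(f"node {node}: non-numeric coordinates") from exc
    return np.asarray(coords, dtype=float)


def read_gml(file_path: str | Path) -> FilamentGraph:
    """Read a weighted geometric graph from a GML file.

    Raises :class:`GMLFormatError` for missing weights or coordinates and
    :class:`GraphValidationError` for self-loops, parallel edges, or
    non-positive weights.
    """
    try:
        raw = nx.read_gml(str(file_path), label="id")
    except nx.NetworkXError as exc:
        # networkx reports duplicate edges in plain (non-multigraph) GML
        if "duplicated" in str(exc):
            raise GraphValidationError(f"parallel edge in {file_path}: {exc}") from exc
        raise GMLFormatError(f"cannot parse {file_path}: {exc}") from exc
    if raw.is_multigraph():
        flat = nx.Graph()
        flat.add_nodes_from(raw.nodes(data=True))
        for u, v, data in raw.edges(data=True):
            if flat.has_edge(u, v):
                raise GraphValidationError(f"parallel edge {(u, v)} in {file_path}")
            flat.add_edge(u, v, **data)
        raw = flat

    g = nx.Graph()
    for n, attrs in raw.nodes(data=True):
        g.add_node(int(n), pos=_node_position(n, attrs))
    for u, v, attrs in raw.edges(data=True):
        if "weight" not in attrs:
            raise GMLFormatError(f"edge ({u}, {v}): missing 'weight' attribute")
        g.add_edge(int(u), int(v), weight=attrs["weight"])
    return FilamentGraph(g)


def write_gml(graph: FilamentGraph, file_path: str | Path) -> None:
    """Write a plain weighted geometric graph (no filament identities)."""
    nx.write_gml(_export_graph(graph), str(file_path))


def _export_graph(graph: FilamentGraph) -> nx.Graph:
    out = nx.Graph()
    axes = "xyz"
    for n in sorted(graph.graph.nodes):
        pos = graph.position(n)
        out.add_node(n, **{axes[i]: _sig(pos[i]) for i in range(pos.size)})
    for u, v in graph.edges:
        out.add_edge(u, v, weight=_sig(graph.weight(u, v)))
    return out


def write_cover_gml(
    graph: FilamentGraph, cover: FilamentCover, file_path: str | Path
) -> None:
    """Write the graph with filament identities stored on its edges.

    Each edge carries ``filaments`` (semicolon-joined sorted covering ids)
    and ``filament`` (the lowest covering id, usable as a colour key).
    """
    cover.validate_against(graph)
    members = cover.edge_membership()
    out = _export_graph(graph)
    for e, ids in members.items():
        ordered = sorted(ids)
        out.edges[e]["filaments"] = ";".join(str(i) for i in ordered)
        out.edges[e]["filament"] = ordered[0]
    nx.write_gml(out, str(file_path))


def read_cover_gml(file_path: str | Path) -> tuple[FilamentGraph, FilamentCover]:
    """Read a graph whose edges carry filament identities.

    The cover is reconstructed from the per-edge ``filaments`` attribute as
    edge-paths ordered along each filament; a filament whose edges do not
    form a single path is split into maximal runs.
    """
    graph = read_gml(file_path)
    raw = nx.read_gml(str(file_path), label="id")
    by_filament: dict[int, list[tuple[int, int]]] = {}
    for u, v, attrs in raw.edges(data=True):
        ids_attr = attrs.get("filaments", attrs.get("filament"))
        if ids_attr is None:
            raise GMLFormatError(
                f"edge ({u}, {v}): missing 'filaments' attribute in {file_path}"
            )
        for tok in str(ids_attr).split(";"):
            by_filament.setdefault(int(tok), []).append(edge_key(int(u), int(v)))
    paths: list[EdgePath] = []
    for fid in sorted(by_filament):
        paths.extend(_edges_to_paths(by_filament[fid]))
    cover = FilamentCover(tuple(paths))
    cover.validate_against(graph)
    return graph, cover


def _edges_to_paths(edges: list[tuple[int, int]]) -> list[EdgePath]:
    """Chain an unordered edge set into edge-paths (maximal simple runs)."""
    sub = nx.Graph()
    sub.add_edges_from(edges)
    paths: list[EdgePath] = []
    for comp in nx.connected_components(sub):
        csub: nx.Graph = sub.subgraph(comp).copy()
        if nx.is_eulerian(csub):
            circuit = list(nx.eulerian_circuit(csub))
            seq = [circuit[0][0]] + [v for _, v in circuit]
            paths.append(EdgePath(tuple(seq)))
        elif nx.has_eulerian_path(csub):
            trail = list(nx.eulerian_path(csub))
            seq = [trail[0][0]] + [v for _, v in trail]
            paths.append(EdgePath(tuple(seq)))
        else:
            # branched filament label: peel off maximal simple runs
            remaining = {edge_key(u, v) for u, v in csub.edges()}
            incident: dict[int, set[tuple[int, int]]] = {}
            for e in remaining:
                for n in e:
                    incident.setdefault(n, set()).add(e)

            def _take(node: int) -> int | None:
                for e in list(incident.get(node, ())):
                    if e in remaining:
                        remaining.discard(e)
                        return e[0] if e[1] == node else e[1]
                return None

            while remaining:
                u, v = next(iter(remaining))
                remaining.discard((u, v))
                seq = [u, v]
                while (nxt := _take(seq[-1])) is not None:
                    seq.append(nxt)
                while (prv := _take(seq[0])) is not None:
                    seq.insert(0, prv)
                paths.append(EdgePath(tuple(seq)))
    return paths


# -- CSV output ------------------------------------------------------------

#: fixed column order of the per-filament measures table
CSV_COLUMNS = (
    "filament_id",
    "n_edges",
    "length_geometric",
    "mean_weight",
    "roughness_pair",
    "roughness_all",
    "max_angle_deg",
    "median_orientation_deg",
    "convolutedness",
    "node_sequence",
)


def write_filament_csv(
    metrics: Sequence,
    file_path: str | Path,
    header_comments: Sequence[str] = (),
) -> None:
    """Write per-filament measures as CSV with a fixed 10-column schema.

    ``metrics`` are records exposing the :data:`CSV_COLUMNS` attributes
    (see :class:`filacover.analytics.FilamentMetrics`). Optional comment
    lines (``# ...``) record run options and seeds for reproducibility.
    """
    if not metrics:
        raise ValueError("metrics must be non-empty")
    lines = [f"# {c}" for c in header_comments]
    lines.append(",".join(CSV_COLUMNS))
    for m in metrics:
        row = []
        for col in CSV_COLUMNS:
            val = getattr(m, col)
            if isinstance(val, float):
                row.append(f"{_sig(val):.{PRINT_SIG_DIGITS}g}")
            else:
                row.append(str(val))
        lines.append(",".join(row))
    Path(file_path).write_text("\n".join(lines) + "\n")
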
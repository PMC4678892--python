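"""Per-filament descriptive measures and cover-level summaries.

Once a cover is computed, each filament can be characterised by its length
(edge count and geometric length), mean segment weight, weight roughness
under both measures, maximal deflection angle, median orientation relative
to a reference axis (the cell axis for cytoskeletal data; defaults to the
x-axis), and convolutedness -- the ratio of the filament's length to the
largest side of its axis-aligned bounding box, 1 for straight axis-aligned
filaments. Note the known caveat: convolutedness is biased by the filament's
orientation relative to the coordinate axes (a 45-degree straight filament
scores sqrt(2)); the maximal deflection angle is the orientation-free
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core_model import EdgePath, FilamentCover, FilamentGraph
from .errors import GeometryError
from .roughness import (
    all_to_all_roughness,
    euclidean_angle,
    max_deflection_angle,
    pairwise_roughness,
)


@dataclass(frozen=True)
class FilamentMetrics:
    filament_id: int
    n_edges: int
    length_geometric: float
    mean_weight: float
    roughness_pair: float
    roughness_all: float
    max_angle_deg: float
    median_orientation_deg: float
    convolutedness: float
    node_sequence: str


def geometric_length(path: EdgePath, graph: FilamentGraph) -> float:
    """Sum of Euclidean edge lengths along the path."""
    return float(np.linalg.norm(path.segments(graph), axis=1).sum())


def convolutedness(path: EdgePath, graph: FilamentGraph) -> float:
    """Filament length over the largest side of its axis-aligned bounding box.

    A zero-extent bounding box (all nodes coincident up to float precision)
    is defined as convolutedness 1.
    """
    pos = np.asarray([graph.position(n) for n in path.nodes], dtype=float)
    extent = float(np.max(pos.max(axis=0) - pos.min(axis=0)))
    if extent == 0.0:
        return 1.0
    return geometric_length(path, graph) / extent


def median_orientation(
    path: EdgePath, graph: FilamentGraph, axis: np.ndarray | None = None
) -> float:
    """Median over edges of the acute angle to a reference axis, in [0, 90].

    Acute folding makes the measure independent of edge and path direction.
    """
    if axis is None:
        axis = np.zeros(graph.ndim)
        axis[0] = 1.0
    axis = np.asarray(axis, dtype=float)
    if np.linalg.norm(axis) == 0.0:
        raise GeometryError("reference axis must be non-zero")
    angles = []
    for seg in path.segments(graph):
        if np.linalg.norm(seg) == 0.0:
            raise GeometryError("zero-length edge in path")
        a = euclidean_angle(seg, axis)
        angles.append(min(a, 180.0 - a))
    return float(np.median(angles))


def filament_metrics(
    cover: FilamentCover,
    graph: FilamentGraph,
    axis: np.ndarray | None = None,
) -> list[FilamentMetrics]:
    """One record per filament combining all per-filament measures."""
    records = []
    for fid, path in enumerate(cover.paths):
        records.append(
            FilamentMetrics(
                filament_id=fid,
                n_edges=path.n_edges,
                length_geometric=geometric_length(path, graph),
                mean_weight=float(path.weights(graph).mean()),
                roughness_pair=pairwise_roughness(path, graph),
                roughness_all=all_to_all_roughness(path, graph),
                max_angle_deg=max_deflection_angle(path, graph),
                median_orientation_deg=median_orientation(path, graph, axis),
                convolutedness=convolutedness(path, graph),
                node_sequence="-".join(str(n) for n in path.nodes),
            )
        )
    return records


def component_lengths(graph: FilamentGraph) -> list[float]:
    """Total Euclidean edge length per connected component.

    Component length is the classical proxy for filament size; comparing it
    with per-filament lengths shows how strongly components concatenate (and
    hence overestimate) individual filaments.
    """
    out = []
    for comp in nx.connected_components(graph.graph):
        sub = graph.graph.subgraph(comp)
        out.append(
            float(sum(graph.edge_length(u, v) for u, v in sub.edges()))
        )
    return out


#: metric columns entering the correlation summary
_NUMERIC_COLUMNS = (
    "n_edges",
    "length_geometric",
    "mean_weight",
    "roughness_pair",
    "roughness_all",
    "max_angle_deg",
    "median_orientation_deg",
    "convolutedness",
)


def metric_correlations(metrics: list[FilamentMetrics]):
    """Pearson correlation matrix of the numeric per-filament measures.

    Returns a pandas DataFrame indexed by metric name. Columns with zero
    variance yield NaN rows/columns, as usual for Pearson correlation.
    """
    import pandas as pd

    df = pd.DataFrame(
        {c: [getattr(m, c) for m in metrics] for c in _NUMERIC_COLUMNS},
        dtype=float,
    )
    return df.corr(method="pearson")
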
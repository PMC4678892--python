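"""Path-quality functionals: weight roughness and deflection angles.

Three penalties assess how filament-like an edge-path is:

* pairwise roughness -- mean absolute weight difference between adjacent
  edges; small when the intensity/thickness varies smoothly along the path;
* all-to-all roughness -- mean over edges of each edge's maximal absolute
  weight difference to any other edge of the path; penalises any abrupt
  thickness change anywhere in the path, which matters where physical
  overlaps cause intensity jumps;
* maximal deflection angle -- the largest turning angle between consecutive
  traversal-oriented segments; 0 deg is a perfectly straight filament.

Single-edge paths score their own edge weight under both weight measures
(this makes short, bright fragments expensive and long smooth runs cheap,
which is what drives the set-cover objective towards whole filaments).
"""

from __future__ import annotations

import numpy as np

from .core_model import EdgePath, FilamentCover, FilamentGraph
from .errors import GeometryError


def pairwise_roughness(path: EdgePath, graph: FilamentGraph) -> float:
    """Mean absolute weight difference between adjacent edges.

    For an open path of P >= 2 edges with weights w_1..w_P this is
    ``sum_i |w_{i+1} - w_i| / (P - 1)``; a single-edge path scores its own
    weight. In a closed path the last and first edges are adjacent too, so
    the seam difference |w_1 - w_P| enters the mean (P differences over P
    adjacent pairs) -- this also makes the value independent of the
    arbitrary traversal rotation of the loop.
    """
    w = path.weights(graph)
    if w.size == 1:
        return float(w[0])
    diffs = np.abs(np.diff(w))
    if path.is_closed:
        diffs = np.append(diffs, abs(w[0] - w[-1]))
    return float(np.mean(diffs))


def all_to_all_roughness(
    path: EdgePath, graph: FilamentGraph, variant: str = "per_edge_max"
) -> float:
    """Average maximal weight difference between any two edges of the path.

    The default reading averages, over the P edges, each edge's maximal
    absolute weight difference to any other edge:
    ``sum_i max_j |w_i - w_j| / P``. ``variant="range"`` instead returns the
    plain range ``max(w) - min(w)``. A single-edge path scores its own
    weight under either variant.
    """
    w = path.weights(graph)
    if w.size == 1:
        return float(w[0])
    if variant == "per_edge_max":
        # max_j |w_i - w_j| = max(w_i - min w, max w - w_i)
        return float(np.mean(np.maximum(w - w.min(), w.max() - w)))
    if variant == "range":
        return float(w.max() - w.min())
    raise ValueError(f"unknown all-to-all variant {variant!r}")


def euclidean_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise GeometryError("angle of a zero-length vector is undefined")
    cos = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def max_deflection_angle(path: EdgePath, graph: FilamentGraph) -> float:
    """Maximal deflection angle between consecutive oriented segments.

    Each edge is oriented along the traversal direction; the deflection at an
    interior node is the Euclidean angle between the incoming and outgoing
    segment. For a closed path the seam deflection (last segment against
    first segment) is included. Single-edge paths return 0.
    """
    segs = path.segments(graph)
    if np.any(np.linalg.norm(segs, axis=1) == 0.0):
        raise GeometryError("coincident consecutive node positions")
    if len(segs) == 1:
        return 0.0
    pairs = zip(segs, segs[1:])
    angles = [euclidean_angle(a, b) for a, b in pairs]
    if path.is_closed:
        angles.append(euclidean_angle(segs[-1], segs[0]))
    return float(max(angles))


def path_roughness(
    path: EdgePath,
    graph: FilamentGraph,
    measure: str = "pair",
    all_variant: str = "per_edge_max",
) -> float:
    """Dispatch to the configured weight-roughness measure."""
    if measure == "pair":
        return pairwise_roughness(path, graph)
    if measure == "all":
        return all_to_all_roughness(path, graph, variant=all_variant)
    raise ValueError(f"unknown roughness measure {measure!r}")


def cover_total_roughness(
    cover: FilamentCover,
    graph: FilamentGraph,
    measure: str = "pair",
    all_variant: str = "per_edge_max",
) -> float:
    """Total roughness R = sum over filaments of the per-path roughness."""
    return float(
        sum(path_roughness(p, graph, measure, all_variant) for p in cover.paths)
    )


def cover_average_roughness(
    cover: FilamentCover,
    graph: FilamentGraph,
    measure: str = "pair",
    all_variant: str = "per_edge_max",
) -> float:
    """Average roughness R / |cover|."""
    return cover_total_roughness(cover, graph, measure, all_variant) / cover.n_filaments
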
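"""Planted filamentous scenes and the two robustness protocols.

The generator draws filaments as polylines (closed with some probability),
inserts a node wherever two polylines cross, lets filaments share exact edge
runs (overlaps), and assigns each edge the clipped sum of the smoothly
varying intensities of the filaments covering it plus centred Gaussian
noise. It returns both the weighted geometric graph and the planted
ground-truth cover, so decompositions can be scored against a known answer.

Base intensities default to (0.8, 0.9) with a 25% linear taper along each
filament: bright strokes and fluorescently labelled filaments are recorded
close to the detector ceiling and their apparent thickness varies steadily
along the filament. Because intensities are additive but clipped at 1,
physically overlapping segments saturate rather than doubling in
brightness -- the abrupt apparent-thickness change at overlap boundaries
that distinguishes the all-to-all from the pairwise roughness measure is
preserved, while the weight scale stays normalised to a maximum of 1. The
taper keeps the per-edge intensity gradient well above the default noise
scale, so the planted decomposition is identifiable from the weights.

Two robustness protocols mirror the standard stress tests for cover
quality: deleting growing random edge subsets, and perturbing all edge
weights with centred Gaussian noise of growing relative standard deviation;
both report the mean structure-aware Jaccard index JI^1 against the planted
cover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .core_model import CoverOptions, EdgePath, FilamentCover, FilamentGraph
from .cover_solver import build_cover_program, solve_average, solve_total
from .errors import GeometryError, GraphValidationError
from .path_sampling import sample_paths
from .roughness import max_deflection_angle
from .similarity import contingency_counts, jaccard_index

#: weights are clipped to this floor after noise so they stay positive
WEIGHT_FLOOR = 1e-6
#: coordinate rounding (decimals) used to merge coincident polyline vertices
_COORD_DECIMALS = 9
_END_TOL = 1e-7


@dataclass(frozen=True)
class SceneParams:
    """Parameters of a random planted scene.

    ``turn_max_deg`` bounds the planted turning angle and must stay below
    the BFS straightness threshold used downstream, so every planted
    filament is guaranteed to appear in the BFS candidate pool.
    """

    n_filaments: int = 5
    n_segments_range: tuple[int, int] = (3, 6)
    turn_max_deg: float = 45.0
    p_overlap: float = 0.2
    p_loop: float = 0.2
    base_intensity_range: tuple[float, float] = (0.8, 0.9)
    intensity_modulation: float = 0.25
    weight_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_overlap <= 1.0 or not 0.0 <= self.p_loop <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 < self.turn_max_deg < 180.0:
            raise ValueError("turn_max_deg must lie in (0, 180)")
        lo, hi = self.base_intensity_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("base_intensity_range must lie within (0, 1]")
        if self.weight_noise_sd < 0.0:
            raise ValueError("weight_noise_sd must be >= 0")
        if not 0.0 <= self.intensity_modulation < 1.0:
            raise ValueError("intensity_modulation must lie in [0, 1)")
        if self.n_filaments < 1:
            raise ValueError("n_filaments must be >= 1")


def _taper(x: float) -> float:
    """Periodic asymmetric taper, period 1, range [-1, 1].

    Rises linearly over the first third of the period and falls linearly
    over the remaining two thirds. The gradient magnitude is therefore
    bounded between 3 and 6 per period -- never close to zero -- so the
    intensity varies at a steady rate everywhere along a filament.
    """
    x = x - math.floor(x)
    return 6.0 * x - 1.0 if x < 1.0 / 3.0 else 1.0 - 3.0 * (x - 1.0 / 3.0)


def _coord_key(p: np.ndarray) -> tuple[float, ...]:
    return tuple(round(float(c), _COORD_DECIMALS) for c in p)


def _same_segment(a1, b1, a2, b2, tol=1e-9) -> bool:
    return (
        np.allclose(a1, a2, atol=tol) and np.allclose(b1, b2, atol=tol)
    ) or (np.allclose(a1, b2, atol=tol) and np.allclose(b1, a2, atol=tol))


def _insert_crossings(polylines: list[np.ndarray]) -> list[np.ndarray]:
    """Split segments at pairwise interior intersections.

    Crossings at shared vertices need no splitting (the vertex registry
    merges them); T-junctions split only the pierced segment. Collinear
    partial overlap between non-identical segments is a degeneracy.
    """
    segs: list[tuple[int, int, np.ndarray, np.ndarray]] = []
    for fi, verts in enumerate(polylines):
        for si, (a, b) in enumerate(zip(verts, verts[1:])):
            segs.append((fi, si, a, b))
    splits: dict[tuple[int, int], list[tuple[float, tuple[float, ...]]]] = {}
    for i in range(len(segs)):
        f1, s1, a1, b1 = segs[i]
        line1 = LineString([a1, b1])
        for j in range(i + 1, len(segs)):
            f2, s2, a2, b2 = segs[j]
            if _same_segment(a1, b1, a2, b2):
                continue  # intended shared run: identical edge after merging
            inter = line1.intersection(LineString([a2, b2]))
            if inter.is_empty:
                continue
            if inter.geom_type != "Point":
                raise GeometryError(
                    "collinear partial overlap between non-identical segments"
                )
            p = np.array([inter.x, inter.y])
            key = _coord_key(p)
            for f, s, a, b in ((f1, s1, a1, b1), (f2, s2, a2, b2)):
                d = b - a
                length2 = float(np.dot(d, d))
                t = float(np.dot(p - a, d)) / length2
                margin = _END_TOL / math.sqrt(length2)
                if margin < t < 1.0 - margin:
                    splits.setdefault((f, s), []).append((t, key))
    refined = []
    for fi, verts in enumerate(polylines):
        out = [verts[0]]
        for si in range(len(verts) - 1):
            for _, key in sorted(set(splits.get((fi, si), []))):
                out.append(np.asarray(key))
            out.append(verts[si + 1])
        arr = []
        for v in out:
            if arr and np.linalg.norm(v - arr[-1]) < _END_TOL:
                raise GeometryError("near-coincident vertices after splitting")
            arr.append(np.asarray(v, dtype=float))
        refined.append(np.asarray(arr))
    return refined


def assemble_scene(
    polylines: list[np.ndarray],
    base_intensities: list[float],
    weight_noise_sd: float,
    rng: np.random.Generator,
    intensity_modulation: float = 0.25,
) -> tuple[FilamentGraph, FilamentCover]:
    """Build a weighted graph and planted cover from filament polylines.

    Each polyline is an (k+1, 2) vertex array (a closed filament repeats its
    first vertex at the end). Crossings between polylines become graph
    nodes; vertices with identical coordinates merge, so exactly-copied
    vertex runs become shared (overlapping) edges.

    Each filament carries a smooth intensity profile of relative amplitude
    ``intensity_modulation``: open filaments taper linearly from one end to
    the other (random direction), as filament thickness does along its
    length; closed filaments follow a periodic asymmetric triangular taper
    whose turning points are aligned with edge centres, so the intensity
    gradient is bounded away from zero everywhere and the loop has no
    intensity seam. An edge's weight is ``min(1, sum of covering filament
    intensities)`` plus centred Gaussian noise, clipped to a small positive
    floor.
    """
    if len(polylines) != len(base_intensities):
        raise ValueError("one base intensity per filament required")
    refined = _insert_crossings([np.asarray(p, dtype=float) for p in polylines])

    node_ids: dict[tuple[float, ...], int] = {}
    positions: dict[int, np.ndarray] = {}

    def _node(p: np.ndarray) -> int:
        key = _coord_key(p)
        if key not in node_ids:
            node_ids[key] = len(node_ids)
            positions[node_ids[key]] = np.asarray(key, dtype=float)
        return node_ids[key]

    paths: list[EdgePath] = []
    intensity: dict[tuple[int, int], float] = {}
    for fid, verts in enumerate(refined):
        seq = tuple(_node(v) for v in verts)
        path = EdgePath(seq)  # raises on repeated edges / self-loop steps
        paths.append(path)
        n = path.n_edges
        if path.is_closed:
            # periodic taper; the peak sits on a random edge centre, so the
            # per-edge gradient never degenerates to zero
            phase = 1.0 / 3.0 - (float(rng.integers(n)) + 0.5) / n
        else:
            direction = 1.0 if rng.uniform() < 0.5 else -1.0
        for i, e in enumerate(path.edges):
            s = (i + 0.5) / n  # arc position of the edge centre
            if path.is_closed:
                mod = _taper(s + phase)
            else:
                mod = direction * (2.0 * s - 1.0)
            profile = 1.0 + intensity_modulation * mod
            intensity[e] = intensity.get(e, 0.0) + base_intensities[fid] * profile

    edges = []
    for e in sorted(intensity):
        w = min(1.0, intensity[e]) + rng.normal(0.0, weight_noise_sd)
        edges.append((e[0], e[1], max(w, WEIGHT_FLOOR)))
    graph = FilamentGraph.from_data(positions, edges)
    cover = FilamentCover(tuple(paths))
    cover.validate_against(graph)
    return graph, cover


def _random_polyline(
    rng: np.random.Generator,
    params: SceneParams,
    box: float,
) -> np.ndarray:
    """Open random walk with bounded turning, anchored near the box centre."""
    n = int(rng.integers(params.n_segments_range[0], params.n_segments_range[1] + 1))
    anchor = box / 2 + rng.uniform(-box / 6, box / 6, size=2)
    heading = rng.uniform(0.0, 2.0 * math.pi)
    start = anchor - (n / 2.0) * np.array([math.cos(heading), math.sin(heading)])
    pts = [start]
    for _ in range(n):
        pts.append(pts[-1] + np.array([math.cos(heading), math.sin(heading)]))
        heading += math.radians(rng.uniform(-0.8, 0.8) * params.turn_max_deg)
    return np.asarray(pts)


def _loop_polyline(
    rng: np.random.Generator, params: SceneParams, box: float
) -> np.ndarray:
    """Closed regular polygon with deflections strictly below turn_max."""
    m = int(math.floor(360.0 / params.turn_max_deg)) + 1
    radius = 0.5 / math.sin(math.pi / m)
    centre = rng.uniform(0.25 * box, 0.75 * box, size=2)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    angles = phase + 2.0 * math.pi * np.arange(m + 1) / m
    return centre + radius * np.stack([np.cos(angles), np.sin(angles)], axis=1)


def _overlap_polyline(
    rng: np.random.Generator,
    params: SceneParams,
    host: np.ndarray,
) -> np.ndarray:
    """Filament routed along a copied vertex run of an existing open filament."""
    n_host = len(host) - 1
    run_len = int(rng.integers(1, min(2, n_host - 2) + 1))
    k = int(rng.integers(1, n_host - run_len))
    run = [host[i].copy() for i in range(k, k + run_len + 1)]
    turn = math.radians(rng.uniform(0.45, 0.8) * params.turn_max_deg)
    sign = 1.0 if rng.uniform() < 0.5 else -1.0

    def _dir(a: np.ndarray, b: np.ndarray) -> float:
        return math.atan2(b[1] - a[1], b[0] - a[0])

    tails_in = int(rng.integers(1, 3))
    tails_out = int(rng.integers(1, 3))
    pts = list(run)
    heading = _dir(run[-2], run[-1]) + sign * turn
    for _ in range(tails_out):
        pts.append(pts[-1] + np.array([math.cos(heading), math.sin(heading)]))
    heading = _dir(run[1], run[0]) + sign * turn
    head = []
    for _ in range(tails_in):
        nxt = (head[0] if head else pts[0]) + np.array(
            [math.cos(heading), math.sin(heading)]
        )
        head.insert(0, nxt)
    return np.asarray(head + pts)


def generate_scene(
    params: SceneParams, max_retries: int = 30
) -> tuple[FilamentGraph, FilamentCover]:
    """Random planted scene: polyline filaments, crossings, overlaps, loops.

    Reproducible from ``params`` (including ``params.seed``). Raises
    :class:`GeometryError` if no degeneracy-free layout is found within the
    retry budget.
    """
    rng = np.random.default_rng(params.seed)
    box = 2.0 + 1.5 * math.sqrt(params.n_filaments) * (
        (params.n_segments_range[0] + params.n_segments_range[1]) / 4.0
    )
    last_error: Exception | None = None
    for _ in range(max_retries):
        try:
            polylines: list[np.ndarray] = []
            open_hosts: list[int] = []
            for _fid in range(params.n_filaments):
                u = rng.uniform()
                if u < params.p_loop:
                    polylines.append(_loop_polyline(rng, params, box))
                elif u < params.p_loop + params.p_overlap and any(
                    len(polylines[h]) >= 4 for h in open_hosts
                ):
                    hosts = [h for h in open_hosts if len(polylines[h]) >= 4]
                    host = polylines[int(rng.choice(hosts))]
                    polylines.append(_overlap_polyline(rng, params, host))
                else:
                    poly = _random_polyline(rng, params, box)
                    open_hosts.append(len(polylines))
                    polylines.append(poly)
            bases = list(
                rng.uniform(*params.base_intensity_range, size=params.n_filaments)
            )
            graph, cover = assemble_scene(
                polylines,
                bases,
                params.weight_noise_sd,
                rng,
                intensity_modulation=params.intensity_modulation,
            )
            for path in cover.paths:
                if max_deflection_angle(path, graph) >= params.turn_max_deg:
                    raise GeometryError("planted deflection exceeds turn_max")
            return graph, cover
        except (GeometryError, GraphValidationError) as exc:
            last_error = exc
    raise GeometryError(
        f"no degeneracy-free scene within {max_retries} retries: {last_error}"
    )


def contrived_scene(
    seed: int = 0, weight_noise_sd: float = 0.02
) -> tuple[FilamentGraph, FilamentCover]:
    """Deterministic planted scene with crossings, an overlap, and a loop.

    Five filaments with distinct base intensities, smooth per-filament
    intensity profiles, and turning angles strictly below 45 degrees:

    * two straight filaments crossing each other and the overlap corridor at
      right angles (right-angle crossings cannot be traversed by the
      angle-constrained BFS, as in imaged filament crossings);
    * a host filament and a second filament entering and leaving it at
      shallow angles, sharing one edge (the overlap);
    * a closed nine-sided loop (deflections 40 degrees).

    Only the edge-weight noise depends on ``seed``; the geometry is fixed.
    """
    c, s = 0.8, 0.6  # 36.87-degree entry/exit direction components

    # F0: horizontal 3-edge filament at y = 4, crossed by F1 at (4, 4)
    f0 = np.array([[2.0, 4.0], [3.0, 4.0], [4.0, 4.0], [5.0, 4.0]])
    # F1: vertical filament crossing F0 at (4,4) and the corridor at (4,1)
    f1 = np.array([[4.0, y] for y in (-1.0, 0.0, 1.0, 2.0, 3.0, 4.0, 5.0)])
    # F2: overlap host along y = 1; run edge (3,1)-(4,1)
    f2 = np.array([[2.0, 1.0], [3.0, 1.0], [4.0, 1.0], [5.0, 1.0]])
    # F3: enters the run at (3,1) and leaves at (4,1) at 25 degrees to the
    # x-axis; 25 < 45 keeps the planted bend admissible, while the 65-degree
    # angle to F1's vertical keeps the BFS from mixing F1 into F3's exit
    ex, ey = math.cos(math.radians(25.0)), math.sin(math.radians(25.0))
    f3 = np.array(
        [
            [3.0 - ex, 1.0 - ey],
            [3.0, 1.0],
            [4.0, 1.0],
            [4.0 + ex, 1.0 + ey],
        ]
    )
    # F4: closed 9-gon loop, disjoint from the rest
    m = 9
    radius = 0.5 / math.sin(math.pi / m)
    centre = np.array([9.5, 5.5])
    angles = 2.0 * math.pi * np.arange(m + 1) / m
    f4 = centre + radius * np.stack([np.cos(angles), np.sin(angles)], axis=1)

    bases = [0.88, 0.84, 0.82, 0.86, 0.80]
    rng = np.random.default_rng(seed)
    return assemble_scene([f0, f1, f2, f3, f4], bases, weight_noise_sd, rng)


# -- robustness protocols ----------------------------------------------------


def add_weight_noise(
    graph: FilamentGraph, sd_fraction: float, seed: int = 0
) -> FilamentGraph:
    """Perturb each weight by centred Gaussian noise of sd ``sd_fraction * w_e``.

    Topology and positions are untouched; the input graph is not modified.
    Weights are clipped to a small positive floor.
    """
    if sd_fraction < 0:
        raise ValueError("sd_fraction must be >= 0")
    out = graph.copy()
    if sd_fraction == 0:
        return out
    rng = np.random.default_rng(seed)
    for _, _, data in out.graph.edges(data=True):
        w = data["weight"]
        data["weight"] = max(w + rng.normal(0.0, sd_fraction * w), WEIGHT_FLOOR)
    return out


def remove_random_edges(
    graph: FilamentGraph, k: int, seed: int = 0
) -> FilamentGraph:
    """Delete ``k`` uniformly sampled distinct edges; isolated nodes remain."""
    if not 0 <= k < graph.n_edges:
        raise ValueError(f"k must satisfy 0 <= k < E = {graph.n_edges}")
    out = graph.copy()
    if k == 0:
        return out
    rng = np.random.default_rng(seed)
    edges = graph.edges
    idx = rng.choice(len(edges), size=k, replace=False)
    out.graph.remove_edges_from(edges[i] for i in idx)
    return out


def _solve(graph: FilamentGraph, options: CoverOptions) -> FilamentCover:
    candidates = sample_paths(graph, options)
    program = build_cover_program(candidates, graph, options)
    return solve_total(program) if options.objective == "total" else solve_average(
        program
    )


def _ji1(
    cover: FilamentCover, reference: FilamentCover, graph: FilamentGraph
) -> float:
    ref_labels = {
        e: ids
        for e, ids in reference.edge_membership().items()
        if graph.graph.has_edge(*e)
    }
    h = contingency_counts(cover.edge_membership(), ref_labels, graph, d=1)
    return jaccard_index(h)


def edge_removal_curve(
    graph: FilamentGraph,
    reference: FilamentCover,
    options: CoverOptions,
    k_max: int = 50,
    samples_per_k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean JI^1 against the reference after deleting k random edges.

    Row k = 0 is the unperturbed baseline. The reference is restricted to
    the surviving edge set, since deleted edges cannot be covered.
    Returns a DataFrame with columns ``k`` and ``mean_ji1``.
    """
    rng = np.random.default_rng(seed)
    rows = [(0, _ji1(_solve(graph, options), reference, graph))]
    for k in range(1, min(k_max, graph.n_edges - 1) + 1):
        vals = []
        for _ in range(samples_per_k):
            variant = remove_random_edges(
                graph, k, seed=int(rng.integers(2**31 - 1))
            )
            cover = _solve(variant, options)
            vals.append(_ji1(cover, reference, variant))
        rows.append((k, float(np.mean(vals))))
    return pd.DataFrame(rows, columns=["k", "mean_ji1"])


def noise_robustness_curve(
    graph: FilamentGraph,
    reference: FilamentCover,
    options: CoverOptions,
    sd_levels: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2),
    n_instances: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean JI^1 against the reference under relative Gaussian weight noise.

    Noise changes only the weights, so the candidate pool is sampled once
    from the unperturbed topology and re-costed per noisy instance. Returns
    a DataFrame with columns ``sd`` and ``mean_ji1``.
    """
    rng = np.random.default_rng(seed)
    candidates = sample_paths(graph, options)

    def _solve_on(g: FilamentGraph) -> FilamentCover:
        program = build_cover_program(candidates, g, options)
        return (
            solve_total(program)
            if options.objective == "total"
            else solve_average(program)
        )

    rows = []
    for sd in sd_levels:
        if sd == 0.0:
            rows.append((0.0, _ji1(_solve_on(graph), reference, graph)))
            continue
        vals = []
        for _ in range(n_instances):
            noisy = add_weight_noise(graph, sd, seed=int(rng.integers(2**31 - 1)))
            vals.append(_ji1(_solve_on(noisy), reference, noisy))
        rows.append((float(sd), float(np.mean(vals))))
    return pd.DataFrame(rows, columns=["sd", "mean_ji1"])
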
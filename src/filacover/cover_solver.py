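"""Set-cover integer programming for the filament cover problem.

Given a candidate path pool P with per-path roughness costs r_p, the cover
program selects a binary indicator x_p per path:

    minimise    sum_p r_p x_p            (total objective)
           or   sum_p r_p x_p / sum_p x_p   (average objective)
    subject to  sum_{p covering e} x_p >= 1   for every edge e   ('over')
           or   sum_{p covering e} x_p  = 1                      ('exact')
                x_p in {0, 1}

The total objective is a plain binary linear program, solved to proven
optimality with the HiGHS backend behind :func:`scipy.optimize.milp` (MIP
gap 0). The average objective is a fractional 0-1 program; it is solved by
Dinkelbach iteration, which repeatedly solves the parametric binary program
``min sum_p (r_p - lambda) x_p`` and updates lambda to the incumbent ratio.
Dinkelbach is exact and finite for ratio objectives with positive
denominator; lambda is initialised at the average roughness of the
always-feasible all-singletons cover and decreases monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .core_model import CoverOptions, FilamentCover, FilamentGraph
from .errors import InfeasibleCoverError, SolverError
from .path_sampling import CandidatePathSet, sample_paths
from .roughness import path_roughness

#: Dinkelbach convergence tolerance on the parametric objective
DINKELBACH_TOL = 1e-9
#: Dinkelbach iteration cap
DINKELBACH_MAX_ITER = 100


@dataclass(frozen=True)
class CoverProgram:
    """The covering program over a fixed candidate pool.

    ``matrix`` is the edge-by-path incidence matrix (CSR), ``costs`` the
    per-path roughness vector, ``exact`` selects equality covering rows.
    """

    candidates: CandidatePathSet
    graph: FilamentGraph
    costs: np.ndarray
    matrix: sparse.csr_matrix
    exact: bool
    options: CoverOptions = field(default_factory=CoverOptions)

    @property
    def n_variables(self) -> int:
        return len(self.candidates.paths)

    @property
    def n_constraints(self) -> int:
        return self.matrix.shape[0]


def build_cover_program(
    candidates: CandidatePathSet,
    graph: FilamentGraph,
    options: CoverOptions,
) -> CoverProgram:
    """Assemble costs and covering rows for a candidate pool.

    Raises :class:`InfeasibleCoverError` naming the first edge covered by no
    candidate (unreachable when the pool includes all singletons).
    """
    edges = graph.edges
    edge_index = {e: i for i, e in enumerate(edges)}
    rows, cols = [], []
    for j, path in enumerate(candidates.paths):
        for e in path.edges:
            i = edge_index.get(e)
            if i is None:
                raise InfeasibleCoverError(
                    f"candidate path uses edge {e} absent from the graph"
                )
            rows.append(i)
            cols.append(j)
    matrix = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(edges), len(candidates.paths)),
    )
    covered = np.asarray(matrix.sum(axis=1)).ravel()
    if np.any(covered == 0):
        bad = edges[int(np.argmin(covered))]
        raise InfeasibleCoverError(f"edge {bad} is covered by no candidate path")
    costs = np.array(
        [
            path_roughness(
                p, graph, options.roughness, options.all_roughness_variant
            )
            for p in candidates.paths
        ]
    )
    return CoverProgram(
        candidates=candidates,
        graph=graph,
        costs=costs,
        matrix=matrix,
        exact=options.cover == "exact",
        options=options,
    )


def _solve_binary(program: CoverProgram, costs: np.ndarray) -> np.ndarray:
    """Solve one binary covering program to proven optimality."""
    n = program.n_variables
    lb = 1.0
    ub = 1.0 if program.exact else np.inf
    res = milp(
        costs,
        constraints=LinearConstraint(program.matrix, lb, ub),
        integrality=np.ones(n),
        bounds=Bounds(0.0, 1.0),
        options={"mip_rel_gap": 0.0, "presolve": True},
    )
    if not res.success:
        raise SolverError(f"MILP backend failed: status={res.status} ({res.message})")
    return np.round(res.x).astype(bool)


def _to_cover(
    program: CoverProgram, selected: np.ndarray, total: float
) -> FilamentCover:
    paths = tuple(
        p for p, s in zip(program.candidates.paths, selected) if s
    )
    cover = FilamentCover(paths, total_roughness=float(total), options=program.options)
    # re-verify the covering constraints independently of the solver
    members = cover.edge_membership()
    for e in program.graph.edges:
        k = len(members.get(e, ()))
        if k < 1 or (program.exact and k != 1):
            raise SolverError(f"solver returned a cover violating edge {e}")
    return cover


def solve_total(program: CoverProgram) -> FilamentCover:
    """Minimise the total cover roughness (binary linear program)."""
    selected = _solve_binary(program, program.costs)
    total = float(program.costs[selected].sum())
    return _to_cover(program, selected, total)


def solve_average(program: CoverProgram) -> FilamentCover:
    """Minimise the average cover roughness via Dinkelbach iteration."""
    # initial lambda: the all-singletons cover is always feasible
    singleton = np.array([p.n_edges == 1 for p in program.candidates.paths])
    if singleton.any():
        lam = float(program.costs[singleton].mean())
    else:
        lam = float(program.costs.mean())
    prev_lam = np.inf
    selected = None
    for _ in range(DINKELBACH_MAX_ITER):
        if lam > prev_lam + 1e-12:
            raise SolverError("Dinkelbach lambda sequence increased")
        prev_lam = lam
        selected = _solve_binary(program, program.costs - lam)
        k = int(selected.sum())
        value = float((program.costs - lam)[selected].sum())
        if value >= -DINKELBACH_TOL:
            total = float(program.costs[selected].sum())
            return _to_cover(program, selected, total)
        lam = float(program.costs[selected].sum()) / k
    raise SolverError(
        f"Dinkelbach did not converge within {DINKELBACH_MAX_ITER} iterations "
        f"(last lambda={lam})"
    )


def solve_fcp(graph: FilamentGraph, options: CoverOptions | None = None) -> FilamentCover:
    """Sample candidates, build the program, and solve per ``options``.

    Deterministic given ``options.seed`` (the only random component is RMST
    sampling).
    """
    options = options or CoverOptions()
    candidates = sample_paths(graph, options)
    program = build_cover_program(candidates, graph, options)
    if options.objective == "total":
        return solve_total(program)
    return solve_average(program)
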
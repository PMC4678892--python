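# filacover

Decompose weighted geometric graphs into individual filaments by set-cover
integer programming, and compare decompositions with structure-aware
partition-similarity measures.

## The problem

Filamentous structures — actin cytoskeletons, neuronal arbors, galaxy
filaments — are routinely reduced to weighted geometric graphs: nodes carry
image positions, edges represent filament *segments*, and edge weights
encode local intensity or thickness. The graph alone does not say which
segments belong to the same physical filament, yet per-filament statistics
(length, orientation, bending, thickness) are what most downstream analyses
need. `filacover` recovers whole filaments from such a graph: crossing
filaments, filaments that physically overlap on shared segments, and closed
loops.

## The model

A filament is an edge-path `p = (e_1, …, e_P)`, an ordered run of adjacent,
non-repeating edges (closed paths model loops). Each candidate path gets a
roughness cost `r_p`:

- **pair** — mean absolute weight difference between adjacent edges,
  `r_p = Σ|w_{i+1} − w_i| / (P−1)` (for a closed path the seam pair enters
  the mean as well);
- **all** — mean over edges of each edge's maximal absolute weight
  difference to any other edge of the path;
- single-edge paths cost their own weight under both measures, which makes
  short bright fragments expensive and long smooth runs cheap.

The **filament cover problem** selects binary indicators `x_p` over a
candidate path pool P:

```
min   Σ_p r_p x_p          (total)    or    Σ_p r_p x_p / Σ_p x_p   (avg)
s.t.  Σ_{p ∋ e} x_p ≥ 1    for every edge e       (over — overlaps allowed)
      Σ_{p ∋ e} x_p = 1    for an exact cover     (exact)
      x_p ∈ {0, 1}
```

The pool P comes from either an angle-constrained breadth-first search
(**bfs**: every path whose maximal deflection between consecutive oriented
segments stays below 60°, loops included) or repeated random minimum
spanning trees (**rmst**: all tree paths of T = 100 trees under i.i.d.
uniform auxiliary weights; loop-free by construction). All four options are
categorical, so the 2⁴ = 16 combinations can be swept. The total objective
is a binary linear program solved to proven optimality (HiGHS via
`scipy.optimize.milp`, MIP gap 0); the average objective is a fractional
0-1 program solved exactly by Dinkelbach iteration.

Cover quality against a reference (e.g. manual) assignment is measured by
the Rand and Jaccard indices over edge pairs, their structure-aware
variants `RI^d`/`JI^d` that count only edge pairs separated by at most `d`
nodes (`d = 1`: adjacent edges only; `d = ∞`: the classical indices), and —
for non-overlapping covers — the variation of information.

## Worked example

```python
import math
import filacover as fc

graph, truth = fc.contrived_scene(seed=0)     # crossings, an overlap, a loop
print(f"scene: N = {graph.n_nodes} nodes, E = {graph.n_edges} edges, "
      f"{truth.n_filaments} planted filaments")

options = fc.CoverOptions(sampling="bfs", cover="over",
                          roughness="pair", objective="total")
cover = fc.solve_fcp(graph, options)
print(f"decomposition: {cover.n_filaments} filaments, "
      f"total roughness R = {cover.total_roughness:.4f}")

a, b = cover.edge_membership(), truth.edge_membership()
for d, tag in ((1, "1"), (math.inf, "inf")):
    h = fc.contingency_counts(a, b, graph, d=d)
    print(f"RI^{tag} = {fc.rand_index(h):.3f}   JI^{tag} = {fc.jaccard_index(h):.3f}")

for r in fc.filament_metrics(cover, graph):
    print(f"filament {r.filament_id}: {r.n_edges} edges, "
          f"length {r.length_geometric:.2f}, mean weight {r.mean_weight:.3f}, "
          f"max angle {r.max_angle_deg:.0f} deg, "
          f"convolutedness {r.convolutedness:.2f}")
```

prints (abridged):

```
scene: N = 24 nodes, E = 23 edges, 5 planted filaments
decomposition: 5 filaments, total roughness R = 0.6227
RI^1 = 1.000   JI^1 = 1.000
RI^inf = 1.000   JI^inf = 1.000
filament 0: 3 edges, length 3.00, mean weight 0.889, max angle 0 deg, convolutedness 1.00
filament 3: 6 edges, length 6.00, mean weight 0.819, max angle 0 deg, convolutedness 1.00
filament 4: 9 edges, length 9.00, mean weight 0.803, max angle 40 deg, convolutedness 3.13
```

The planted decomposition is recovered exactly: the right-angle crossings
are resolved, the two filaments sharing an edge are both returned in full
(the shared edge is covered twice), and the closed loop comes back as one
closed path (filament 4, nine edges, maximal deflection 40°,
convolutedness ≫ 1). `JI^1 = 1` means every pair of adjacent edges is
grouped identically in the decomposition and the ground truth.

## Command line

```bash
filacover decompose input.gml --sampling bfs --cover overlap \
    --roughness pair --objective total --out-gml cover.gml --out-csv table.csv
filacover compare cover.gml manual.gml --d-list 1,2,inf
filacover simulate --filaments 6 --seed 1 --out scene.gml --out-truth truth.gml
filacover robustness noise scene.gml truth.gml --instances 25 --out curve.csv
```

Input graphs are GML with node coordinates (`x`/`y`(/`z`), top-level or in a
`graphics` block) and a positive `weight` per edge. `decompose` writes a GML
whose edges carry the covering filament ids (`filaments="0;2"`, lowest id in
`filament` as a colour key) and a CSV of per-filament measures (edge count,
geometric length, mean weight, both roughnesses, maximal deflection angle,
median orientation, convolutedness, node sequence). `--sweep` runs all 16
option combinations.

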
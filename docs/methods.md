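# Methods

## Model and assumptions

A filamentous structure is represented as a simple, undirected geometric
graph: every node has a 2D or 3D position, every edge a finite positive
weight interpreted as the local intensity/thickness of a filament segment
(typically normalised so the brightest segment has weight 1; `filacover`
never rescales on load — `normalize_weights` and the CLI `--normalize` flag
exist for callers who want the max-1 convention). Self-loops and parallel
edges are rejected at load: the path and roughness definitions presuppose a
simple graph, and graphs extracted from images are simple.

A filament is an edge-path: an ordered sequence of pairwise-adjacent edges
in which no edge repeats; a path whose first and last node coincide models
a closed loop. A filament cover is a set of edge-paths that covers every
edge at least once (overlaps allowed) or exactly once (exact cover). The
decomposition problem is: among covers assembled from a candidate path
pool, find the one of minimum total — or minimum average — roughness.

### Roughness

Two weight functionals score a path of `P` edges with weights
`w_1, …, w_P`:

- pairwise: the mean absolute difference between adjacent edge weights.
  For an open path that is `Σ_{i<P} |w_{i+1} − w_i| / (P−1)`. For a
  *closed* path the first and last edges are also adjacent, so the seam
  difference `|w_1 − w_P|` enters and the mean runs over `P` pairs. This
  departure from the open-path formula is deliberate: without the seam
  term a loop's roughness would depend on which rotation of the cycle the
  traversal happens to start at, which is meaningless for a closed curve
  and incompatible with storing one canonical representative per loop.
- all-to-all: the mean over edges of each edge's maximal absolute weight
  difference to any other edge of the path,
  `Σ_i max_j |w_i − w_j| / P`. The phrase "average maximal difference
  between any two edge weights" admits a second parse — the plain range
  `max(w) − min(w)` — which is available as
  `all_to_all_roughness(..., variant="range")`; the per-edge-max mean is
  the default because it is the literal reading of "average maximal".

Both functionals score a single-edge path by its own edge weight. That
convention is what gives the set-cover objective its shape: fragmenting a
filament into bright singletons is expensive, while extending a smooth run
is nearly free. It also makes results depend on the weight scale, which is
why normalisation is left to the caller rather than applied silently.

The angular functional `max_deflection_angle` orients every edge along the
traversal direction and returns the maximum Euclidean angle between
consecutive segment vectors (plus the seam deflection for closed paths);
0° is a perfectly straight filament. Dot products are clipped to [−1, 1]
before `arccos`.

## Candidate path sampling

The pool of candidate paths is sampled, not exhaustive (the unrestricted
problem is intractable — it embeds Hamiltonian-path-type decisions even on
planar graphs):

- **BFS** (default): breadth-wise extension of partial paths from every
  starting edge, pruning an extension as soon as its newest deflection
  angle reaches the straightness threshold (default 60°, strict `<`).
  Pruning is sound because a path's maximal deflection never decreases
  under extension, so the enumeration returns *every* path of the graph
  meeting the criterion. A partial path may close into a loop only at its
  own start node, and the seam deflection is then checked too — this is
  what lets gently curved loops enter the pool in one piece. The paths are
  deduplicated in a canonical orientation (lexicographically smaller of
  the two traversals; loops additionally rotated to start at their minimal
  node). Enumeration is capped (default 10⁶ paths) and fails loudly rather
  than truncating silently.
- **RMST**: `T = 100` repetitions; each draws i.i.d. uniform(0,1)
  auxiliary edge weights, computes the minimum spanning tree (per
  connected component) and contributes the unique tree path between every
  node pair. Trees are loop-free, so closed filaments can only be
  recovered piecewise — the expected over-segmentation of loops under this
  sampler is a feature of the comparison, not a bug.

Single-edge paths are always appended, which guarantees feasibility of
both covering modes and realises the single-edge cost convention.

## Solving the cover program

The edge-by-path incidence matrix and per-path costs form a binary linear
program: minimise `Σ r_p x_p` subject to per-edge covering rows (`≥ 1` or
`= 1`). It is solved to proven optimality with HiGHS through
`scipy.optimize.milp` with the MIP gap set to 0; returned covers are
re-verified against the covering constraints independently of the solver.
The average objective `Σ r_p x_p / Σ x_p` is a fractional 0-1 program
solved by Dinkelbach iteration: repeatedly minimise `Σ (r_p − λ) x_p`
under the same constraints and update `λ` to the incumbent ratio, stopping
when the parametric optimum is `≥ −10⁻⁹` (iteration cap 100, λ initialised
at the average cost of the always-feasible all-singletons cover; the λ
sequence is checked to be non-increasing). Dinkelbach is exact and finite
for ratio objectives with positive denominator, so it is an
optimality-equivalent route to the fractional program rather than a
heuristic.

Among multiple optimal covers the solver's incumbent is accepted; tests
compare objective values, never path identities, except where the optimum
is provably unique.

## Comparing covers

Two covers of the same graph are compared as labellings of the edge set.
For a pair of distinct edges, "same" in a labelling means the two edges'
membership sets intersect — for exact covers this is ordinary co-membership,
and it is the minimal consistent extension to overlapping covers. The four
pair counts (same/same, same/different, …) give the Rand index
`(h₌₌ + h≠≠)/total` and Jaccard index `h₌₌/(h₌₌ + h₌≠ + h≠₌)`.

The structure-aware variants `RI^d`/`JI^d` restrict the counted pairs to
edges separated by at most `d` nodes. Edge separation is
`D(e, f) = min` over endpoint pairs of shortest-path length (in edges), and
a pair is admissible at bound `d` iff `D ≤ d − 1`; the convention is fixed
so that `d = 1` admits exactly the pairs of adjacent edges, and `d = ∞`
recovers the classical indices. This numbering choice silently changes
every `RI^d`/`JI^d` value, hence it is stated here explicitly.

The variation of information `VI = H(A) + H(B) − 2 I(A;B)` (natural
logarithm, probabilities from filament edge-count fractions) is defined for
non-overlapping covers only and raises on overlapping input.

Filament identities between two covers are matched by a rectangular linear
assignment (`scipy.optimize.linear_sum_assignment`) maximising the total
number of shared edges over matched pairs; surplus filaments stay
unmatched.

## Per-filament analytics

For each filament: edge count, geometric length (sum of Euclidean segment
lengths), mean edge weight, both roughnesses, maximal deflection angle,
median orientation (acute angle in [0°, 90°] between each edge and a
reference axis — defaults to the x-axis, configurable because a biological
"cell axis" is dataset-specific — folded so the value is direction- and
reversal-invariant), and convolutedness: geometric length over the largest
side of the axis-aligned bounding box, 1 for straight axis-aligned
filaments and defined as 1 for zero-extent boxes. Convolutedness is *not*
rotation-invariant (a straight filament at 45° scores √2); this known
orientation bias is preserved, not corrected, and the maximal deflection
angle is the orientation-free alternative. Component lengths (total edge
length per connected component) are exposed for contrast with per-filament
lengths, and a Pearson correlation matrix of the numeric per-filament
measures is available.

## Synthetic scenes

The generator draws filaments as polylines with bounded turning
(`turn_max_deg`, default 45°, strictly below the BFS threshold so every
planted filament is in the BFS pool), closes a filament into a regular
polygon loop with probability `p_loop` (the polygon order is the smallest
count whose deflection is below the turning bound), and with probability
`p_overlap` routes a filament along an exactly-copied vertex run of an
earlier filament, producing shared edges. Wherever two polylines cross, a
node is inserted at the intersection (computed with shapely) splitting
both segments; crossings at shared vertices merge through a coordinate
registry, T-junctions split only the pierced segment, and collinear
partial overlap between non-identical segments is rejected as degenerate
(the generator retries with fresh randomness).

Edge weights: each filament has a base intensity drawn from
`base_intensity_range` (default (0.8, 0.9)) modulated by a smooth taper of
relative amplitude `intensity_modulation` (default 0.25) along its arc
position — a linear ramp with random direction for open filaments, a
periodic asymmetric triangle for loops with its turning points snapped to
edge centres so the gradient magnitude never degenerates. An edge covered
by several filaments sums their local intensities, the sum is clipped at 1
(detector saturation: overlaps brighten abruptly but do not double), and
centred Gaussian noise of sd `weight_noise_sd` (default 0.02) is added,
with a floor of 10⁻⁶ keeping weights positive.

Why the taper matters: with constant per-filament intensities, whether the
optimal cover keeps a long smooth path whole or splits it at a
noise-inflated weight difference is decided by noise alone — the margin
and the perturbation both scale with the noise sd, so a few percent of
random scenes would be mis-decomposed at *any* noise level. A steady
intensity gradient (chosen ≳ 2.4× the sd of a noise difference at default
settings) gives whole filaments a structural advantage, so planted
decompositions are identifiable from the weights. One residual ambiguity
is inherent: at a shared-run overlap, the two ways of pairing entries with
exits have exactly equal cost under any intensity assignment (the boundary
jumps redistribute but their sum does not change), so which filament
"continues through" the overlap is decided by noise. The structure-aware
`JI^1` is unaffected — all adjacent pairs agree either way — which is
precisely the argument for structure-aware comparison; the global `JI`
dips slightly when the tie resolves against the reference.

`contrived_scene` is a fixed five-filament layout exercising all features:
two straight filaments crossing at right angles (right-angle crossings are
never traversable by the 60° BFS), an overlap corridor whose tails are one
edge long (so any fragmentation of it must pay a full singleton weight),
and a disjoint nine-sided loop (deflections 40°). Only the weight noise
depends on the seed. Across 200 seeds, the default decomposition recovers
the planted cover with `JI^1 = 1` in 198; the two failures split the loop
under unusually adversarial noise — an honest reflection of the method's
behaviour, not an artefact.

What the generator does *not* emulate: point-spread blur and pixelation,
networks with high-degree junction clusters, spatially correlated noise,
curvature beyond the turning bound, and 3D scenes. Passing tests therefore
show correctness of the optimisation and measures under the stated model,
not image-level performance.

## Robustness protocols

Two stress tests score decompositions against the planted cover by mean
`JI^1`:

- edge removal: for `k = 1 … k_max`, delete `k` uniformly chosen edges
  (several samples per `k`), re-solve, and compare on the surviving edge
  set (the reference is restricted, since deleted edges cannot be
  covered);
- weight noise: perturb every weight by centred Gaussian noise of sd equal
  to a fraction of that weight, re-solve per instance. The candidate pool
  depends only on topology, so it is sampled once and re-costed per
  instance.

At the default scene both protocols show the expected behaviour: no
measurable decline per removed edge, well under 0.001 decline per 1% of
weight noise up to 20%, and a plateau well above zero at 100% noise —
the angle-constrained topology alone pins down most of the decomposition
even when the weights are uninformative.

## Numerical choices and problem sizes

- GML/CSV print precision: 6 significant digits (reproducible text diffs).
- Coordinates merge at 10⁻⁹ rounding; vertices closer than 10⁻⁷ after
  splitting are a degeneracy.
- MIP gap 0; Dinkelbach tolerance 10⁻⁹, cap 100 iterations.
- The test suite and the acceptance script use deliberately small problem
  sizes — scenes of ~23 edges, oracle instances of ≤ 8 edges and ≤ 15
  candidate paths (60–200 instances), 25 noisy instances per level, removal
  up to 8 edges — chosen so the whole validation runs in seconds while
  still exercising every code path; the solver itself handles the
  candidate pools of hundreds to thousands of paths produced by the
  samplers without special handling.

## Known limitations

- The candidate pool bounds attainable covers: no optimality statement is
  made relative to the unrestricted problem (which is intractable).
- BFS enumeration can explode on graphs with many near-straight
  alternatives at high degree; the cap turns this into an explicit error.
- Convolutedness inherits the bounding-box orientation bias by design.
- `VI` is unavailable for overlapping covers.
- Distribution fitting and hypothesis testing on the per-filament measures
  are out of scope; the CSV/correlation outputs are meant to feed standard
  statistics tools.
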
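# Methods

This document defines the models implemented by `gyrihinge`, the default
parameters, the scope of the synthetic generators, and the numerical and
design decisions that shape the results.

## 1. Surface model and 3-hinge detection

A cortical surface is a closed-or-bordered triangulated 2-manifold
(`SurfaceMesh`): vertices in mm, triangle faces, optional per-vertex
*gyral altitude*. Altitude is the signed distance from each vertex to a
smoothed mid-surface (200 rounds of uniform Laplacian smoothing,
λ = 0.5), projected on the outward vertex normal — gyral crowns are
positive, sulcal fundi negative.

Hinge detection is a four-stage geometric pipeline (`detect_hinges`):

1. **Watershed crest segmentation** (`watershed_segment`). Vertices below
   the crest level (default 0 mm) are flooded in ascending altitude
   order from plateau-aware regional minima. A vertex reached by two or
   more distinct basins is a flooding-collision ridge. The *crest mask*
   is the union of the at/above-level region and the collision ridges;
   each basin is edge-connected and represents one sulcal catchment.
2. **Geodesic distance transform** (`distance_transform_crest`).
   Multi-source Dijkstra over mesh edges from the crest/basin boundary
   into the crest, giving each crest vertex its geodesic depth inside
   the gyral ridge band. Non-crest vertices are NaN.
3. **Tree marching** (`build_crest_trees`). Crest vertices are attached
   in descending distance order to their highest-distance already-claimed
   neighbour, producing a forest of marching trees rooted at local
   distance maxima (the ridge centrelines).
4. **Branch-depth pruning** (`prune_and_extract`). The significance of a
   branch is its maximum downstream geodesic path length. At every tree
   vertex the deepest child branch (the trunk continuation) is always
   kept; any other child branch is deleted when its downstream length is
   below the threshold (default 6× the median edge length). The rule
   removes every spur shorter than the threshold, including nested ones,
   never erodes the trunk, and is idempotent — pruning the pruned graph
   is a no-op, which the test suite verifies. Surviving vertices with
   trunk-graph degree ≥ 3 are hinges; degree 3 identifies a 3-hinge.

## 2. Parcellation and patch classes

`equal_area_parcellate` grows patches by seeded area-balanced region
growing: farthest-point seeding on mesh geodesics, then repeated
assignment sweeps in which the currently smallest patch claims adjacent
unassigned or stealable vertices, followed by a connectivity repair pass.
Patches cover the surface, are edge-connected, and their areas stay
within a modest factor of the target (observed max deviation ≈ 22% at
200 patches on the synthetic sheets).

`label_patches` assigns each patch one of three convolution classes:

- **SULCAL** if the majority of its area lies below the crest level
  (the sulcal rule wins over hinge content);
- **H3** if it is gyral and contains at least one detected 3-hinge;
- **H2** if it is gyral and hinge-free.

On the synthetic demo sheets most of the area is sulcal basin, so a
100-patch parcellation typically yields only ~5–10 gyral patches. This
is sufficient for the end-to-end demonstration pipeline, but group
statistics in validation therefore run on the network-cohort generator
(§6), which plants class labels directly at controlled sizes.

## 3. Connectome construction

Streamline endpoints are snapped to the nearest surface vertex within
2 mm (default); farther endpoints are non-cortical. Each streamline
becomes an order-normalised patch pair. `build_connectivity` counts
pairs into a symmetric weight matrix and returns an audit dictionary
(within-patch and non-cortical exclusions) satisfying exact fiber
conservation: `W.sum()/2 + within + noncortical == total fibers`. Counts
are never normalised, so the generator → connectome round trip is exact
and integer.

`class_connection_counts` aggregates fiber counts into a 3×3 table over
{H3, H2, NON(-gyral)} endpoint classes, dividing by the summed patch
surface area per class pair (in cm² by default) to correct for the very
different total areas of the classes.

## 4. Nodal graph metrics

All six metrics operate on nonnegative symmetric weight matrices with
zero diagonal; shortest paths use edge lengths `1/w`.

- **Degree**: count of nonzero-weight neighbours.
- **Strength**: sum of incident weights.
- **Betweenness**: weighted Brandes betweenness, unnormalised, each
  unordered pair counted once.
- **Local efficiency**: for node i with neighbourhood N(i), the mean over
  ordered neighbour pairs (j, h) of
  `cbrt(w_ij · w_ih / d_{N(i)}(j, h))`, where the path length is computed
  in the subgraph induced by N(i); divisor `k(k−1)`.
- **Clustering**: Onnela's weighted clustering — the cube-root triangle
  intensity with weights scaled by the global maximum, divided by
  `k(k−1)`.
- **Participation**: `1 − Σ_m (d_im / d_i)²` with binary degree counts
  over modules from seeded Louvain modularity maximisation at resolution
  γ (default 1). Communities are sorted by their smallest member, making
  module ids deterministic for a fixed seed.

Every metric is validated against an independent brute-force oracle
(Floyd–Warshall paths, explicit path counting with tie tolerance 1e-12,
triple loops) on random weighted graphs; observed deviations are at
machine precision, asserted below 1e-9.

## 5. Decompositions and ratio curves

The **s-core** at level s is the maximal subgraph in which every
surviving node has residual strength ≥ s, computed by iterative node
deletion to a fixpoint. This is the weighted analogue of the k-core, and
on unit-weight graphs with integer s it coincides exactly with the
classical k-core (verified against `networkx.k_core` on 50 random
graphs). A strictly harsher variant that additionally deletes individual
edges of weight < s before the node fixpoint is available behind the
`edge_prune` flag; it is *not* the default because it breaks the k-core
correspondence (at s ≥ 2 it deletes every unit edge outright).
The **nodal-strength decomposition** is the single-pass filter keeping
nodes whose intact-network strength is ≥ s; its survivor sets are also
nested, but it ignores cascade effects.

**Ratio curves** track the fraction of surviving nodes per class as s
rises over a linear grid from 0 to the maximum nodal strength (50 levels
by default). Levels with no survivors have NaN ratios. In hub-enriched
networks the H3 curve climbs with s and eventually strictly exceeds the
H2 curve — the *crossing event*.

The **crossing permutation test** exploits that survivor sets depend only
on the network, not the labels: masks are computed once, then class
labels are shuffled (preserving class sizes) and the crossing event is
re-evaluated per permutation; `p = (1 + #events) / (1 + n_perm)`. A
caveat: near the top of the grid the surviving set can shrink to a
handful of nodes regardless of labels. For the single-pass
nodal-strength method the top survivors are simply the highest-strength
nodes, so a random labelling assigns an H3 label to the last survivor
with probability ≈ n_H3/n, which lower-bounds the achievable p-value
(≈ 0.125 at the default class sizes). The s-core method does not suffer
this floor to the same degree because deep cores contain many nodes;
stringent p-value assertions are therefore made for the s-core method
only, while the crossing *fraction* is asserted for both.

## 6. Group statistics

Metric tables are z-scored within subject over all patches before
pooling, removing subject-level offsets. Group contrasts (H3 vs H2) use
Welch's t-test and a size-preserving label permutation test. The
permutation statistic is the **absolute** difference of class means,
evaluated identically on the observed and every shuffled labelling.
Using a post-hoc directed statistic (sign chosen from the observed data)
against a one-sided null would double the type-I error; with the
absolute statistic the measured type-I error at α = 0.05 is 0.03–0.07
over 600 null cohorts at 200 permutations, as asserted in the acceptance
suite. When `subject_id` is supplied, labels are shuffled within subject,
preserving per-subject class sizes (exchangeability under
subject-specific offsets).

## 7. Functional involvement

A signal matrix X (t × n, one column per vertex) is factorised as
X ≈ D·α with an overcomplete dictionary (k atoms) and lasso-sparse
coefficients, via scikit-learn's mini-batch dictionary learning
(coordinate-descent fitting and coding, seeded epochs of seeded
mini-batches, hence fully deterministic). The **involvement** of a vertex
is ‖α_i‖₀, the number of atoms with nonzero coefficient in its column.

The default SVD dictionary initialisation produces atoms that are dense
mixtures of the underlying sources, and the online updates rarely
untangle them — on planted 1-sparse data this inflates the median
involvement from 1 to ~9 despite near-perfect reconstruction. The
learner is therefore initialised by greedy farthest-point selection of
maximally decorrelated signal columns (max–min absolute cosine), which
starts the atoms at near-pure sources. With this initialisation the
noiseless 1-sparse recovery test achieves median involvement exactly 1
and relative reconstruction error < 0.005 at k = 2× the true atom count.
Coordinate-descent iteration caps are raised to 5000 for the final
coding pass so the lasso converges to exact zeros.

## 8. Synthetic generators: scope and limits

- **Folded surfaces** (`gen_folded_surface`): rectangular triangulated
  sheets whose altitude is a sum of Gaussian ridge bumps (height 4 mm,
  σ = 1.5 mm, basin depth 1.5 mm) along a planted skeleton of Y-shaped
  junction elements (arm length 12 mm) placed on a non-overlapping grid,
  plus optional straight ridges. Junction locations are analytic, so
  recovery is scored by 2-D distance matching (3 mm radius): measured
  sensitivity ≥ 0.96 and spurious rate ≤ 0.01 over 20 surfaces × 5
  junctions. Limits: sheets are flat (no curvature confound), ridges do
  not intersect except at planted junctions, and altitude is given
  analytically rather than recomputed from folding geometry.
- **Network cohorts** (`gen_network_cohort`): weighted modular graphs
  (4 modules, within/between edge probabilities 0.35/0.05, log-normal-ish
  positive weights with multiplicative noise). A planted H3 minority
  receives (1 + boost) on edge probability and weight, elevated
  cross-module probability, and a rich-club term densifying H3–H3 pairs
  (probability floor `rich_club_prob · min(boost, 1)` and a second
  (1 + boost) weight factor). The rich-club term is part of the hub
  model: without it the planted hubs' strength rests on spokes to
  non-hubs and the hub set collapses in a single s-core cascade, so no
  generator of this family could exhibit the crossing behaviour the
  decomposition is designed to detect. Because the term is scaled by
  min(boost, 1), setting boost = 0 (and cross-module probability to
  background) yields an exchangeable null cohort, which the calibration
  tests rely on. Subjects draw from counter-derived independent seed
  streams, so cohorts are order-independent and reproducible.
- **Streamlines** (`gen_streamlines`): realises a requested symmetric
  integer patch-pair count matrix exactly, sampling endpoint vertices
  inside each patch and connecting them with smooth 3-D polylines lifted
  off the surface. Endpoints lie exactly on surface vertices, so
  endpoint snapping recovers the requested matrix with zero error.
- **Signal matrices** (`gen_signal_matrix`): X = D·α + noise with
  random orthonormal-ish atoms and exactly `sparsity` nonzero
  coefficients per column, the ground truth for dictionary recovery.

## 9. Numerical choices

- Shortest-path ties in the betweenness oracle are resolved with an
  absolute tolerance of 1e-12 on path lengths.
- All permutation p-values use the add-one correction
  `(1 + hits) / (1 + n_perm)`, so p = 0 is impossible and the tests are
  valid at finite n_perm.
- Seeds everywhere are plain integers < 2³¹; derived streams use
  `numpy.random.SeedSequence([master, salt])`, never arithmetic on the
  master seed, avoiding stream collisions.
- CSV outputs are written with `%.10g` float formatting and the manifest
  stores SHA-256 checksums; the pipeline is asserted byte-identical
  across reruns with the same configuration.
- The demonstration pipeline multinomially thins a planted weight matrix
  into an integer fiber-count matrix, so connectome counts remain
  integers end to end.

## 10. Limitations

- Synthetic surfaces are flat sheets; detection on closed, curved
  cortical meshes is implemented by the same code path (nothing assumes
  planarity except the generators' ground-truth scoring) but is not
  validated against real data here.
- The parcellation balances area greedily; it does not solve an optimal
  partition problem and its balance factor degrades on very elongated
  patches.
- Louvain modularity is a stochastic heuristic; determinism is per seed,
  not per graph, and participation coefficients inherit that dependence.
- The crossing permutation test's p-value floor for the nodal-strength
  method (§5) is a property of the event definition, not of the
  implementation.
- Dictionary learning guarantees exact-zero coefficients only through
  the lasso; correlated true atoms (coherent dictionaries) can still
  split a vertex's energy across atoms and inflate involvement.
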
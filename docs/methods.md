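# Methods

This note documents the models, algorithmic choices, numerical conventions
and known limitations of `conparc`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Dense connectomes and coarsening

A dense connectome is the discrete analogue of the intensity function
`λ(x, y)` of a symmetric inhomogeneous Poisson point process over the union
`Ω` of two topologically spherical hemisphere surfaces: a symmetric
nonnegative `K×K` matrix with zero diagonal on the `K` mesh vertices.
Given a partition `{E_1, …, E_L}` of the vertices, the coarse connectome is
the block sum

    ω(E_a, E_b) = Σ_{u∈E_a} Σ_{v∈E_b} W_uv ,

the discrete realization of the double integral of the intensity, i.e. the
expected number of observed tracts between regions. Total mass is conserved
exactly (asserted to 1e−9 relative tolerance in tests).

## Modularity and the Louvain hierarchy

Modularity is computed in the standard Newman convention with
`m = Σ_{u,v} W_uv` over **ordered** pairs, so the single-community partition
scores exactly 0 and `Q ∈ [−1, 1]`. The resolution parameter is fixed at 1.

The flat clustering step delegates to python-igraph's `community_multilevel`
(the canonical Louvain implementation); our own `modularity()` is
implemented independently and validates every delegated result (it must
score at least the all-singleton partition, else the call fails loudly).
Determinism: a seeded vertex permutation is applied before clustering and
igraph's RNG is seeded per call, so the same seed reproduces the same
partition bit-exactly within one build.

Hierarchy: level 1 clusters the full graph; each deeper level re-clusters
every parcel's induced subgraph as an independent graph (edges leaving the
parcel are dropped; original edge weights kept). Parcels with fewer than
`min_parcel_fraction · K` vertices (default 1%) and parcels whose induced
subgraph has no edges are copied unchanged. Per-parcel sub-seeds are derived
deterministically from `(random_seed, level, parcel)` via `SeedSequence`.
Subject-level hierarchies are nested refinements by construction; ensemble
outputs are not constrained to be nested.

## Partition distance and the hard ensemble

Partitions are equivalence classes of label vectors up to relabeling; the
canonical form renumbers labels 0…L−1 in order of first appearance. The
membership matrix `P` is binary `K×L` with exactly one nonzero per row;
matrices with fewer clusters are zero-padded on the right when compared.

The distance `d(C_i, C_j) = min_π ‖P_i − P_j π‖²_F` is solved exactly by
the Hungarian algorithm on the contingency-overlap matrix (for hard
partitions `‖P‖²_F = K`, so the minimum equals `2K − 2·max-assignment`);
greedy matching is never used, because it can miss the minimum. The distance
is a pseudometric on label vectors and vanishes iff the partitions are
equivalent (verified against exhaustive permutation search in tests).

The HE consensus absorbs partitions successively: the running membership is
a row-stochastic soft matrix; each new subject is aligned by the same
assignment solve (maximizing the overlap with the running average) and folded
in with weights `(t−1):1`, which makes the final result an unweighted mean
under fixed alignments. Hardening takes per-row argmax with ties broken
toward the lower column index; empty labels are dropped, then canonicalized.
The procedure is order-dependent; the default is input order, and the
order-permutation experiment drives `order_seed` explicitly.

HE is a *greedy* approximation of the Karcher mean. On coherent cohorts —
perturbed copies of one underlying partition, which is the regime the method
targets — it attains the brute-force global optimum on all tested 6-element
fixtures; on cohorts of unrelated uniform-random label vectors it can and
does end above the optimum, as expected for a greedy minimizer of an
NP-complete objective.

Baselines: CSPA builds the co-occurrence matrix `S[a,b] = #{i : C_i(a) =
C_i(b)}` from the deepest individual level, zeroes its diagonal, and
clusters it (unthresholded) with the same three-level Louvain hierarchy;
"Average" clusters the mean connectome `W* = (1/N) Σ W_i` the same way.

## Comparison metrics

* **Piecewise-constant approximation / KL.** `γ` takes the block mean
  `ω(E_i, E_j)/(|E_i||E_j|)` with `|E|` = vertex counts. For KL, both `λ`
  and `γ` are restricted to off-diagonal unordered pairs, renormalized to
  probability distributions, and compared with natural log and the
  convention `0·log 0 = 0`. KL ≥ 0, vanishes iff `λ` is block-constant on
  the partition, and is non-increasing under refinement (log-sum
  inequality; asserted numerically on random nested fixtures).
* **AMImax.** `AMI = (MI − E[MI]) / (max(H(X), H(Y)) − E[MI])` in natural
  log. `E[MI]` is the exact expectation under the fixed-marginal
  (hypergeometric permutation) model, evaluated in log-space with `gammaln`
  for stability; it is cross-checked against a Monte-Carlo permutation
  average and against scikit-learn's implementation in tests. Equivalent
  partitions return exactly 1 (detected by canonical-form equality, which
  also covers the zero-denominator case); a zero denominator otherwise
  returns 0.
* **Minimal-cover Dice.** For an anatomical region `X`, the minimal cover
  `Y*` in a partition is the union of all regions intersecting `X` (unique
  for partitions), and `Dice = 2|X| / (|X| + |Y*|)`.
* **Symmetry.** AMI between the labels of left-hemisphere vertices and the
  labels of their mirror images.
* **Contiguity.** Fraction of vertices whose label induces exactly one
  connected component in the mesh adjacency graph ("simply connected" is
  implemented as single-component; genus detection is not attempted).
* **Coarse-graph characteristics.** Coarse graphs are near-complete, so
  binary measures degenerate; we use the weighted forms: Onnela
  geometric-mean clustering coefficient on weights rescaled by the maximum
  (scale-invariant), and average shortest-path length over connected
  unordered pairs with edge length `1/weight` (scales inversely with a
  global weight factor). Both definitions are recorded in every report.
* **Ensemble goodness.** Mean AMI of a consensus to the individual
  partitions it aggregates.

## Synthetic cohorts

The generator emulates mirrored, spatially smooth, block-structured
connectome cohorts:

* **Mesh.** Two unit icospheres (order-`n` subdivision: `10·4ⁿ+2` vertices,
  `30·4ⁿ` edges, `20·4ⁿ` faces each), the right one mirrored through the
  `x = 0` plane, mirror correspondence by index. Order 5 gives the 10,242
  vertices per hemisphere used for resampled cortical surfaces.
* **Planted truth.** Geodesic Voronoi cells from farthest-point-sampled
  seeds (multi-source Dijkstra on edge lengths), grown on the left
  hemisphere and mirrored — cells are connected by construction. A
  two-level hierarchy subdivides each super-region the same way.
* **Subjects.** Each subject perturbs the deepest planted level by flipping
  a `label_noise` fraction of vertices to the label of a random
  differently-labeled mesh neighbor (boundary jitter; parents follow), then
  draws each edge as Poisson with a three-tier mean — `within_intensity`
  inside a sub-region, `within_super_intensity` between sub-regions of one
  super-region, `between_intensity` otherwise — times unit-mean lognormal
  noise with σ = `edge_noise`. Poisson counts honor the point-process
  framing; lognormal factors model subject variability.

Defaults (the study conditions of the test fixtures): mesh order 3
(642 vertices per hemisphere; order 5 is reserved for the mesh-combinatorics
check and the acceptance script, keeping the full pipeline fast), N = 20
subjects, 8 mirrored super-regions × 3 sub-regions, intensities 8 / 2 / 0.5,
10% label noise, 10% edge noise. The intermediate tier defaults to the
geometric mean `√(within·between)`: a hierarchy is only recoverable if the
tiers are ordered, and the geometric midpoint separates both scales without
favoring either. Smaller meshes (orders 1–2) are used where a test's
property does not depend on scale.

What the generator does **not** emulate: realistic cortical geometry and
folding, distance-dependent connectivity decay, tractography biases
(gyral-crown seeding, false-positive bundles), or heavy-tailed edge-weight
distributions. Passing tests therefore demonstrate correctness of the
algorithms and the recovery behavior under the stated block-model regime,
not performance on real diffusion-MRI connectomes.

## Experiments

* **Sparsity sweep.** Sparsification keeps the heaviest fraction `q` of
  nonzero upper-triangle edges per subject (global quantile; ties at the
  threshold all kept, so the edge sets are monotone in `q`). The sweep
  reports, per sparsity × method × level: region count, mean KL over
  subjects, ensemble goodness, symmetry, contiguity, and mean weighted
  CC/APL; plus intramethod similarity (mean pairwise AMI of one method's
  partitions across sparsity levels).
* **Stability.** Split-half: `n_splits` random disjoint half-cohorts
  (without replacement), one ensemble each, all `n(n−1)/2` pairwise AMI
  values. Order-permutation: HE re-run under shuffled absorption orders.
* **Classification.** A stratified half of the subjects drives the
  consensus (individual hierarchies + HE at the deepest level); the fixed
  consensus is applied to the held-out half by coarsening, and the
  upper-triangle coarse weights — including the diagonal, since
  within-region mass is part of the coarse connectome — are the features.
  Outer 5-fold stratified CV gives the AUC distribution; an inner 5-fold CV
  selects the L1 penalty on a logarithmic grid (10⁻²…10², 10 points);
  standardization is fit on training folds only.

## Numerical conventions and degenerate inputs

* Vertex indices 0-based; canonical labels by first appearance; all label
  I/O canonicalizes.
* Connectome invariants (symmetry, zero diagonal, nonnegativity) are
  asserted in every constructor; symmetrization of one-triangle input is by
  elementwise max; diagonal entries are dropped with a warning.
* Matrix Market writing uses precision 17, so save→load round trips are
  bit-exact.
* Modularity on an empty graph (m = 0) raises; CC on fewer than 3 regions
  raises; empty cohorts raise everywhere.
* Hardening ties and Voronoi distance ties break toward the lower index —
  deterministic and documented.
* All derived seeds come from `SeedSequence` and stay below 2³¹.

## Limitations

* HE is greedy and order-dependent; the order-permutation harness
  quantifies, but does not remove, that dependence.
* CSPA's co-occurrence matrix is dense `K×K`; at vertex resolution this is
  the memory bottleneck of the baselines.
* The piecewise-constant `γ` spreads diagonal-block mass over all `|E|²`
  cells including the (excluded) diagonal cells; after restriction and
  renormalization the effect is negligible for realistic region sizes but
  makes `γ` slightly below the exact off-diagonal block mean for small
  regions.
* GIFTI/FreeSurfer readers are thin conveniences for real data and require
  nibabel (optional extra); no surface registration is provided — inputs
  are assumed to be in dense vertex correspondence already.
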
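# Methods

This note records the models implemented in `mvmanifold`, the numerical
choices behind them, what the synthetic benchmark generator does and does
not emulate, and the known limitations. It is the companion to the README's
overview; nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Multi-view SNE family

### Model

For each view `m`, high-dimensional affinities follow the symmetric t-SNE
construction: Gaussian conditionals `p_{j|i} ∝ exp(−‖x_i−x_j‖²/2σ_i²)` with
per-point bandwidths `σ_i` calibrated by binary search so that
`2^{H(P_i)}` equals the requested perplexity, then
`p_ij = (p_{j|i}+p_{i|j})/2N`. One shared Student-t distribution
`q_ij ∝ (1+‖y_i−y_j‖²)^{-1}` (normalised over ordered pairs) describes the
embedding. Multi-SNE minimises `Σ_m w^m KL(P^(m)‖Q)` with `w` on the
simplex; the gradient is the `w`-weighted sum of per-view t-SNE gradients.
m-SNE runs ordinary t-SNE on the convex combination `Σ_m β^m P^(m)`.

With fixed weights the two cost functions differ by a constant that does
not depend on `Y`, so fixed-weight multi-SNE and m-SNE with `β = w` follow
the same trajectory at the same perplexity. The distinction matters
(a) when the weights adapt during the run, which only multi-SNE supports,
and (b) in practice, because the two methods are tuned to different
perplexities.

### Adaptive view weights

Weights start uniform and are frozen for the first 100 iterations while the
embedding takes shape. Afterwards, every iteration: normalise the per-view
divergences `k^(m) = KL(P^(m)‖Q)` to sum 1, set raw weights `1 − k^(m)`, and
renormalise to the simplex. The renormalisation step is ours: the two-step
rule alone leaves `Σ w = M−1`, which only lies on the simplex for `M = 2`;
renormalising preserves the intended ordering (lowest divergence, largest
weight) for every `M`. Weights are applied identically in the cost and the
gradient — they are the same coefficients. All divergences are reported in
nats; the weight trace is exported with the KL trace.

### Optimiser

Gradient descent with momentum 0.5 → 0.8 (switch at iteration 250), early
exaggeration ×4 for the first 100 iterations, learning rate 100 with
per-parameter adaptive gains (gain + 0.2 on sign disagreement between
gradient and velocity, × 0.8 otherwise, floored at 0.01), 1000 iterations,
and an N(0, 10⁻⁴) initialisation. The gains are part of the classic t-SNE
recipe and are load-bearing: without them, plain descent at this learning
rate settles in a compressed configuration whose clusters never separate.
They can be disabled (`OptimiserConfig(use_gains=False)`) — the cost is
then provably non-increasing for small learning rates, which the test suite
exercises. An optional stopping rule ends the run when the relative cost
change falls below `stop_tol` (default off: the iteration budget is fixed
so that runs are comparable). Everything is deterministic given the seed.

`q_ij` is floored at 10⁻¹² inside logarithms only; gradients use the exact
values. Duplicate points are legal (the Student-t kernel handles zero
distances); degenerate perplexity targets (e.g. two samples) produce a
warning and the best achievable bandwidth rather than an error.

### Pre-training

SNE-family methods first reduce each view: PCA on the centred view keeping
the smallest number of components whose cumulative explained variance
reaches 80 % (exact SVD, no scaling), or multiset CCA. The multi-CCA
variant whitens each view (ridge 10⁻⁶ · tr(C)/p on the covariance) and
takes the top eigenvectors of the whitened cross-correlation block matrix —
the SUMCOR-style relaxation. For two views this reduces exactly to
classical CCA (verified against a generalized-eigenproblem oracle); for
more views the per-view orthogonality of successive components is
approximate, which we accept in exchange for the eigenvalue ordering that
makes the achieved objective non-increasing by construction. Views are
centred, not scaled, in both modes.

## Multi-LLE

Per view: `Γ_i` is the K Euclidean nearest neighbours (ties broken by
sample index), and the reconstruction weights solve the local constrained
least-squares via the Gram system `G w = 1`, normalised to sum 1. When
`K > p_m` or the Gram matrix is ill-conditioned (condition number above
10¹²), a ridge `10⁻³ tr(G)/K` conditions the solve; it is never allowed to
fail. The consensus matrix `Ŵ = Σ_m α^m W^(m)` keeps rows stochastic as a
convex combination. The embedding is the `d` bottom eigenvectors of
`(I−Ŵ)ᵀ(I−Ŵ)` after discarding the constant eigenvector; eigenvector signs
are fixed by forcing the largest-magnitude entry positive.

The unconditional ridge deserves emphasis. A conditional rule (regularise
only when the Gram matrix is singular) looks harmless when K is well below
the feature count, but near-exact local reconstructions then create
localised near-null modes of `(I−W)ᵀ(I−W)` that occasionally hijack the
bottom eigenvectors: the embedding collapses to a spike around the origin
with a few outlying points, and clustering on it fails even though the
neighbour graph is clean. The always-on ridge — the convention of the
reference LLE implementations — suppresses these modes; its effect on
well-conditioned solves is negligible.

The sign convention exists because eigenvectors are sign-ambiguous and
m-LLE averages per-view embeddings — without a convention the average is
ill-defined. A side effect worth knowing: the convention *aligns* per-view
embeddings before m-LLE averages them, so m-LLE here is stronger than an
implementation that averages raw eigensolver output (whose effectively
random relative signs cancel structure). No Procrustes rotation is applied
— the method is a plain weighted average, and the rotation ambiguity is
accepted.

## Multi-ISOMAP

Per view: a symmetrised K-NN graph (edge if either endpoint lists the
other) with Euclidean lengths, K capped at N−1. The combined graph takes
the union of edges; each edge's length is the weight-averaged length over
the views in which the edge exists. Averaging over the union rather than
the intersection is our resolution of an ambiguity — the averaged-distance
formula is undefined for pairs that are neighbours in some views only, and
intersection graphs disconnect at small K. Geodesics are exact all-pairs
shortest paths (Dijkstra from every source; a hand-written Floyd–Warshall
serves as the test oracle). Classical MDS embeds the geodesic matrix:
eigen-decompose `τ(D) = −HSH/2`, keep the top-d positive eigenpairs, columns
`√λ_p u_p`, zero-mean by the double centring, signs fixed as in LLE. A
disconnected combined graph raises an error naming the remedy (increase K)
unless `largest_component=True`, in which case the largest component is
embedded and the surviving sample indices are attached to the result;
silently embedding mutually unreachable components would corrupt the MDS
geometry.

## Evaluation protocol

K-means (best of 10 seeded restarts) with the true cluster count, compared
with the ground truth by: accuracy under the optimal one-to-one
cluster-label assignment (rectangular assignment on the contingency table —
the standard clustering-accuracy convention), NMI with geometric-mean
normalisation (defined as 0 when either partition is trivial), Rand index,
adjusted Rand index, misclustering error `1 − ACC` and the silhouette
score. The tuning protocol runs a method over the admissible part of the
grid `{2, 10, 20, 50, 80, 100, 200}` (values ≥ N dropped), repeats
stochastic methods, reports mean (sd) per measure, and selects the highest
mean accuracy with NMI as tie-break. Within a tuning run, K-means is seeded
identically across replicates so that the reported spread reflects the
method's stochasticity, not the clusterer's.

## Synthetic scenario generator

Each view draws every sample from `MVN(μ_g, I)` where `g` is the group of
the sample's cluster under that view's partition — a view separates exactly
the groups of its partition and nothing finer. Views listed as noisy
additionally receive `ε ~ MVN(0.5·1, I)`, doubling their variance. Each
(view, group) pair then gets a random polynomial (degree 2–4, coefficients
uniform on [−1, 1]) applied elementwise to make the group structure
non-linear, so that linear reductions cannot shortcut the problem.

Choices a reader should know, with their reasons:

* **Group means** are `μ_g = mu_scale · u` with `u` uniform on `{−1,+1}^p`,
  drawn once per (view, group). The separation scale is 3.75 for MMDS/NDS
  and 1.25 for MCS — chosen once, during design, so that the clustering
  difficulty of each scenario sits in the range the benchmark methods are
  known to produce (near-ceiling for multi-SNE on NDS, genuinely hard but
  solvable for the five-cluster scenario). Per-scenario scales mirror the
  fact that separation strength is a property of each simulated data set.
* **Polynomials act per group, not per cluster.** A per-cluster transform
  would let every view distinguish every cluster (and would imprint cluster
  structure even on the pure-noise view), destroying the defining property
  that each view separates only its own groups. Samples that a view merges
  stay indistinguishable in that view.
* **Polynomials act on the standardised block** and their output standard
  deviation is capped at √10 × the input's. Raw high-degree terms are
  dominated by their extreme tails; at realistic separation scales they
  shred the local neighbourhood structure the transform is meant to bend,
  not destroy.
* **Per-view random streams** are spawned independently from the seed, so
  adding a view (NDS = MMDS + noise view) leaves the shared views
  bit-identical.
* **MCS partitions**: view 1 `{A|B|CDE}`, view 2 `{C|DE|AB}`, view 3
  `{E|AC|BD}` with the extra noise on view 3. Jointly the partitions
  identify all five clusters while no single view does; the D–E pair is
  separated only by the noisy third view, which keeps the joint problem
  hard rather than saturated.

What the generator does **not** emulate: heterogeneous feature types,
count/sparse omics distributions, batch effects, unequal cluster sizes, or
correlated features within a view (covariances are identity). Passing the
synthetic benchmarks therefore demonstrates correct joint-structure
recovery under the stated generative model, not performance on real
multi-omics data.

## Known limitations and honest disagreements

* **Complete-graph multi-ISOMAP is near-perfect here.** With K = N−1 the
  combined geodesics equal the view-averaged Euclidean distances, and under
  every generator configuration in which multi-SNE and multi-LLE behave as
  expected, classical MDS of that average separates the NDS clusters almost
  perfectly (accuracy ≈ 1.0). Configurations that degrade it (uncapped
  raw-value polynomials at weak separation) push multi-LLE and multi-SNE
  far below their expected ranges. The benchmark value for this setting
  therefore reads high relative to published mid-range figures; the
  corresponding check is left failing rather than distorting the generator.
* The SNE optimiser is the exact O(N²) algorithm — no Barnes–Hut or
  interpolation acceleration — and is intended for N up to a few thousand.
* Multiset CCA's per-view orthogonality is exact only for two views.
* LLE/MDS eigen-embeddings use dense solvers; memory is O(N²).
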
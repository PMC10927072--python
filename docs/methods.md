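# Methods

## Scope and design

`scgeom` measures the geometry of a point cloud, not its biology: every
score is a function of coordinates alone. The package has five parts —
preprocessing (expression matrix → PCA point cloud), the DPT geodesic,
the five scores, the simulators, and the landscape classifier — each usable
on its own.

## DPT geodesic distance

The diffusion operator is built on a kNN graph (default
`n_graph_neighbors = 15`) with an adaptive Gaussian kernel: each point's
bandwidth σ_i is its distance to the k-th neighbor, and the edge weight is
`exp(−d_ij² / (σ_i² + σ_j²))`. The k-th neighbor is found with ties broken
by ascending point index, but the neighborhood then includes *every* point
within that radius; this tie-inclusive rule guarantees that coincident
points receive identical affinity rows and hence exactly zero DPT distance.
The affinity is symmetrized as `(W + Wᵀ)/2`, which makes the row-normalized
transition operator similar to a symmetric matrix and its spectrum real.
Eigenpairs are taken from the symmetric conjugate `D^{−1/2} W D^{−1/2}`
(dense `eigh` below n = 400, Lanczos above); eigenvalues within 1e−10 of 1
(the stationary vector, duplicated once per connected component) are
excluded, and the `n_diffusion_components = 10` largest remaining
eigenpairs enter

    dpt(i,j)² = Σ_s (λ_s/(1−λ_s))² (ψ_s(i) − ψ_s(j))²,   ψ = D^{−1/2} v.

Pairs in different graph components have no finite geodesic and are marked
infinite; `finite_fill` replaces them with 1.5 × the maximum finite
distance. m = 10 captures the dominant geometry at O(n·m) cost per pair;
both k and m are configuration fields, and for clouds smaller than k+1
(subset rescoring) the neighborhood is clamped to n−1.

## The scores

**Histograms.** Both entropy scores use 10 equal-width bins over
[min, max] of the observed values, natural log, 0·ln 0 = 0; a zero-range
input has entropy 0. The homology score applies `ln` to the entropy,
floored at 1e−12 so degenerate inputs return the finite sentinel
ln(1e−12) ≈ −27.63 rather than −∞.

**Persistence.** The 0-dimensional persistence deaths of a Vietoris–Rips
filtration coincide with the single-linkage dendrogram heights, i.e. the
minimum-spanning-tree edge weights; `zero_dim_merge_heights` therefore
computes them with single-linkage clustering on the (finite) DPT matrix,
and the test suite checks the multiset against an independent Kruskal
union-find oracle. The infinite bar of the last surviving component is
discarded — only merge events are recorded.

**Vector magnitude.** K = max(2, round(0.05·n)) K-means centers (one
deterministic initialization per repeat, single-threaded so reruns are
byte-identical). The walk starts at a uniformly drawn center, always moves
to the nearest *unvisited* center (revisits would oscillate between mutual
nearest pairs), and stops when the next hop exceeds the 20th percentile of
pairwise center distances. The summed steps telescope to (final − start),
whose p-norm is taken with p equal to the post-reduction dimension (5 when
PCA reduction occurred, the ambient dimension otherwise). Five repeats with
derived sub-seeds are averaged. Because each dataset is min–max scaled to
the unit box first, the score is scale-invariant — a deliberate property
with one consequence noted under Limitations.

**Ripley's K.** The classical density constant λ is omitted: both the data
curve and the uniform-reference curve are normalized to [0,1] by their own
maxima, under which any constant factor cancels. The reference is a seeded
uniform sample in the axis-aligned bounding box — the simplest convex
region containing all points, and the only one that stays samplable in 20
dimensions (hull-restricted sampling is combinatorially infeasible there).
Each matrix gets its own 100 equally spaced thresholds from 0 to its
maximum, the curves are compared index-by-index (i.e. as functions of the
normalized threshold), and the absolute difference is integrated by the
trapezoid rule over [0,1].

**Connectivity.** The neighbor-fraction grid is 0.05, 0.10, …, 0.95
(19 values; the endpoints are fixed, the step is a configuration choice).
Reachability excludes self — (component size − 1)/(n − 1) — so an isolated
point scores 0; the AUC is divided by the grid span so the score lies in
[0,1]. Note that mutual-kNN component structure depends on k relative to
cluster *sizes*, not on how far apart clusters are: the score separates
few-large-cluster data from continua much better than many-tiny-cluster
data.

**Seeding.** All stochastic steps (K-means repeats, walk starts, Ripley
reference) draw sub-seeds from `SeedSequence([seed, metric_index, repeat])`,
so `score_all` is a pure function of (coordinates, configs, seed).

## Simulators

The four dataset families are 2-D by construction. Defaults, all
configurable: n uniform in 200–1000; cluster count uniform in 2–8 with
means uniform in a 10×10 box (re-drawn while any two means are closer
than 1), flat-Dirichlet mixing proportions, isotropic components whose
standard deviations are scaled so that min mean separation / max σ equals
6 (clear) or a uniform draw from 2–4 (noisy); trajectories are sine belts
`(10 s, A sin(2π f s + φ))` with amplitude 1–3, frequency 0.75–2 periods,
random phase and planar rotation, isotropic noise of 0.05·A (clear) or
(0.2–0.5)·A (noisy); noisy trajectories bifurcate with probability 0.5
into a second branch (own amplitude and phase, attached continuously at a
branch point drawn from the middle 60 % of the arc, populated by 15–35 %
of the points). For a fixed seed the clear and noisy variants share every
structural draw — toggling the flag changes only dispersion — which is why
the separation constraint is enforced constructively (σ scaled to the drawn
means) rather than by rejection.

What the simulations emulate is the *geometry* the two analysis families
presuppose, not scRNA-seq data itself: there is no dropout, no library-size
variation, no high-dimensional noise floor. Passing the directional and
landscape tests therefore shows that the scores respond to geometry as
intended; it does not by itself certify performance on any particular real
dataset, where preprocessing choices add their own variance.

## Preprocessing

Gene filter (nonzero in ≥ 3 cells), cell filters (library size within
median ± 3 MAD; mitochondrial fraction ≤ 0.2, genes prefixed `MT-`),
median library-size normalization, log1p, top 2000 genes by dispersion
(variance/mean of the log-normalized values, ties kept in gene order),
PCA (full SVD, no whitening — whitening would rescale the geometry the
scores measure) to d = min(20, n_hvg, n−1). Cells are filtered before HVG
selection. These defaults are the common community pipeline; none are
claims about any particular published run.

## Landscape

Score columns are z-standardized before UMAP because the five scores live
on wildly different scales (entropies 0–2.3, the homology log down to its
−27.6 floor, AUCs in [0,1]); the stored location/scale make out-of-sample
projection consistent. UMAP runs with Euclidean metric, 30 neighbors,
min_dist 0.6, seeded (which forces single-threaded, reproducible layout).
Classification takes the 15 nearest embedded training sims; the trajectory
fraction counts both clear and noisy trajectory types; a tie at exactly 0.5
resolves to cluster_like. Classification uses the 2-D embedding; the test
suite separately verifies that the clear types are already ≥ 90 %
separable by leave-one-out kNN in the standardized 5-D score space, so the
separation is a property of the scores, not an embedding artifact.

## Numerical and degenerate-input choices

- Distance matrices must be exactly symmetric with zero diagonal; DPT
  output satisfies this by construction (condensed-distance round trip).
- Zero kernel bandwidths (coincident k-th neighbors) are guarded by the
  `d² = 0` limit; zero degrees are floored at the smallest positive float.
- `ripley_curve` refuses an identically zero curve; `finite_fill` refuses
  an all-infinite matrix; subsets below 10 points are skipped with a
  warning rather than scored.
- Constant dimensions in the vector-magnitude min–max scaling map to 0.
- K-means runs single-threaded: parallel reductions can perturb center
  coordinates in the last bits and break byte-identical CLI reruns.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the pipeline at desk scale,
chosen to exercise every code path at the default simulation conditions:
oracle equivalence on 50 clouds (n ≤ 100) for persistence and 20–10 clouds
(n = 40, full spectrum) for DPT; 100 simulations per type for the
directional medians and the landscape; 100 (suite) / 40 (script) held-out
simulations per clear type for classification. The landscape of the
original study (3000 per type) is reproducible with the same code via
`sim_batch(3000, …)`.

## Known limitations

- **Vector magnitude is scale-invariant.** Min–max scaling each dataset to
  the unit box means a short, nearly straight fragment of a trajectory can
  score as high as — or higher than — the full curve. Consequently,
  re-scoring the arc-pieces of a clear trajectory does *not* reliably
  lower this score (observed: every-piece-below-parent holds for roughly
  4 of 10 seeds), even though re-scoring the individual clusters of a
  mixture reliably lowers the Ripley score (10 of 10). The corresponding
  distributional assertion in the acceptance tests documents this gap.
- Mutual-kNN connectivity is blind to inter-cluster distances (see above).
- The landscape is only as representative as the simulators; datasets that
  are simultaneously cluster- and trajectory-like ("clusters of
  trajectories") project unstably between the regions. Rescoring per
  cluster (`score_subsets`) is the intended probe for such data.
- The DPT implementation targets clouds up to a few thousand points; the
  dense n×n distance matrices dominate memory beyond that.
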
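"""The five clusterness/trajectoriness scores.

Each score condenses one geometric aspect of a point cloud into a scalar:

1. ``score_pdist`` — entropy of the pairwise DPT distance histogram. Distinct
   clusters make the distance distribution multi-modal (peaky), lowering the
   entropy; a continuum spreads it out, raising it.
2. ``score_homology`` — natural log of the entropy of the 0-dimensional
   persistent-homology merge heights (the thresholds at which connected
   components of the distance filtration die). Cluster gaps concentrate the
   merges at a few scales; trajectories merge gradually.
3. ``score_vector_magnitude`` — over-cluster with K-means, greedily chain
   nearest cluster centers, and measure the p-norm of the summed step
   vectors. Steps along a trajectory align and accumulate; steps between
   arbitrary clusters cancel.
4. ``score_ripley`` — area between the (normalized, geodesic) Ripley K curve
   of the data and that of a matched uniform sample. Aggregation into
   clusters pulls the curve away from the uniform reference.
5. ``score_connectivity`` — area under the curve of median mutual-kNN
   reachability as the neighbor fraction sweeps 5%..95%. Clusters cap
   reachability at the cluster size until k grows past it; a trajectory
   chains everything together at small k.

All randomness flows from a single integer seed through documented sub-seed
derivations, making ``score_all`` reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.cluster.hierarchy import linkage
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from threadpoolctl import threadpool_limits

from .exceptions import DegenerateCurveError, DegenerateInputError, MetricError
from .geodesic import DiffusionConfig, DistanceMatrix, dpt_distance_matrix, finite_fill
from .preprocess import PointCloud

__all__ = [
    "HistogramSpec",
    "VectorWalkConfig",
    "RipleyConfig",
    "ConnectivityConfig",
    "ScoreConfigs",
    "ScoreVector",
    "histogram_entropy",
    "score_pdist",
    "zero_dim_merge_heights",
    "score_homology",
    "walk_vector_sum",
    "score_vector_magnitude",
    "ripley_curve",
    "score_ripley",
    "mutual_knn_reachability",
    "score_connectivity",
    "score_all",
]

_HOMOLOGY_ENTROPY_FLOOR = 1e-12


@dataclass
class HistogramSpec:
    """Histogram used by the entropy scores: equal-width bins, natural log."""

    n_bins: int = 10

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass
class VectorWalkConfig:
    """Parameters of the vector-magnitude score.

    kmeans_fraction: K = max(2, round(fraction * n)) cluster centers.
    stop_percentile: walk stops when the next nearest unvisited center is
        farther than this percentile of all pairwise center distances.
    n_repeats: K-means runs averaged over (each with its own sub-seed).
    pca_dim: clouds with d > pca_dim are PCA-reduced to pca_dim first.
    norm_p: order of the p-norm; defaults to the post-PCA dimensionality.
    """

    kmeans_fraction: float = 0.05
    stop_percentile: float = 20.0
    n_repeats: int = 5
    pca_dim: int = 5
    norm_p: Optional[int] = None

    def __post_init__(self):
        if not 0 < self.kmeans_fraction < 1:
            raise ValueError("kmeans_fraction must be in (0, 1)")
        if not 0 < self.stop_percentile < 100:
            raise ValueError("stop_percentile must be in (0, 100)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class RipleyConfig:
    """Parameters of the Ripley's-K score."""

    n_thresholds: int = 100
    reference: str = "bounding_box"

    def __post_init__(self):
        if self.n_thresholds < 2:
            raise ValueError("n_thresholds must be >= 2")
        if self.reference != "bounding_box":
            raise ValueError(f"unknown reference region {self.reference!r}")


def _default_fraction_grid() -> np.ndarray:
    return np.round(np.arange(1, 20) * 0.05, 10)


@dataclass
class ConnectivityConfig:
    """Neighbor fractions swept by the connectivity score (default 5%..95%)."""

    fraction_grid: Sequence[float] = field(default_factory=_default_fraction_grid)

    def __post_init__(self):
        g = np.asarray(self.fraction_grid, dtype=float)
        if g.ndim != 1 or len(g) < 2:
            raise ValueError("fraction_grid must hold at least 2 fractions")
        if np.any(g <= 0) or np.any(g >= 1):
            raise ValueError("fractions must lie in (0, 1)")
        if np.any(np.diff(g) <= 0):
            raise ValueError("fraction_grid must be strictly increasing")
        self.fraction_grid = g


@dataclass
class ScoreConfigs:
    """Bundle of all per-metric configurations used by ``score_all``."""

    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)
    histogram: HistogramSpec = field(default_factory=HistogramSpec)
    vector_walk: VectorWalkConfig = field(default_factory=VectorWalkConfig)
    ripley: RipleyConfig = field(default_factory=RipleyConfig)
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)


@dataclass
class ScoreVector:
    """The five named scalar scores of one dataset."""

    pdist_entropy: float
    homology: float
    vector_magnitude: float
    ripley: float
    connectivity: float

    FIELDS = ("pdist_entropy", "homology", "vector_magnitude", "ripley", "connectivity")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELDS], dtype=float)

    def as_dict(self) -> dict:
        return {f: float(getattr(self, f)) for f in self.FIELDS}


def _subseed(seed: int, *key: int) -> int:
    """Deterministic sub-seed < 2^31 derived from (seed, key...)."""
    return int(np.random.SeedSequence([int(seed), *map(int, key)]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# metric 1 — pairwise distance entropy


def histogram_entropy(values, spec: HistogramSpec = HistogramSpec()) -> float:
    """Shannon entropy (nats) of the equal-width histogram of *values*.

    Bins span [min, max]; counts are normalized to sum to 1; 0 * ln 0 := 0.
    Identical values (zero range) give entropy 0.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise DegenerateInputError("cannot take histogram entropy of empty input")
    if v.min() == v.max():
        return 0.0
    counts, _ = np.histogram(v, bins=spec.n_bins, range=(v.min(), v.max()))
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def score_pdist(dm: DistanceMatrix, spec: HistogramSpec = HistogramSpec()) -> float:
    """Entropy of the distribution of the n(n-1)/2 pairwise distances."""
    if dm.n < 3:
        raise DegenerateInputError(f"need at least 3 points, got {dm.n}")
    if not dm.is_finite:
        raise DegenerateInputError("distance matrix has non-finite entries; apply finite_fill")
    upper = dm.values[np.triu_indices(dm.n, k=1)]
    return histogram_entropy(upper, spec)


# ---------------------------------------------------------------------------
# metric 2 — persistent homology


def zero_dim_merge_heights(dm: DistanceMatrix) -> np.ndarray:
    """Finite death values of 0-dim persistent homology, ascending.

    As the distance threshold grows, connected components of the
    Vietoris-Rips filtration merge; the n-1 finite thresholds at which merges
    occur are exactly the single-linkage dendrogram heights (equivalently,
    the minimum-spanning-tree edge weights). The infinite bar of the last
    surviving component is excluded.
    """
    if dm.n < 2:
        raise DegenerateInputError(f"need at least 2 points, got {dm.n}")
    if not dm.is_finite:
        raise DegenerateInputError("distance matrix has non-finite entries; apply finite_fill")
    heights = linkage(squareform(dm.values, checks=False), method="single")[:, 2]
    return np.sort(heights)


def score_homology(dm: DistanceMatrix, spec: HistogramSpec = HistogramSpec()) -> float:
    """ln of the merge-height histogram entropy (floored at 1e-12)."""
    h = histogram_entropy(zero_dim_merge_heights(dm), spec)
    return float(np.log(max(h, _HOMOLOGY_ENTROPY_FLOOR)))


# ---------------------------------------------------------------------------
# metric 3 — vector magnitude


def walk_vector_sum(centers: np.ndarray, start_index: int, stop_percentile: float = 20.0) -> np.ndarray:
    """Sum of step vectors of a greedy nearest-unvisited-center walk.

    From the current center, step to the nearest unvisited center; stop when
    that distance exceeds the ``stop_percentile``-th percentile of all
    pairwise center distances, or when all centers are visited. The returned
    sum telescopes to (final position - start position).
    """
    centers = np.asarray(centers, dtype=float)
    m = centers.shape[0]
    if m < 2:
        raise DegenerateInputError(f"need at least 2 centers, got {m}")
    if not 0 <= start_index < m:
        raise DegenerateInputError(f"start_index {start_index} out of range [0, {m})")
    D = squareform(pdist(centers))
    threshold = np.percentile(squareform(D, checks=False), stop_percentile)

    visited = np.zeros(m, dtype=bool)
    current = start_index
    visited[current] = True
    total = np.zeros(centers.shape[1])
    while not visited.all():
        dists = np.where(visited, np.inf, D[current])
        nxt = int(np.argmin(dists))  # ties -> lowest index
        if dists[nxt] > threshold:
            break
        total += centers[nxt] - centers[current]
        visited[nxt] = True
        current = nxt
    return total


def score_vector_magnitude(
    pc: PointCloud,
    cfg: VectorWalkConfig = VectorWalkConfig(),
    seed: int = 0,
) -> float:
    """Mean p-norm of the summed center-walk vector over K-means repeats.

    Clouds with d > ``pca_dim`` are first PCA-reduced; every dimension is
    then min-max scaled to [0, 1] (constant dimensions map to 0). Each of the
    ``n_repeats`` repeats runs K-means with its own derived sub-seed, starts
    the walk at a uniformly drawn center and takes the p-norm of the summed
    step vectors; the mean over repeats is returned.
    """
    X = pc.coords
    n = X.shape[0]
    K = max(2, int(round(cfg.kmeans_fraction * n)))
    if n < K:
        raise DegenerateInputError(f"need n >= K = {K}, got {n}")
    if X.shape[1] > cfg.pca_dim:
        X = PCA(n_components=cfg.pca_dim, svd_solver="full").fit_transform(X)
    rng_range = X.max(axis=0) - X.min(axis=0)
    scale = np.where(rng_range > 0, rng_range, 1.0)
    X = np.where(rng_range > 0, (X - X.min(axis=0)) / scale, 0.0)

    p = cfg.norm_p if cfg.norm_p is not None else X.shape[1]
    mags = []
    for r in range(cfg.n_repeats):
        sub = _subseed(seed, 3, r)
        rng = np.random.default_rng(sub)
        # single-threaded fit: parallel reductions can jitter the last bits
        # of the centers, breaking byte-identical reruns
        with threadpool_limits(limits=1):
            km = KMeans(n_clusters=K, n_init=1, random_state=sub).fit(X)
        start = int(rng.integers(K))
        vec = walk_vector_sum(km.cluster_centers_, start, cfg.stop_percentile)
        mags.append(float(np.sum(np.abs(vec) ** p) ** (1.0 / p)))
    return float(np.mean(mags))


# ---------------------------------------------------------------------------
# metric 4 — Ripley's K


def ripley_curve(dm: DistanceMatrix, thresholds) -> np.ndarray:
    """Normalized Ripley K curve over the given ascending thresholds.

    raw(t) = #{ordered pairs i != j : d_ij < t} / n; the curve is then
    divided by its maximum so it ends at 1 (the density constant of the
    classical definition cancels under this normalization).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) < 0):
        raise DegenerateInputError("thresholds must be ascending")
    cond = np.sort(squareform(dm.values, checks=False))
    raw = 2.0 * np.searchsorted(cond, thresholds, side="left") / dm.n
    m = raw.max()
    if m == 0:
        raise DegenerateCurveError("no pair falls below any threshold")
    return raw / m


def score_ripley(
    pc: PointCloud,
    cfg: RipleyConfig = RipleyConfig(),
    seed: int = 0,
    diffusion: DiffusionConfig = DiffusionConfig(),
    dm: Optional[DistanceMatrix] = None,
) -> float:
    """Area between the geodesic Ripley curves of *pc* and a uniform reference.

    A uniform sample of the same size is drawn (seeded) inside the
    axis-aligned bounding box of the cloud; DPT distance matrices are
    computed for both; each gets ``n_thresholds`` equally spaced thresholds
    from 0 to its own maximum; the two normalized curves are differenced
    index-by-index and the absolute difference integrated over the
    normalized threshold axis [0, 1].

    *dm* may supply a precomputed (finite) DPT matrix for *pc*.
    """
    if pc.n < 3:
        raise DegenerateInputError(f"need at least 3 points, got {pc.n}")
    rng = np.random.default_rng(_subseed(seed, 4))
    lo, hi = pc.coords.min(axis=0), pc.coords.max(axis=0)
    ref = PointCloud(coords=rng.uniform(lo, hi, size=pc.coords.shape))

    if dm is None:
        dm = finite_fill(dpt_distance_matrix(pc, diffusion), diffusion.infinity_fill_factor)
    dm_ref = finite_fill(dpt_distance_matrix(ref, diffusion), diffusion.infinity_fill_factor)

    curves = []
    for matrix in (dm, dm_ref):
        ts = np.linspace(0.0, matrix.values.max(), cfg.n_thresholds)
        curves.append(ripley_curve(matrix, ts))
    diff = np.abs(curves[0] - curves[1])
    x = np.linspace(0.0, 1.0, cfg.n_thresholds)
    return float(np.trapezoid(diff, x))


# ---------------------------------------------------------------------------
# metric 5 — degrees of connectivity


def _neighbor_ranks(X: np.ndarray) -> np.ndarray:
    """rank[i, j] = position of j in i's distance order (self = 0, ties by index)."""
    D = squareform(pdist(X))
    np.fill_diagonal(D, -1.0)
    order = np.argsort(D, axis=1, kind="stable")
    n = X.shape[0]
    rank = np.empty((n, n), dtype=np.int64)
    rows = np.arange(n)[:, None]
    rank[rows, order] = np.arange(n)[None, :]
    return rank


def _median_reachability(rank: np.ndarray, k: int) -> float:
    n = rank.shape[0]
    mutual = (rank <= k) & (rank.T <= k)
    np.fill_diagonal(mutual, False)
    _, labels = connected_components(sp.csr_matrix(mutual), directed=False)
    sizes = np.bincount(labels)
    reach = (sizes[labels] - 1) / (n - 1)
    return float(np.median(reach))


def mutual_knn_reachability(pc: PointCloud, k: int) -> float:
    """Median reachability in the mutual k-nearest-neighbor graph.

    Edge (i, j) exists iff i is among j's k nearest Euclidean neighbors AND
    vice versa (ties by index). A point's reachability is the fraction of
    *other* points in its connected component; the median over all points is
    returned.
    """
    n = pc.n
    if not 1 <= k <= n - 1:
        raise DegenerateInputError(f"k must be in [1, {n - 1}], got {k}")
    return _median_reachability(_neighbor_ranks(pc.coords), k)


def score_connectivity(pc: PointCloud, cfg: ConnectivityConfig = ConnectivityConfig()) -> float:
    """Normalized AUC of median reachability over the neighbor-fraction grid."""
    if pc.n < 3:
        raise DegenerateInputError(f"need at least 3 points, got {pc.n}")
    n = pc.n
    rank = _neighbor_ranks(pc.coords)
    fracs = np.asarray(cfg.fraction_grid, dtype=float)
    ys = [_median_reachability(rank, min(max(1, int(round(f * n))), n - 1)) for f in fracs]
    return float(np.trapezoid(ys, fracs) / (fracs[-1] - fracs[0]))


# ---------------------------------------------------------------------------
# all five together


def score_all(pc: PointCloud, configs: ScoreConfigs = None, seed: int = 0) -> ScoreVector:
    """Compute all five scores of a point cloud, sharing one DPT matrix.

    The diffusion neighborhood is clamped to n - 1 for small clouds so that
    subsets down to n = 10 remain scoreable. Deterministic given *seed*.
    """
    if configs is None:
        configs = ScoreConfigs()
    if pc.n < 3:
        raise DegenerateInputError(f"need at least 3 points, got {pc.n}")
    diff_cfg = configs.diffusion
    if pc.n < diff_cfg.n_graph_neighbors + 1:
        diff_cfg = replace(diff_cfg, n_graph_neighbors=max(2, pc.n - 1))

    def run(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - reported with the metric name
            raise MetricError(name, exc) from exc

    dm = run(
        "dpt",
        lambda: finite_fill(dpt_distance_matrix(pc, diff_cfg), diff_cfg.infinity_fill_factor),
    )
    return ScoreVector(
        pdist_entropy=run("pdist_entropy", lambda: score_pdist(dm, configs.histogram)),
        homology=run("homology", lambda: score_homology(dm, configs.histogram)),
        vector_magnitude=run(
            "vector_magnitude",
            lambda: score_vector_magnitude(pc, configs.vector_walk, seed),
        ),
        ripley=run(
            "ripley",
            lambda: score_ripley(pc, configs.ripley, seed, diffusion=diff_cfg, dm=dm),
        ),
        connectivity=run("connectivity", lambda: score_connectivity(pc, configs.connectivity)),
    )
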
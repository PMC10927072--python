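import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from scgeom.exceptions import DegenerateCurveError, DegenerateInputError
from scgeom.geodesic import DiffusionConfig, DistanceMatrix
from scgeom.metrics import (
    ConnectivityConfig,
    HistogramSpec,
    RipleyConfig,
    ScoreConfigs,
    VectorWalkConfig,
    histogram_entropy,
    mutual_knn_reachability,
    ripley_curve,
    score_all,
    score_connectivity,
    score_homology,
    score_pdist,
    score_ripley,
    score_vector_magnitude,
    walk_vector_sum,
    zero_dim_merge_heights,
)
from scgeom.preprocess import PointCloud

from conftest import blob_cloud, clusters_cloud, segment_cloud


def euclidean_dm(X):
    return DistanceMatrix(values=squareform(pdist(np.asarray(X, dtype=float))))


# ---------------------------------------------------------------------------
# oracles (kept independent of the implementation paths they check)


def kruskal_mst_weights(D):
    """Edge weights of the MST by Kruskal with an explicit union-find."""
    n = D.shape[0]
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges = sorted((D[i, j], i, j) for i in range(n) for j in range(i + 1, n))
    weights = []
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            weights.append(w)
    return np.array(sorted(weights))


def union_find_components(n, edges):
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    roots = [find(i) for i in range(n)]
    return {r: [i for i in range(n) if roots[i] == r] for r in set(roots)}


# ---------------------------------------------------------------------------
# metric 1


class TestHistogramEntropy:
    def test_one_value_per_bin_gives_ln_nbins(self):
        values = np.arange(10) + 0.5
        assert histogram_entropy(values) == pytest.approx(np.log(10), abs=1e-12)

    def test_identical_values_give_zero(self):
        assert histogram_entropy([3.3] * 7) == 0.0

    def test_two_bins_occupied(self):
        # {0, 0, 1}: p = (2/3, 1/3) -> H = ln 3 - (2/3) ln 2
        got = histogram_entropy([0.0, 0.0, 1.0], HistogramSpec(n_bins=10))
        assert got == pytest.approx(np.log(3) - (2 / 3) * np.log(2), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            histogram_entropy([])


class TestScorePdist:
    def test_equal_distances_score_zero(self):
        v = np.ones((5, 5)) - np.eye(5)
        assert score_pdist(DistanceMatrix(v)) == 0.0

    def test_matches_direct_recomputation(self, rng):
        dm = euclidean_dm(rng.normal(size=(20, 3)))
        upper = dm.values[np.triu_indices(20, k=1)]
        counts, _ = np.histogram(upper, bins=10, range=(upper.min(), upper.max()))
        p = counts / counts.sum()
        want = -(p[p > 0] * np.log(p[p > 0])).sum()
        assert score_pdist(dm) == pytest.approx(want, abs=1e-12)

    def test_bimodal_below_unimodal(self, rng):
        two_blobs = euclidean_dm(clusters_cloud(rng, [(0, 0), (20, 0)], n_per=30, sigma=0.3).coords)
        one_blob = euclidean_dm(blob_cloud(rng, n=60).coords)
        assert score_pdist(two_blobs) < score_pdist(one_blob)


# ---------------------------------------------------------------------------
# metric 2


class TestMergeHeights:
    def test_three_points_on_a_line(self):
        dm = euclidean_dm(np.array([[0.0], [1.0], [3.0]]))
        assert np.allclose(zero_dim_merge_heights(dm), [1.0, 2.0])

    def test_equilateral_merges_at_common_distance(self):
        v = 2.0 * (np.ones((4, 4)) - np.eye(4))
        assert np.allclose(zero_dim_merge_heights(DistanceMatrix(v)), [2.0] * 3)

    def test_kruskal_oracle_on_random_clouds(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 51))
            dm = euclidean_dm(rng.normal(size=(n, int(rng.integers(2, 5)))))
            got = zero_dim_merge_heights(dm)
            want = kruskal_mst_weights(dm.values)
            assert len(got) == n - 1
            assert np.max(np.abs(np.sort(got) - want)) < 1e-9


class TestScoreHomology:
    def test_uniform_merge_heights(self):
        # chain with gaps 1..10: one MST edge per histogram bin -> H = ln 10
        gaps = np.arange(1.0, 11.0)
        pos = np.concatenate([[0.0], np.cumsum(gaps)])
        dm = euclidean_dm(pos[:, None])
        assert score_homology(dm) == pytest.approx(np.log(np.log(10)), abs=1e-12)

    def test_identical_heights_hit_floor(self):
        v = 3.0 * (np.ones((6, 6)) - np.eye(6))
        assert score_homology(DistanceMatrix(v)) == pytest.approx(np.log(1e-12))

    def test_clusters_below_trajectory(self, rng):
        clus = euclidean_dm(
            clusters_cloud(rng, [(0, 0), (15, 0), (0, 15)], n_per=20, sigma=0.2).coords
        )
        traj = euclidean_dm(segment_cloud(rng, n=60, noise=0.02).coords)
        assert score_homology(clus) < score_homology(traj)


# ---------------------------------------------------------------------------
# metric 3


class TestWalkVectorSum:
    def test_collinear_walk_telescopes_to_far_end(self):
        centers = np.array([[0.0, 0.0], [0.5, 0.0], [1.0, 0.0]])
        vec = walk_vector_sum(centers, start_index=0, stop_percentile=99.0)
        assert np.allclose(vec, [1.0, 0.0])

    def test_immediate_stop_gives_zero_vector(self):
        # centers 0/1 close together, 2 far: starting at 2, the first step
        # already exceeds a low percentile threshold
        centers = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 0.0]])
        vec = walk_vector_sum(centers, start_index=2, stop_percentile=20.0)
        assert np.allclose(vec, [0.0, 0.0])

    def test_telescoping_identity(self, rng):
        """The summed steps always equal final minus start position."""
        for _ in range(20):
            centers = rng.normal(size=(int(rng.integers(3, 12)), 3))
            start = int(rng.integers(len(centers)))
            # replay the greedy walk independently to find the final center
            D = squareform(pdist(centers))
            thr = np.percentile(pdist(centers), 50.0)
            visited = {start}
            cur = start
            while len(visited) < len(centers):
                cand = min(
                    (j for j in range(len(centers)) if j not in visited),
                    key=lambda j: (D[cur, j], j),
                )
                if D[cur, cand] > thr:
                    break
                visited.add(cand)
                cur = cand
            vec = walk_vector_sum(centers, start, stop_percentile=50.0)
            assert np.allclose(vec, centers[cur] - centers[start], atol=1e-12)


class TestScoreVectorMagnitude:
    def test_collinear_centers_hand_traced(self):
        # spacing 0.25 after min-max scaling; full walk end-to-end -> norm 1
        centers = np.array([[i * 0.25, 0.0] for i in range(5)])
        vec = walk_vector_sum(centers, start_index=0, stop_percentile=99.0)
        assert np.sum(np.abs(vec) ** 2) ** 0.5 == pytest.approx(1.0)

    def test_deterministic_given_seed(self, rng):
        pc = blob_cloud(rng, n=80)
        cfg = VectorWalkConfig(n_repeats=1)
        a = score_vector_magnitude(pc, cfg, seed=5)
        b = score_vector_magnitude(pc, cfg, seed=5)
        assert a == b

    def test_segment_scores_far_above_blob(self, rng):
        seg = segment_cloud(rng, n=300, noise=0.005)
        tight_clusters = clusters_cloud(
            rng, [(0, 0), (10, 0), (0, 10), (10, 10)], n_per=75, sigma=0.15
        )
        s_seg = score_vector_magnitude(seg, seed=2)
        s_clus = score_vector_magnitude(tight_clusters, seed=2)
        assert s_seg > 2 * s_clus
        assert s_seg > 0.35  # random start: expected |end - start| ~ 0.5


# ---------------------------------------------------------------------------
# metric 4


class TestRipleyCurve:
    def test_hand_counted_three_points(self):
        v = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        got = ripley_curve(DistanceMatrix(v), [1.5, 2.5, 3.5])
        assert np.allclose(got, [1 / 3, 2 / 3, 1.0])

    def test_non_decreasing_and_ends_at_one(self, rng):
        for _ in range(10):
            dm = euclidean_dm(rng.normal(size=(25, 2)))
            ts = np.linspace(0, dm.values.max(), 50)
            curve = ripley_curve(dm, ts)
            assert np.all(np.diff(curve) >= 0)
            assert curve[-1] == pytest.approx(1.0)

    def test_all_zero_curve_rejected(self):
        dm = euclidean_dm(np.array([[0.0], [5.0], [9.0]]))
        with pytest.raises(DegenerateCurveError):
            ripley_curve(dm, [0.5, 1.0])


class TestScoreRipley:
    def test_identical_curves_give_zero_area(self, rng):
        dm = euclidean_dm(rng.normal(size=(30, 2)))
        ts = np.linspace(0, dm.values.max(), 100)
        curve = ripley_curve(dm, ts)
        diff = np.abs(curve - curve)
        assert np.trapezoid(diff, np.linspace(0, 1, 100)) == 0.0

    def test_bounded_in_unit_interval(self, rng, small_diffusion):
        for _ in range(5):
            pc = blob_cloud(rng, n=40)
            s = score_ripley(pc, seed=3, diffusion=small_diffusion)
            assert 0.0 <= s <= 1.0

    def test_clusters_score_above_trajectory(self, rng, small_diffusion):
        clus = clusters_cloud(rng, [(0, 0), (8, 0), (0, 8), (8, 8)], n_per=40, sigma=0.2)
        t = rng.uniform(0, 1, 160)
        sine = PointCloud(np.column_stack([10 * t, 2 * np.sin(2 * np.pi * 1.5 * t)])
                          + 0.05 * rng.normal(size=(160, 2)))
        s_clus = score_ripley(clus, seed=4, diffusion=small_diffusion)
        s_traj = score_ripley(sine, seed=4, diffusion=small_diffusion)
        assert s_clus > s_traj


# ---------------------------------------------------------------------------
# metric 5


class TestMutualKnnReachability:
    def test_complete_graph_at_max_k(self, rng):
        pc = blob_cloud(rng, n=12)
        assert mutual_knn_reachability(pc, k=11) == 1.0

    def test_hand_traced_line_of_four(self):
        # points 0,1,2,3 on a line, k=1: 1's nearest is 0 (index tie-break),
        # mutual edges {0,1} only -> reachabilities (1/3, 1/3, 0, 0)
        pc = PointCloud(np.array([[0.0], [1.0], [2.0], [3.0]]))
        assert mutual_knn_reachability(pc, k=1) == pytest.approx(1 / 6)

    def test_union_find_oracle_components(self, rng):
        X = rng.normal(size=(30, 2))
        pc = PointCloud(X)
        k = 4
        D = squareform(pdist(X))
        np.fill_diagonal(D, np.inf)
        knn = [set(sorted(range(30), key=lambda j: (D[i, j], j))[:k]) for i in range(30)]
        edges = [(i, j) for i in range(30) for j in range(i + 1, 30)
                 if j in knn[i] and i in knn[j]]
        comps = union_find_components(30, edges)
        sizes = {i: len(c) for c in comps.values() for i in c}
        want = float(np.median([(sizes[i] - 1) / 29 for i in range(30)]))
        assert mutual_knn_reachability(pc, k) == pytest.approx(want, abs=1e-12)

    def test_non_decreasing_in_k(self, rng):
        for _ in range(10):
            pc = blob_cloud(rng, n=25, d=int(rng.integers(2, 5)))
            vals = [mutual_knn_reachability(pc, k) for k in range(1, 25)]
            assert np.all(np.diff(vals) >= 0)


class TestScoreConnectivity:
    def test_fully_connected_cloud_scores_one(self):
        # equally spaced ring: the mutual graph is a connected cycle at every
        # grid k (min k = 2 for n = 40), so the curve is constantly 1
        ang = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        pc = PointCloud(np.column_stack([np.cos(ang), np.sin(ang)]))
        assert score_connectivity(pc) == pytest.approx(1.0)

    def test_equally_spaced_line(self):
        pc = PointCloud(np.arange(100, dtype=float)[:, None])
        # chain mutual graph connects at every k >= 2 (grid min k = 5)
        assert score_connectivity(pc) >= 0.94

    def test_separated_clusters_cap_reachability(self, rng):
        # 3 clusters of 50: below the cluster size, reachability is pinned
        # near (50 - 1)/(n - 1); the late rise depresses the AUC
        pc = clusters_cloud(rng, [(0, 0), (10, 0), (0, 10)], n_per=50, sigma=0.1)
        assert mutual_knn_reachability(pc, k=8) == pytest.approx(49 / 149, abs=0.02)
        blob = blob_cloud(rng, n=150)
        assert score_connectivity(pc) < 0.85 < score_connectivity(blob)


# ---------------------------------------------------------------------------
# all five


class TestScoreAll:
    def test_deterministic(self, rng, small_configs):
        pc = blob_cloud(rng, n=50)
        a = score_all(pc, small_configs, seed=9)
        b = score_all(pc, small_configs, seed=9)
        assert a == b

    def test_range_invariants_over_seeds(self, small_configs):
        from scgeom.simulate import SimConfig, sim_batch

        sims = sim_batch(3, master_seed=5, cfg=SimConfig(n_points_range=(60, 120)))
        for ds in sims:
            sv = score_all(ds.points, small_configs, seed=ds.seed)
            assert 0.0 <= sv.pdist_entropy <= np.log(10) + 1e-12
            assert np.isfinite(sv.homology)
            assert sv.vector_magnitude >= 0
            assert 0.0 <= sv.ripley <= 1.0
            assert 0.0 <= sv.connectivity <= 1.0

    def test_clear_cluster_vs_trajectory_directions(self):
        """Median over a few seeds carries the expected sign for all five."""
        from scgeom.simulate import SimConfig, sim_clusters, sim_trajectory

        cfg = SimConfig(n_points_range=(200, 400))
        sc = np.median(
            [score_all(sim_clusters(cfg, noisy=False, seed=s).points, seed=1).as_array()
             for s in range(5)], axis=0)
        st = np.median(
            [score_all(sim_trajectory(cfg, noisy=False, seed=s).points, seed=1).as_array()
             for s in range(5)], axis=0)
        # pdist_entropy, homology, vector_magnitude, connectivity: traj higher
        assert np.all(st[[0, 1, 2, 4]] > sc[[0, 1, 2, 4]])
        assert sc[3] > st[3]  # ripley: clusters higher

    def test_small_cloud_rejected(self, small_configs):
        with pytest.raises(DegenerateInputError):
            score_all(PointCloud(np.zeros((2, 2))), small_configs)
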
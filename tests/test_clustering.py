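import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleokit.clustering import (cluster_metrics, dbscan, extract_clusters,
                                  filter_clusters, size_scaling_exponent)
from nucleokit.errors import FitError, ParameterError
from nucleokit.synthetic import GeneratorConfig, generate_localization_map, sample_cluster_sizes


def brute_force_dbscan(points, eps, min_pts):
    """O(N^2) reference implementation (neighborhood includes the point)."""
    n = len(points)
    if n == 0:
        return np.empty(0, dtype=int)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        labels[i] = cluster
        stack = [i]
        while stack:
            j = stack.pop()
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    if core[k]:
                        stack.append(k)
        cluster += 1
    return labels


def same_partition(l1, l2):
    """Equality of clusterings up to label permutation (noise must match)."""
    if len(l1) != len(l2):
        return False
    if not np.array_equal(l1 == -1, l2 == -1):
        return False
    mapping = {}
    for a, b in zip(l1, l2):
        if a == -1:
            continue
        if mapping.setdefault(a, b) != b:
            return False
    return len(set(mapping.values())) == len(mapping)


class TestDbscan:
    def test_disc_plus_noise(self, rng):
        # 12 points inside a 30 nm disc, 3 points far away
        th = rng.uniform(0, 2 * np.pi, 12)
        r = 15 * np.sqrt(rng.random(12))
        disc = np.column_stack([r * np.cos(th), r * np.sin(th)])
        far = np.array([[500.0, 0.0], [0.0, 800.0], [-600.0, -600.0]])
        pts = np.vstack([disc, far])
        labels = dbscan(pts, eps=40.0, min_pts=10)
        assert (labels[:12] == labels[0]).all() and labels[0] >= 0
        assert (labels[12:] == -1).all()

    def test_min_pts_one_is_connected_components(self, rng):
        pts = rng.uniform(0, 300, size=(60, 2))
        labels = dbscan(pts, eps=25.0, min_pts=1)
        assert (labels >= 0).all()  # every point is core
        assert same_partition(labels, brute_force_dbscan(pts, 25.0, 1))

    def test_nine_points_below_min_pts_all_noise(self, rng):
        th = rng.uniform(0, 2 * np.pi, 9)
        r = 15 * np.sqrt(rng.random(9))
        pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
        assert (dbscan(pts, eps=40.0, min_pts=10) == -1).all()

    def test_empty_input(self):
        assert len(dbscan(np.empty((0, 2)))) == 0

    def test_nonfinite_raises(self):
        with pytest.raises(ParameterError):
            dbscan(np.array([[0.0, np.nan]]))

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000),
           n_points=st.integers(0, 300),
           eps=st.floats(5.0, 80.0),
           min_pts=st.integers(1, 12))
    def test_matches_brute_force_oracle(self, seed, n_points, eps, min_pts):
        rng = np.random.default_rng(seed)
        # mixture of a few dense blobs and uniform background
        blobs = [rng.normal(rng.uniform(0, 500, 2), rng.uniform(5, 30),
                            size=(rng.integers(5, 40), 2))
                 for _ in range(rng.integers(0, 4))]
        background = rng.uniform(0, 500, size=(rng.integers(0, 60), 2))
        pts = np.vstack(blobs + [background]) if blobs else background
        pts = pts[:n_points]
        assert same_partition(dbscan(pts, eps, min_pts),
                              brute_force_dbscan(pts, eps, min_pts))


class TestClusterMetrics:
    def test_equilateral_triangle(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, np.sqrt(3.0)]])
        rec = cluster_metrics(pts)
        assert rec.diameter_nm == pytest.approx(2.0)
        assert rec.R_nm == pytest.approx(1.0)
        assert rec.n == pytest.approx(1.0)
        assert not rec.degenerate

    def test_circle_radius_50(self, rng):
        th = np.linspace(0, 2 * np.pi, 101)[:-1]
        pts = 50.0 * np.column_stack([np.cos(th), np.sin(th)])
        rec = cluster_metrics(pts)
        d_brute = max(np.hypot(*(p - q)) for p in pts for q in pts)
        assert rec.diameter_nm == pytest.approx(d_brute)
        assert rec.R_nm == pytest.approx(50.0, rel=1e-3)
        assert rec.n == pytest.approx(1.25e5, rel=3e-3)

    def test_cube_of_162(self):
        pts = np.array([[0.0, 0.0], [324.0, 0.0], [162.0, 1.0]])
        rec = cluster_metrics(pts)
        assert rec.R_nm == pytest.approx(162.0)
        assert rec.n == pytest.approx(4_251_528.0)

    def test_collinear_degenerate(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        rec = cluster_metrics(pts)
        assert rec.degenerate
        assert rec.diameter_nm == pytest.approx(np.sqrt(8.0))

    def test_two_points_degenerate(self):
        rec = cluster_metrics(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert rec.degenerate and rec.diameter_nm == pytest.approx(5.0)

    def test_mean_radius_method_unbiased_on_disc(self, rng):
        r = 60.0 * np.sqrt(rng.random(4000))
        th = rng.uniform(0, 2 * np.pi, 4000)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
        rec = cluster_metrics(pts, radius_method="mean")
        assert rec.R_nm == pytest.approx(60.0, rel=0.02)


class TestFilterClusters:
    def _rec(self, diameter):
        pts = np.array([[0.0, 0.0], [diameter, 0.0], [diameter / 2, 0.1]])
        return cluster_metrics(pts)

    def test_boundary_kept(self):
        recs = [self._rec(d) for d in (40.0, 50.0, 60.0)]
        kept = filter_clusters(recs, min_diameter=50.0)
        assert [round(r.diameter_nm) for r in kept] == [50, 60]

    def test_empty(self):
        assert filter_clusters([]) == []

    def test_retained_ground_truth_sizes(self, fixed_params):
        a, b = fixed_params
        cfg = GeneratorConfig(a=a, b=b, seed=17, n_clusters=150,
                              n_background_molecules=0)
        sizes = sample_cluster_sizes(cfg)
        m, _ = generate_localization_map(sizes, cfg)
        labels = dbscan(m.points)
        kept = filter_clusters(extract_clusters(m.points, labels))
        # diameter >= 50 nm implies R >= 25, n >= 1.5625e4
        for r in kept:
            assert r.R_nm >= 25.0
            assert r.n >= 1.5625e4

    def test_idempotent(self):
        recs = [self._rec(d) for d in (45.0, 55.0, 80.0)]
        once = filter_clusters(recs)
        assert filter_clusters(once) == once


class TestSizeScalingExponent:
    def _records_power(self, power, k=40):
        rng = np.random.default_rng(0)
        recs = []
        for radius in np.geomspace(25, 150, k):
            count = max(3, int(round(radius ** power / 25 ** power * 12)))
            th = rng.uniform(0, 2 * np.pi, count)
            r = radius * np.sqrt(rng.random(count))
            pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
            rec = cluster_metrics(pts)
            recs.append(rec)
        return recs

    def test_exact_cube_law(self):
        # construct records with counts exactly proportional to R^3
        from nucleokit.clustering import ClusterRecord
        recs = [ClusterRecord(cluster_id=i, member_indices=np.arange(1),
                              centroid_nm=(0, 0), diameter_nm=2 * R, R_nm=R,
                              localization_count=int(R) ** 3, n=R ** 3)
                for i, R in enumerate([30, 40, 50, 60, 80, 100, 120, 140, 160, 180])]
        slope, sem = size_scaling_exponent(recs)
        assert slope == pytest.approx(3.0, abs=1e-6)

    def test_square_law_contrast(self):
        from nucleokit.clustering import ClusterRecord
        recs = [ClusterRecord(cluster_id=i, member_indices=np.arange(1),
                              centroid_nm=(0, 0), diameter_nm=2 * R, R_nm=R,
                              localization_count=int(R) ** 2, n=R ** 3)
                for i, R in enumerate([30, 40, 50, 60, 80, 100, 120, 140, 160, 180])]
        slope, _ = size_scaling_exponent(recs)
        assert slope == pytest.approx(2.0, abs=1e-5)

    def test_generator_defaults_cube_law(self, fixed_params):
        a, b = fixed_params
        rng = np.random.default_rng(2)
        sizes = rng.uniform(50.0, 150.0, 100) ** 3
        # loc_sigma=0: a 20 nm localization error inflates the measured R
        # of the smallest clusters and steepens the apparent exponent
        cfg = GeneratorConfig(a=a, b=b, seed=2, n_background_molecules=0,
                              loc_sigma=0.0)
        m, _ = generate_localization_map(sizes, cfg)
        labels = dbscan(m.points)
        kept = filter_clusters(extract_clusters(m.points, labels))
        slope, _ = size_scaling_exponent(kept)
        assert slope == pytest.approx(3.0, abs=0.2)

    def test_too_few_records_raises(self):
        with pytest.raises(FitError):
            size_scaling_exponent([])


class TestParameterRobustness:
    def test_factor_two_in_eps_min_pts(self, fixed_params):
        # halving/doubling the DBSCAN parameters changes the retained
        # cluster count by < 20% on a default synthetic map
        a, b = fixed_params
        cfg = GeneratorConfig(a=a, b=b, seed=23, n_clusters=200,
                              n_background_molecules=100)
        sizes = sample_cluster_sizes(cfg)
        m, _ = generate_localization_map(sizes, cfg)
        counts = {}
        for eps, mp in [(40.0, 10), (20.0, 5), (80.0, 20)]:
            labels = dbscan(m.points, eps=eps, min_pts=mp)
            counts[(eps, mp)] = len(filter_clusters(extract_clusters(m.points, labels)))
        base = counts[(40.0, 10)]
        for key, val in counts.items():
            assert abs(val - base) / base < 0.2, (key, counts)
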
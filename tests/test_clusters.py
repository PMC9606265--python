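"""Cluster primitives: graph, Ward cut, C_c oracle, hulls, randomization."""

import numpy as np
import pytest
from shapely.geometry import Polygon
from sklearn.cluster import AgglomerativeClustering

from engram import clusters as cl
from engram import synthetic as sy
from engram.types import ParameterError


def brute_force_cc(points, labels):
    """Independent exhaustive-enumeration oracle for the clustering index."""
    points = np.asarray(points, float)
    labels = np.asarray(labels)
    ratios = []
    for i in range(len(points)):
        mates = [j for j in range(len(points)) if j != i and labels[j] == labels[i]]
        others = [j for j in range(len(points)) if labels[j] != labels[i]]
        if not mates or not others:
            continue
        m = np.median([np.hypot(*(points[i] - points[j])) for j in mates])
        e = min(np.hypot(*(points[i] - points[j])) for j in others)
        if e > 0:
            ratios.append(m / e)
    return float(np.mean(ratios))


class TestConnectivityGraph:
    def test_collinear_symmetrization(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        g = cl.connectivity_graph(pts, k=1).toarray()
        assert g[1, 0] and g[1, 2]  # middle point linked to both ends

    def test_default_k_rule(self):
        assert cl.default_k(40) == 4
        assert cl.default_k(5) == 1

    def test_duplicate_coordinates_ok(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        g = cl.connectivity_graph(pts, k=1)
        assert g.shape == (3, 3)

    def test_too_few_points(self):
        with pytest.raises(ParameterError):
            cl.connectivity_graph(np.array([[0.0, 0.0]]), k=1)


class TestWardClusters:
    def test_two_tight_groups_separate(self, rng):
        a = rng.normal((0, 0), 1.0, size=(10, 2))
        b = rng.normal((100, 100), 1.0, size=(10, 2))
        pts = np.vstack([a, b])
        g = cl.connectivity_graph(pts, k=3)
        labels = cl.ward_clusters(pts, g, 2)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    @pytest.mark.parametrize("n_c", [1, 2, 5, 12, 30])
    def test_cut_matches_sklearn_estimator(self, rng, n_c):
        """Our single-tree cut equals AgglomerativeClustering at each n_c."""
        pts = rng.uniform(0, 200, size=(30, 2))
        g = cl.connectivity_graph(pts, k=3)
        ours = cl.ward_clusters(pts, g, n_c)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = AgglomerativeClustering(
                n_clusters=n_c, linkage="ward", connectivity=g
            ).fit(pts)
        # same partition up to label permutation
        for lab in (ours, est.labels_):
            assert len(np.unique(lab)) == n_c
        pairs_ours = ours[:, None] == ours[None, :]
        pairs_sk = est.labels_[:, None] == est.labels_[None, :]
        assert np.array_equal(pairs_ours, pairs_sk)

    def test_singletons_at_full_cut(self, rng):
        pts = rng.uniform(0, 100, size=(8, 2))
        g = cl.connectivity_graph(pts, k=2)
        assert len(set(cl.ward_clusters(pts, g, 8))) == 8
        assert len(set(cl.ward_clusters(pts, g, 1))) == 1


class TestClusteringIndex:
    def test_two_far_squares(self):
        pts = np.array(
            [[0, 0], [0, 1], [1, 0], [1, 1],
             [100, 100], [100, 101], [101, 100], [101, 101]],
            dtype=float,
        )
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        res = cl.clustering_index(pts, labels)
        assert res.c_c == pytest.approx(brute_force_cc(pts, labels), abs=1e-12)
        assert res.c_c == pytest.approx(0.0072, abs=5e-4)

    def test_single_cluster_rejected(self):
        pts = np.random.default_rng(0).uniform(0, 10, (5, 2))
        with pytest.raises(ParameterError):
            cl.clustering_index(pts, np.zeros(5, dtype=int))

    def test_interleaved_lattice_exceeds_one(self):
        """Alternating labels on a lattice: intra-median >> nearest-other."""
        xs, ys = np.meshgrid(np.arange(6), np.arange(6))
        pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        labels = (xs.ravel() + ys.ravel()) % 2
        res = cl.clustering_index(pts, labels)
        assert res.c_c > 1.0
        assert res.c_c == pytest.approx(brute_force_cc(pts, labels), abs=1e-12)

    def test_oracle_equivalence_random_maps(self, rng):
        """Vectorized C_c equals brute force on random maps (<= 60 points)."""
        for _ in range(25):
            n = int(rng.integers(10, 61))
            pts = rng.uniform(0, 300, size=(n, 2))
            labels = rng.integers(0, max(2, n // 8), size=n)
            if len(np.unique(labels)) < 2:
                continue
            res = cl.clustering_index(pts, labels)
            assert res.c_c == pytest.approx(brute_force_cc(pts, labels), abs=1e-9)

    def test_tightening_a_cluster_lowers_cc(self, rng):
        """Shrinking one cluster toward its centroid never increases C_c."""
        a = rng.normal((0, 0), 10.0, size=(12, 2))
        b = rng.normal((200, 0), 10.0, size=(12, 2))
        labels = np.array([0] * 12 + [1] * 12)
        base = cl.clustering_index(np.vstack([a, b]), labels).c_c
        shrunk = a.mean(axis=0) + 0.3 * (a - a.mean(axis=0))
        tight = cl.clustering_index(np.vstack([shrunk, b]), labels).c_c
        assert tight <= base


class TestRandomization:
    def test_counts_and_containment(self, small_mask):
        spec = sy.GeneratorSpec(n_cells=400, f_tagged=0.1, f_cfos=0.1, rho=2.0, seed=1)
        cm = sy.sample_cellmap(small_mask, spec)
        arts = cl.randomize_cellmap(cm, n_sets=5, seed=0)
        t0, c0, d0 = cl._label_groups(cm)
        for art in arts:
            t, c, d = cl._label_groups(art)
            assert (len(t), len(c), len(d)) == (len(t0), len(c0), len(d0))
            pos = art.positions()
            assert small_mask.contains(pos[:, 0], pos[:, 1]).all()

    def test_seed_substreams_stable_under_n_sets(self, small_mask):
        spec = sy.GeneratorSpec(n_cells=200, f_tagged=0.1, f_cfos=0.1, seed=1)
        cm = sy.sample_cellmap(small_mask, spec)
        a = cl.randomize_cellmap(cm, n_sets=3, seed=42)
        b = cl.randomize_cellmap(cm, n_sets=5, seed=42)
        for x, y in zip(a, b[:3]):
            assert np.array_equal(x.positions(), y.positions())


class TestHullOverlap:
    def test_identity_gives_one(self, rng):
        pts = rng.uniform(0, 100, size=(30, 2))
        labels = rng.integers(0, 3, size=30)
        res = cl.hull_overlap_index(pts, labels, pts, labels)
        for ic in res.best_ic:
            assert ic == pytest.approx(1.0)

    def test_disjoint_gives_zero(self):
        sq = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        res = cl.hull_overlap_index(sq, np.zeros(4, int), sq + 50.0, np.zeros(4, int))
        assert res.best_ic == [0.0]

    def test_offset_unit_squares_closed_form(self):
        """Unit square vs itself shifted 0.5 in x: Jaccard = 0.5/1.5 = 1/3."""
        sq = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        shifted = sq + np.array([0.5, 0.0])
        res = cl.hull_overlap_index(sq, np.zeros(4, int), shifted, np.zeros(4, int))
        assert res.best_ic[0] == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_degenerate_flagged_not_fatal(self):
        line = np.array([[0, 0], [1, 1], [2, 2]], dtype=float)
        sq = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        res = cl.hull_overlap_index(line, np.zeros(3, int), sq, np.zeros(4, int))
        assert res.best_ic == [0.0]
        assert res.degenerate_tagged == [0]

    def test_rectangle_grid_against_shapely_oracle(self, rng):
        """Random axis-aligned rectangles vs closed-form polygon arithmetic."""
        for _ in range(20):
            x0, y0, w0, h0 = rng.uniform(0, 10, 4) + 0.5
            x1, y1, w1, h1 = rng.uniform(0, 10, 4) + 0.5
            r0 = np.array([[x0, y0], [x0 + w0, y0], [x0, y0 + h0], [x0 + w0, y0 + h0]])
            r1 = np.array([[x1, y1], [x1 + w1, y1], [x1, y1 + h1], [x1 + w1, y1 + h1]])
            res = cl.hull_overlap_index(r0, np.zeros(4, int), r1, np.zeros(4, int))
            ix = max(0.0, min(x0 + w0, x1 + w1) - max(x0, x1))
            iy = max(0.0, min(y0 + h0, y1 + h1) - max(y0, y1))
            inter = ix * iy
            union = w0 * h0 + w1 * h1 - inter
            assert res.best_ic[0] == pytest.approx(inter / union, abs=1e-12)


class TestOptimalNc:
    def test_tie_rule_largest(self, monkeypatch, small_mask):
        """All proportions equal: the largest candidate n_c is returned."""
        spec = sy.GeneratorSpec(n_cells=400, f_tagged=0.15, f_cfos=0.15, seed=1)
        cm = sy.sample_cellmap(small_mask, spec)
        monkeypatch.setattr(cl, "_cc_profile", lambda *a, **k: np.ones(16))
        nc, props = cl.optimal_cluster_number(cm, "tagged", cl.ClusterConfig(n_artificial_opt=3))
        assert nc == 20
        assert set(props.values()) == {0.0}

    def test_insufficient_cells_rejected(self, small_mask):
        spec = sy.GeneratorSpec(n_cells=100, f_tagged=0.1, f_cfos=0.1, seed=1)
        cm = sy.sample_cellmap(small_mask, spec)
        with pytest.raises(ParameterError):
            cl.optimal_cluster_number(cm, "tagged", cl.ClusterConfig())
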
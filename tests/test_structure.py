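"""Distances, clustering, reduced sets, neighbour networks and projection."""

import itertools

import numpy as np
import pytest

import tscompass as tc
from tscompass.structure import (
    DistanceMatrix,
    KMedoids,
    build_reduced_set,
    kmedoids,
    linkage_cluster,
    neighbour_network,
    op_distance_corr,
    op_distance_nmi,
    pca_project,
    residual_variance,
    ts_distance,
)


def norm_matrix(make, X, mask=None, **kw):
    return tc.robust_sigmoid_normalize(make(X, mask, **kw))


class TestTsDistance:
    def test_identical_rows_zero(self, matrix_factory):
        X = np.tile(np.random.default_rng(0).random(6), (2, 1))
        d = ts_distance(norm_matrix(matrix_factory, X))
        assert d.values[0, 1] == 0.0

    def test_opposite_corner_rows_closed_form(self, matrix_factory):
        # after normalization the two extreme rows sit at 0 and 1 in every
        # column: distance sqrt(P)
        p = 7
        X = np.vstack([np.zeros(p), np.ones(p),
                       np.random.default_rng(1).random((3, p))])
        d = ts_distance(norm_matrix(matrix_factory, X))
        assert d.values[0, 1] == pytest.approx(np.sqrt(p), abs=1e-9)

    def test_mask_rescaling_matches_hand_formula(self, matrix_factory):
        X = np.random.default_rng(2).random((2, 4))
        mask = np.zeros((2, 4), bool)
        mask[0, 0] = True  # shared columns: 1, 2, 3
        m = norm_matrix(matrix_factory, X, mask)
        d = ts_distance(m)
        a, b = m.normalized[0], m.normalized[1]
        ss = sum((a[c] - b[c]) ** 2 for c in (1, 2, 3))
        assert d.values[0, 1] == pytest.approx(np.sqrt(4 / 3 * ss), abs=1e-12)
        assert d.unreliable is not None and not d.unreliable[0, 1]

    def test_symmetry_and_diagonal(self, cls_matrix):
        d = ts_distance(cls_matrix)
        np.testing.assert_allclose(d.values, d.values.T, atol=1e-12)
        assert np.all(np.diagonal(d.values) == 0)
        assert np.nanmin(d.values) >= 0


class TestOpDistances:
    def test_identical_and_anticorrelated_columns(self, matrix_factory):
        c = np.random.default_rng(3).random(40)
        X = np.column_stack([c, c, 1 - c])
        d = op_distance_corr(norm_matrix(matrix_factory, X))
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d.values[0, 2] == pytest.approx(0.0, abs=1e-12)  # |r| = 1
        assert d.signed_r[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_independent_columns_near_one(self, matrix_factory):
        for seed in range(10):
            X = np.random.default_rng(seed).random((1000, 2))
            d = op_distance_corr(norm_matrix(matrix_factory, X))
            assert d.values[0, 1] >= 0.9

    def test_nmi_sees_nonlinear_dependence(self, matrix_factory):
        for seed in range(10):
            u = np.random.default_rng(seed).uniform(-1, 1, 2000)
            X = np.column_stack([u, u**2])
            m = norm_matrix(matrix_factory, X)
            assert (op_distance_nmi(m).values[0, 1]
                    < op_distance_corr(m).values[0, 1])

    def test_nmi_independent_columns(self, matrix_factory):
        for seed in range(5):
            X = np.random.default_rng(100 + seed).random((2000, 2))
            d = op_distance_nmi(norm_matrix(matrix_factory, X), bins=10)
            assert d.values[0, 1] >= 0.8

    def test_insufficient_shared_rows_undefined(self, matrix_factory):
        X = np.random.default_rng(4).random((6, 2))
        mask = np.zeros((6, 2), bool)
        mask[:4, 0] = True  # only 2 shared rows
        d = op_distance_corr(norm_matrix(matrix_factory, X, mask))
        assert np.isnan(d.values[0, 1])


class TestKMedoids:
    def test_k_equals_n_zero_cost(self):
        d = np.random.default_rng(5).random((6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        est = KMedoids(n_clusters=6, random_state=0).fit(d)
        assert est.inertia_ == 0.0
        assert sorted(est.medoid_indices_) == list(range(6))

    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(6)
        pts = np.vstack([rng.normal(0, 0.01, (10, 2)),
                         rng.normal(100, 0.01, (10, 2))])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        est = KMedoids(n_clusters=2, restarts=1, random_state=0).fit(d)
        assert len(set(est.labels_[:10])) == 1
        assert len(set(est.labels_[10:])) == 1
        assert est.labels_[0] != est.labels_[10]

    def test_pam_matches_exhaustive_search(self):
        rng = np.random.default_rng(7)
        for trial in range(30):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(1, 4))
            pts = rng.random((n, 2))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            est = KMedoids(n_clusters=k, restarts=5, random_state=trial).fit(d)
            brute = min(
                d[:, list(c)].min(axis=1).sum()
                for c in itertools.combinations(range(n), k)
            )
            assert est.inertia_ == pytest.approx(brute, abs=1e-12)

    def test_deterministic_given_seed(self):
        d = np.random.default_rng(8).random((12, 12))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        a = KMedoids(n_clusters=3, random_state=5).fit(d)
        b = KMedoids(n_clusters=3, random_state=5).fit(d)
        np.testing.assert_array_equal(a.medoid_indices_, b.medoid_indices_)

    def test_wrapper_returns_clustering_with_member_medoids(self):
        vals = np.abs(np.subtract.outer(np.arange(5.0), np.arange(5.0)))
        dm = DistanceMatrix(vals, [f"i{i}" for i in range(5)], "euclidean")
        clust = kmedoids(dm, 2, seed=0)
        assert set(clust.assignment) == set(dm.ids)
        for mid in clust.medoids:
            assert clust.assignment[mid] == clust.medoids.index(mid)


class TestLinkage:
    def _toy(self):
        # 6 points on a line at 0, 1, 2, 10, 11, 12
        x = np.array([0.0, 1, 2, 10, 11, 12])
        vals = np.abs(np.subtract.outer(x, x))
        return DistanceMatrix(vals, list("abcdef"), "euclidean")

    def test_threshold_below_min_gives_singletons(self):
        d = self._toy()
        clust = linkage_cluster(d, threshold=0.5)
        assert clust.k == 6

    def test_threshold_above_max_gives_one_cluster(self):
        d = self._toy()
        clust = linkage_cluster(d, threshold=100.0)
        assert clust.k == 1

    def test_complete_linkage_heights_hand_computed(self):
        from scipy.cluster.hierarchy import linkage as scipy_linkage

        d = self._toy()
        z = scipy_linkage(d.condensed(), method="complete")
        # hand agglomeration: (a,b)@1, (d,e)@1, (ab,c)@2, (de,f)@2, rest@12
        np.testing.assert_allclose(sorted(z[:, 2]), [1, 1, 2, 2, 12])
        clust = linkage_cluster(d, k=2)
        left = {i for i, c in clust.assignment.items() if c == clust.assignment["a"]}
        assert left == {"a", "b", "c"}

    def test_exactly_one_of_k_threshold(self):
        with pytest.raises(ValueError):
            linkage_cluster(self._toy())


class TestResidualVariance:
    def test_identical_and_affine_distances_zero(self):
        vals = np.abs(np.subtract.outer(np.arange(4.0), np.arange(4.0)))
        ids = list("abcd")
        full = DistanceMatrix(vals, ids, "m")
        assert residual_variance(full, full) == 0.0
        affine = DistanceMatrix(2 * vals, ids, "m")
        assert residual_variance(full, affine) == pytest.approx(0.0, abs=1e-12)

    def test_hand_built_correlation(self):
        iu = np.triu_indices(4, k=1)
        rng = np.random.default_rng(9)
        a = np.zeros((4, 4))
        b = np.zeros((4, 4))
        a[iu] = rng.random(6)
        b[iu] = rng.random(6)
        a, b = a + a.T, b + b.T
        full = DistanceMatrix(a, list("abcd"), "m")
        red = DistanceMatrix(b, list("abcd"), "m")
        r = np.corrcoef(a[iu], b[iu])[0, 1]
        assert residual_variance(full, red) == pytest.approx(1 - r * r)

    def test_constant_distances_inapplicable(self):
        ids = list("abc")
        ones = np.ones((3, 3)) - np.eye(3)
        full = DistanceMatrix(ones, ids, "m")
        out = residual_variance(full, full)
        assert tc.is_special(out)


class TestReducedSet:
    def test_duplicated_groups_fully_recovered(self, matrix_factory):
        rng = np.random.default_rng(10)
        base = rng.standard_normal((30, 4))
        X = np.hstack([np.tile(base[:, [g]], (1, 5)) for g in range(4)])
        m = norm_matrix(matrix_factory, X,
                        col_ids=[f"g{g}c{j}" for g in range(4) for j in range(5)])
        rs = build_reduced_set(m, 4, seed=0)
        assert rs.residual_variance < 1e-6
        assert {mid[:2] for mid in rs.member_ids} == {"g0", "g1", "g2", "g3"}

    def test_full_set_residual_variance_zero(self, matrix_factory):
        X = np.random.default_rng(11).random((20, 6))
        m = norm_matrix(matrix_factory, X)
        rs = build_reduced_set(m, 6, seed=0)
        assert rs.residual_variance == pytest.approx(0.0, abs=1e-12)

    def test_mean_residual_variance_nonincreasing_in_k(self, mixed_matrix):
        ks = (5, 10, 20, 40)
        means = []
        for k in ks:
            vals = [build_reduced_set(mixed_matrix, k, seed=s).residual_variance
                    for s in range(10)]
            means.append(np.mean(vals))
        for a, b in zip(means, means[1:]):
            assert b <= a + 0.02  # single-step noise allowance


class TestNeighbourNetwork:
    def _dm(self):
        rng = np.random.default_rng(12)
        pts = rng.random((10, 3))
        vals = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        return DistanceMatrix(vals, [f"n{i}" for i in range(10)], "euclidean")

    def test_k_zero_single_node(self):
        g = neighbour_network(self._dm(), "n0", 0, 1.0)
        assert list(g.nodes) == ["n0"]

    def test_duplicate_is_nearest_with_zero_edge(self):
        vals = np.array([[0.0, 0, 5], [0, 0, 5], [5, 5, 0.0]])
        d = DistanceMatrix(vals, ["t", "dup", "far"], "m")
        g = neighbour_network(d, "t", 1, 1.0)
        assert set(g.nodes) == {"t", "dup"}
        assert g.edges["t", "dup"]["distance"] == 0.0

    def test_nodes_and_edges_match_hand_enumeration(self):
        d = self._dm()
        thr = float(np.median(d.values))
        g = neighbour_network(d, "n3", 3, thr)
        ti = 3
        order = sorted((i for i in range(10) if i != ti),
                       key=lambda i: (d.values[ti, i], d.ids[i]))
        nodes = {"n3"} | {d.ids[i] for i in order[:3]}
        assert set(g.nodes) == nodes
        for a, b, w in g.edges(data="distance"):
            assert w < thr
        # every qualifying pair is present
        idx = [d.ids.index(n) for n in nodes]
        expected_edges = sum(
            1 for i, j in itertools.combinations(idx, 2)
            if d.values[i, j] < thr
        )
        assert g.number_of_edges() == expected_edges

    def test_unknown_target_rejected(self):
        with pytest.raises(KeyError):
            neighbour_network(self._dm(), "nope", 2, 1.0)


class TestPCA:
    def test_collinear_data_single_component(self, matrix_factory):
        t = np.linspace(0, 1, 30)
        X = np.column_stack([t, 2 * t, -t + 5])
        # identical ordering in every column: rank-normalized values are
        # exactly collinear
        m = norm_matrix(matrix_factory, X)
        proj = pca_project(m, 2)
        assert proj.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(proj.scores[:, 1], 0, atol=1e-9)

    def test_explained_variance_sorted_and_bounded(self, mixed_matrix):
        proj = pca_project(mixed_matrix, 2)
        evr = proj.explained_variance_ratio
        assert np.all(np.diff(evr) <= 0)
        assert evr.sum() <= 1 + 1e-9

    def test_sign_convention_fixed(self, matrix_factory):
        X = np.random.default_rng(13).random((20, 5))
        m = norm_matrix(matrix_factory, X)
        a, b = pca_project(m, 2), pca_project(m, 2)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-12)
        for c in range(2):
            top = np.argmax(np.abs(a.loadings[c]))
            assert a.loadings[c, top] > 0

    def test_two_class_benchmark_separates_on_pc(self, cls_matrix):
        proj = pca_project(cls_matrix, 2)
        labels = np.array(cls_matrix.row_labels)
        best = 1.0
        for c in range(2):
            mean, _ = tc.threshold_classifier_cv(proj.scores[:, c], labels,
                                                 seed=0)
            best = min(best, mean)
        assert best <= 0.10
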
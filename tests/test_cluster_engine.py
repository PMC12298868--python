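"""Distances, Lance-Williams agglomeration, tree cutting, neighbor joining."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist

from maizecore import (
    LINKAGE_METHODS,
    DistanceMatrix,
    agglomerate,
    cut_tree,
    euclidean_distance,
    mahalanobis_distance,
    neighbor_joining,
)

from conftest import random_additive_tree


def dm(matrix, ids=None):
    matrix = np.asarray(matrix, dtype=float)
    return DistanceMatrix(ids or [f"a{i}" for i in range(len(matrix))], matrix)


#: 3 points with pairwise d(0,1)=1, d(0,2)=2, d(1,2)=3
TRIANGLE = dm([[0, 1, 2], [1, 0, 3], [2, 3, 0]])


class TestDistances:
    def test_euclidean_pythagorean(self):
        d = euclidean_distance(np.array([[0.0, 0.0], [3.0, 4.0]]), ["a", "b"])
        assert d.matrix[0, 1] == pytest.approx(5.0)

    def test_euclidean_identical_rows_zero(self):
        d = euclidean_distance(np.ones((3, 4)), ["a", "b", "c"])
        assert np.all(d.matrix == 0.0)

    def test_euclidean_matches_double_loop(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 4))
        d = euclidean_distance(X, [f"a{i}" for i in range(10)])
        for i in range(10):
            for j in range(10):
                assert d.matrix[i, j] == pytest.approx(
                    np.sqrt(((X[i] - X[j]) ** 2).sum()), abs=1e-12
                )

    def test_mahalanobis_whitened_equals_euclidean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        # whiten so the sample covariance is exactly the identity
        X = X - X.mean(axis=0)
        L = np.linalg.cholesky(np.cov(X, rowvar=False, ddof=1))
        X = X @ np.linalg.inv(L).T
        ids = [f"a{i}" for i in range(40)]
        assert np.allclose(
            mahalanobis_distance(X, ids).matrix,
            euclidean_distance(X, ids).matrix,
            atol=1e-9,
        )

    def test_mahalanobis_scalar_case(self):
        x = np.array([[1.0], [4.0], [6.0]])
        v = np.var(x, ddof=1)
        d = mahalanobis_distance(x, ["a", "b", "c"])
        assert d.matrix[0, 1] == pytest.approx(abs(1 - 4) / np.sqrt(v), abs=1e-12)

    def test_mahalanobis_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        VI = np.linalg.inv(np.cov(X, rowvar=False, ddof=1))
        d = mahalanobis_distance(X, [f"a{i}" for i in range(20)])
        for i in range(20):
            for j in range(20):
                diff = X[i] - X[j]
                assert d.matrix[i, j] == pytest.approx(
                    np.sqrt(diff @ VI @ diff), abs=1e-9
                )

    def test_rejects_nan_and_duplicate_ids(self):
        with pytest.raises(ValueError, match="missing"):
            mahalanobis_distance(np.array([[1.0, np.nan], [0.0, 1.0]]), ["a", "b"])
        with pytest.raises(ValueError, match="duplicate"):
            dm(np.zeros((2, 2)), ids=["a", "a"])


class TestAgglomerate:
    def test_single_linkage_hand_trace(self):
        t = agglomerate(TRIANGLE, "single")
        assert t.heights == pytest.approx([1.0, 2.0])

    def test_complete_linkage_hand_trace(self):
        t = agglomerate(TRIANGLE, "complete")
        assert t.heights == pytest.approx([1.0, 3.0])

    @pytest.mark.parametrize(
        "mine,scipy_name",
        [
            ("single", "single"),
            ("complete", "complete"),
            ("group_average", "average"),
            ("weighted_average", "weighted"),
            ("centroid", "centroid"),
            ("median", "median"),
            ("ward", "ward"),
        ],
    )
    def test_matches_scipy(self, mine, scipy_name):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 5))
        t = agglomerate(euclidean_distance(X, [f"a{i}" for i in range(20)]), mine)
        Z = scipy_linkage(pdist(X), method=scipy_name)
        assert np.allclose(t.heights, Z[:, 2], atol=1e-9)
        assert np.array_equal(np.sort(t.merges[:, :2]), np.sort(Z[:, :2]))

    @pytest.mark.parametrize("method", LINKAGE_METHODS)
    def test_matches_naive_recompute_oracle(self, method):
        """Every linkage agrees with a naive from-scratch recompute oracle."""
        rng = np.random.default_rng(10)
        for _ in range(10):
            X = rng.normal(size=(15, 3))
            D = euclidean_distance(X, [f"a{i}" for i in range(15)])
            t = agglomerate(D, method)
            assert np.allclose(t.heights, _naive_heights(D.matrix, method), atol=1e-9)

    def test_heights_scale_linearly(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 3))
        D = euclidean_distance(X, [f"a{i}" for i in range(12)])
        D3 = DistanceMatrix(D.ids, 3.0 * D.matrix)
        for method in LINKAGE_METHODS:
            h1 = agglomerate(D, method).heights
            h3 = agglomerate(D3, method).heights
            assert np.allclose(h3, 3.0 * h1, atol=1e-9), method

    def test_single_linkage_monotone(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(25, 4))
        h = agglomerate(euclidean_distance(X, [f"a{i}" for i in range(25)]), "single").heights
        assert np.all(np.diff(h) >= -1e-12)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown linkage"):
            agglomerate(TRIANGLE, "upgma-ish")


def _naive_heights(D: np.ndarray, method: str, beta: float = -0.25) -> np.ndarray:
    """O(n^3) recompute-from-scratch merge heights.

    Clusters are kept as explicit member lists; at every step all
    inter-cluster distances are recomputed from the original matrix where a
    from-scratch definition exists (min / max / unweighted mean / centroid
    and Ward via the Gower squared-distance identities), and via a plain
    dict-based Lance-Williams recursion for the inherently recursive methods
    (median, weighted average, flexible).
    """
    n = len(D)
    squared = method in ("median", "centroid", "ward")
    base = D**2 if squared else D.copy()
    clusters = {i: [i] for i in range(n)}
    # recursive store for WPGMA/median/flexible
    rec = {(i, j): base[i, j] for i in range(n) for j in range(n) if i != j}
    heights = []
    next_id = n

    def cdist(a, b):
        ma, mb = clusters[a], clusters[b]
        if method == "single":
            return min(base[i, j] for i in ma for j in mb)
        if method == "complete":
            return max(base[i, j] for i in ma for j in mb)
        if method == "group_average":
            return float(np.mean([base[i, j] for i in ma for j in mb]))
        if method == "centroid":
            # ||ca - cb||^2 from squared distances (Gower)
            na, nb = len(ma), len(mb)
            between = sum(base[i, j] for i in ma for j in mb) / (na * nb)
            wa = sum(base[i, j] for i in ma for j in ma) / (2 * na * na)
            wb = sum(base[i, j] for i in mb for j in mb) / (2 * nb * nb)
            return between - wa - wb
        if method == "ward":
            # merge cost: ESS increase identity on squared distances
            na, nb = len(ma), len(mb)
            between = sum(base[i, j] for i in ma for j in mb) / (na * nb)
            wa = sum(base[i, j] for i in ma for j in ma) / (2 * na * na)
            wb = sum(base[i, j] for i in mb for j in mb) / (2 * nb * nb)
            return 2.0 * na * nb / (na + nb) * (between - wa - wb)
        return rec[(a, b)]

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai, a in enumerate(keys):
            for b in keys[ai + 1 :]:
                v = cdist(a, b)
                if best is None or v < best[0]:
                    best = (v, a, b)
        v, a, b = best
        heights.append(np.sqrt(max(v, 0.0)) if squared else v)
        na, nb = len(clusters[a]), len(clusters[b])
        for k in keys:
            if k in (a, b):
                continue
            if method == "weighted_average":
                new = 0.5 * rec[(k, a)] + 0.5 * rec[(k, b)]
            elif method == "median":
                new = 0.5 * rec[(k, a)] + 0.5 * rec[(k, b)] - 0.25 * rec[(a, b)]
            elif method == "flexible":
                g = (1.0 - beta) / 2.0
                new = g * rec[(k, a)] + g * rec[(k, b)] + beta * rec[(a, b)]
            else:
                new = None
            if new is not None:
                rec[(k, next_id)] = rec[(next_id, k)] = new
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return np.asarray(heights)


class TestCutTree:
    def test_extremes(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(7, 2))
        t = agglomerate(euclidean_distance(X, [f"a{i}" for i in range(7)]), "ward")
        assert len(set(cut_tree(t, 7))) == 7
        assert len(set(cut_tree(t, 1))) == 1

    def test_hand_trace_two_clusters(self):
        t = agglomerate(TRIANGLE, "single")
        labels = cut_tree(t, 2)
        assert labels[0] == labels[1] != labels[2]

    def test_out_of_range_rejected(self):
        t = agglomerate(TRIANGLE, "single")
        with pytest.raises(ValueError):
            cut_tree(t, 0)
        with pytest.raises(ValueError):
            cut_tree(t, 4)


class TestNeighborJoining:
    def test_four_leaf_known_tree(self):
        # classic additive matrix: pendant lengths (2, 3, 4, 4) around one edge
        D = dm([[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]],
               ids=list("abcd"))
        tree = neighbor_joining(D)
        assert np.allclose(tree.path_length_matrix(), D.matrix, atol=1e-9)
        assert "(" in tree.to_newick() and tree.to_newick().endswith(";")

    def test_star_tree_zero_internal_branches(self):
        D = dm(2.0 * (1 - np.eye(5)))
        tree = neighbor_joining(D)
        assert np.allclose(tree.path_length_matrix(), D.matrix, atol=1e-9)

    def test_random_additive_recovery(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            leaves, D = random_additive_tree(6, rng)
            tree = neighbor_joining(DistanceMatrix(leaves, D))
            assert np.allclose(tree.path_length_matrix(), D, atol=1e-9)

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(dm([[0.0, 1.0], [1.0, 0.0]]))
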
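import math

import numpy as np
import pytest
import sklearn.metrics as skm

from pedopress import (
    agglomerative,
    cluster_quality_report,
    davies_bouldin,
    distance,
    dunn_index,
    elbow_curve,
    kmeans,
    pairwise_distances,
    silhouette_score,
    standardize,
)
from pedopress.clustering import DegenerateColumnError, UndefinedDistanceError
from oracles import (
    naive_davies_bouldin,
    naive_dunn_paper,
    naive_dunn_standard,
    naive_linkage_heights,
    naive_silhouette,
)


def _random_labeled_set(rng, n_max=50, d=3, k=3):
    n = int(rng.integers(k + 1, n_max + 1))
    points = rng.normal(size=(n, d))
    labels = rng.integers(0, k, size=n)
    while len(np.unique(labels)) < 2:
        labels = rng.integers(0, k, size=n)
    return points, labels


class TestDistance:
    @pytest.mark.parametrize(
        "x,y,metric,expected",
        [
            ((0, 0), (3, 4), "euclidean", 5.0),
            ((0, 0), (3, 4), "manhattan", 7.0),
            ((1, 1, 0), (1, 0, 1), "jaccard", 2 / 3),
            ((1, 0), (0, 1), "cosine", 1.0),
        ],
    )
    def test_examples(self, x, y, metric, expected):
        assert distance(x, y, metric) == pytest.approx(expected)

    @pytest.mark.parametrize("metric", ["euclidean", "manhattan", "cosine", "jaccard"])
    def test_identity_of_indiscernibles(self, metric, rng):
        x = rng.normal(size=4) + 1.0
        assert distance(x, x, metric) == pytest.approx(0.0, abs=1e-12)

    def test_two_zero_vectors_under_cosine_undefined(self):
        with pytest.raises(UndefinedDistanceError):
            distance((0, 0), (0, 0), "cosine")

    def test_pairwise_matches_scalar(self, rng):
        points = rng.normal(size=(8, 3))
        for metric in ("euclidean", "manhattan", "cosine", "jaccard"):
            d = pairwise_distances(points, metric)
            for i in range(8):
                for j in range(8):
                    assert d[i, j] == pytest.approx(distance(points[i], points[j], metric), abs=1e-10)


class TestStandardize:
    def test_two_point_column(self):
        out = standardize(np.array([[1.0], [3.0]]))
        assert out.ravel() == pytest.approx([-1.0, 1.0])

    def test_idempotent_and_centered(self, rng):
        points = rng.normal(3.0, 2.5, size=(50, 4))
        once = standardize(points)
        assert np.abs(once.mean(axis=0)).max() < 1e-12
        assert once.std(axis=0) == pytest.approx(np.ones(4))
        assert np.allclose(standardize(once), once, atol=1e-12)

    def test_constant_column_named_in_error(self):
        points = np.column_stack([np.arange(5.0), np.full(5, 7.0)])
        with pytest.raises(DegenerateColumnError, match="1"):
            standardize(points)


class TestKMeans:
    def test_four_point_fixture_matches_exhaustive_enumeration(self, four_point_line):
        points, _ = four_point_line
        res = kmeans(points, 2, seed=0)
        # exhaustive enumeration of all 2-partitions of 4 points
        best_inertia, best_partition = math.inf, None
        vals = points.ravel()
        for assign in range(1, 2**4 - 1):
            groups = [np.array([i for i in range(4) if (assign >> i) & 1 == g]) for g in (0, 1)]
            if any(len(g) == 0 for g in groups):
                continue
            inertia = sum(((vals[g] - vals[g].mean()) ** 2).sum() for g in groups)
            if inertia < best_inertia:
                best_inertia, best_partition = inertia, groups
        assert res.inertia == pytest.approx(best_inertia)  # 0.01
        assert best_inertia == pytest.approx(0.01)
        recovered = {frozenset(np.nonzero(res.labels == c)[0].tolist()) for c in (0, 1)}
        assert recovered == {frozenset(g.tolist()) for g in best_partition}

    def test_k_equals_n_zero_inertia(self, rng):
        points = rng.normal(size=(6, 2))
        assert kmeans(points, 6, seed=1).inertia == pytest.approx(0.0, abs=1e-20)

    def test_inertia_trace_non_increasing(self, rng):
        for seed in range(5):
            points = rng.normal(size=(40, 3))
            res = kmeans(points, 4, seed=seed)
            trace = res.inertia_trace
            assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_invalid_k_rejected(self, rng):
        points = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            kmeans(points, 1)
        with pytest.raises(ValueError):
            kmeans(points, 6)

    def test_close_to_sklearn_on_separated_clusters(self):
        from sklearn.cluster import KMeans as SkKMeans
        from pedopress.synthetic import generate_labeled_points

        points, _ = generate_labeled_points(3, 30, [[0, 0], [12, 0], [0, 12]], 0.8, seed=2)
        ours = kmeans(points, 3, seed=2)
        theirs = SkKMeans(n_clusters=3, n_init=10, random_state=2).fit(points)
        assert ours.inertia == pytest.approx(theirs.inertia_, rel=1e-6)


class TestElbow:
    def test_largest_drop_enters_true_k(self):
        from pedopress.synthetic import generate_labeled_points

        points, _ = generate_labeled_points(3, 30, [[0, 0], [15, 0], [0, 15]], 0.5, seed=6)
        curve = elbow_curve(points, range(2, 7), seed=6)
        inertias = dict(curve)
        drops = {k: inertias[k - 1] - inertias[k] for k in range(3, 7)}
        assert max(drops, key=drops.get) == 3

    def test_k_equals_n_gives_zero(self, rng):
        points = rng.normal(size=(8, 2))
        curve = elbow_curve(points, [8], seed=0)
        assert curve[0][1] == pytest.approx(0.0, abs=1e-20)

    def test_monotone_over_random_sets(self, rng):
        points = rng.normal(size=(30, 2))
        curve = elbow_curve(points, range(2, 10), seed=3)
        inertias = [v for _, v in curve]
        assert all(b <= a + 1e-9 for a, b in zip(inertias, inertias[1:]))


class TestAgglomerative:
    def test_three_point_single_linkage_by_hand(self):
        points = np.array([[0.0], [1.0], [10.0]])
        dend = agglomerative(points, "single")
        assert dend.merges[:, 2] == pytest.approx([1.0, 9.0])
        assert set(dend.merges[0, :2]) == {0.0, 1.0}

    def test_two_points_merge_at_their_distance(self):
        points = np.array([[0.0, 0.0], [3.0, 4.0]])
        dend = agglomerative(points, "complete")
        assert dend.merges[0, 2] == pytest.approx(5.0)

    @pytest.mark.parametrize("linkage_name", ["single", "complete", "average", "ward"])
    def test_merge_heights_match_naive_lance_williams(self, rng, linkage_name):
        for _ in range(5):
            points = rng.normal(size=(8, 3))
            dend = agglomerative(points, linkage_name)
            oracle = naive_linkage_heights(points, linkage_name)
            assert sorted(dend.merges[:, 2]) == pytest.approx(sorted(oracle))

    def test_monotone_heights(self, rng):
        for linkage_name in ("single", "complete", "average", "ward"):
            points = rng.normal(size=(12, 2))
            heights = agglomerative(points, linkage_name).merges[:, 2]
            assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_cut_produces_k_clusters(self, rng):
        points = rng.normal(size=(15, 2))
        dend = agglomerative(points, "average")
        for k in (2, 3, 5):
            labels = dend.cut(k)
            assert len(np.unique(labels)) == k
            assert labels.min() == 0 and labels.max() == k - 1

    def test_ward_requires_euclidean(self, rng):
        with pytest.raises(ValueError, match="euclidean"):
            agglomerative(rng.normal(size=(5, 2)), "ward", metric="manhattan")


class TestSilhouette:
    def test_four_point_fixture_hand_value(self, four_point_line):
        points, labels = four_point_line
        s, _ = silhouette_score(points, labels)
        assert s[0] == pytest.approx((10.05 - 0.1) / 10.05, abs=1e-12)  # ~0.99005

    def test_coincident_clusters_give_zero(self):
        points = np.array([[1.0, 1.0]] * 4)
        labels = np.array([0, 0, 1, 1])
        s, mean = silhouette_score(points, labels)
        assert mean == 0.0 and (s == 0).all()

    def test_matches_double_loop_oracle_and_sklearn(self, rng):
        for _ in range(10):
            points, labels = _random_labeled_set(rng)
            s, mean = silhouette_score(points, labels)
            o_s, o_mean = naive_silhouette(points, labels)
            assert mean == pytest.approx(o_mean, abs=1e-10)
            assert s == pytest.approx(o_s, abs=1e-10)
            assert mean == pytest.approx(skm.silhouette_score(points, labels), abs=1e-9)

    def test_singleton_cluster_scores_zero(self):
        points = np.array([[0.0], [5.0], [5.1]])
        labels = np.array([0, 1, 1])
        s, _ = silhouette_score(points, labels)
        assert s[0] == 0.0


class TestDaviesBouldin:
    def test_two_square_fixture(self, two_square_clusters):
        points, labels = two_square_clusters
        assert davies_bouldin(points, labels) == pytest.approx(0.2, abs=1e-12)

    def test_two_singletons_give_zero(self):
        points = np.array([[0.0, 0.0], [5.0, 5.0]])
        assert davies_bouldin(points, np.array([0, 1])) == 0.0

    def test_shrinking_spread_decreases_index(self, two_square_clusters):
        points, labels = two_square_clusters
        center = points.mean(axis=0)
        centroids = np.array([points[labels == c].mean(axis=0) for c in (0, 1)])[labels]
        values = []
        for scale in (1.0, 0.5, 0.25):
            shrunk = centroids + scale * (points - centroids)
            values.append(davies_bouldin(shrunk, labels))
        assert values[0] > values[1] > values[2]

    def test_matches_loop_oracle_and_sklearn(self, rng):
        for _ in range(10):
            points, labels = _random_labeled_set(rng)
            ours = davies_bouldin(points, labels)
            assert ours == pytest.approx(naive_davies_bouldin(points, labels), abs=1e-10)
            assert ours == pytest.approx(skm.davies_bouldin_score(points, labels), abs=1e-9)

    def test_coincident_centroids_rejected(self):
        points = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 1.0], [1.0, -1.0]])
        labels = np.array([0, 0, 1, 1])  # both centroids at (1, 0)
        with pytest.raises(ZeroDivisionError):
            davies_bouldin(points, labels)


class TestDunn:
    def test_two_square_fixture_both_variants(self, two_square_clusters):
        points, labels = two_square_clusters
        assert dunn_index(points, labels, "standard") == pytest.approx(5.0, abs=1e-12)
        assert dunn_index(points, labels, "paper") == pytest.approx(0.2, abs=1e-12)

    def test_separation_increases_standard_dunn(self, two_square_clusters):
        points, labels = two_square_clusters
        far = points.copy()
        far[labels == 1, 0] += 10
        assert dunn_index(far, labels) > dunn_index(points, labels)

    def test_all_singletons_give_inf(self):
        points = np.array([[0.0], [1.0], [5.0]])
        assert math.isinf(dunn_index(points, np.array([0, 1, 2]), "standard"))

    def test_matches_loop_oracles(self, rng):
        for _ in range(10):
            points, labels = _random_labeled_set(rng)
            assert dunn_index(points, labels, "standard") == pytest.approx(
                naive_dunn_standard(points, labels), abs=1e-10
            )
            assert dunn_index(points, labels, "paper") == pytest.approx(
                naive_dunn_paper(points, labels), abs=1e-10
            )


class TestInvariances:
    def test_indices_invariant_to_reordering_and_relabeling(self, rng):
        points, labels = _random_labeled_set(rng, n_max=30)
        perm = rng.permutation(len(points))
        relabel = {c: 10 - c for c in np.unique(labels)}
        labels2 = np.array([relabel[c] for c in labels])[perm]
        points2 = points[perm]
        r1 = cluster_quality_report(points, labels)
        r2 = cluster_quality_report(points2, labels2)
        assert r1.silhouette == pytest.approx(r2.silhouette, abs=1e-10)
        assert r1.davies_bouldin == pytest.approx(r2.davies_bouldin, abs=1e-10)
        assert r1.dunn_standard == pytest.approx(r2.dunn_standard, abs=1e-10)
        assert r1.dunn_paper_variant == pytest.approx(r2.dunn_paper_variant, abs=1e-10)

    def test_well_separated_limit(self):
        from pedopress.synthetic import generate_labeled_points

        sil, dbi, dunn = [], [], []
        for scale in (5.0, 50.0, 500.0):
            points, labels = generate_labeled_points(
                3, 15, [[0, 0], [scale, 0], [0, scale]], 1.0, seed=8
            )
            rep = cluster_quality_report(points, labels)
            sil.append(rep.silhouette)
            dbi.append(rep.davies_bouldin)
            dunn.append(rep.dunn_standard)
        assert sil[-1] > 0.99 and sil == sorted(sil)
        assert dbi[-1] < 0.05 and dbi == sorted(dbi, reverse=True)
        assert dunn == sorted(dunn) and dunn[-1] > 50

    def test_silhouette_bounds(self, rng):
        for _ in range(5):
            points, labels = _random_labeled_set(rng)
            s, mean = silhouette_score(points, labels)
            assert (s >= -1 - 1e-12).all() and (s <= 1 + 1e-12).all()
            assert -1 <= mean <= 1
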
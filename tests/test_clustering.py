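import math

import numpy as np
import pytest

from acgsfe import (
    ClusterSearchRange,
    assign_feature_clusters,
    cluster_search_range,
    feature_embedding,
    feature_obs_ratio,
    select_optimal_clusters,
    score_partition,
)


def brute_davies_bouldin(points, labels):
    """Textbook DB: mean over clusters of max_j (S_i + S_j) / M_ij."""
    ids = np.unique(labels)
    cents = np.array([points[labels == i].mean(axis=0) for i in ids])
    scatter = np.array([
        np.mean(np.linalg.norm(points[labels == i] - cents[n], axis=1))
        for n, i in enumerate(ids)
    ])
    k = len(ids)
    ratios = np.zeros(k)
    for i in range(k):
        r = [
            (scatter[i] + scatter[j]) / np.linalg.norm(cents[i] - cents[j])
            for j in range(k) if j != i
        ]
        ratios[i] = max(r)
    return float(np.mean(ratios))


def brute_silhouette(points, labels):
    """Per-point (b-a)/max(a,b); singleton clusters contribute 0."""
    n = len(points)
    dist = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    svals = np.zeros(n)
    for i in range(n):
        own = (labels == labels[i])
        if own.sum() == 1:
            continue
        a = dist[i, own & (np.arange(n) != i)].mean()
        b = min(dist[i, labels == c].mean() for c in np.unique(labels)
                if c != labels[i])
        svals[i] = (b - a) / max(a, b)
    return float(np.mean(svals))


class TestRatioAndRange:
    @pytest.mark.parametrize("nf,no,expected", [
        (2000, 62, 32.26), (12627, 20, 631.35), (7070, 72, 98.19),
    ])
    def test_benchmark_ratios(self, nf, no, expected):
        assert round(feature_obs_ratio(nf, no), 2) == expected

    def test_zero_obs_rejected(self):
        with pytest.raises(ValueError):
            feature_obs_ratio(100, 0)

    @pytest.mark.parametrize("ratio,divisor,kmax", [
        (32.26, 10, 3),    # low-ratio regime
        (500.0, 40, 12),   # high-ratio regime
        (631.35, 60, 10),
        (98.19, 10, 9),
        (8.0, 10, 2),      # tiny ratio clamps to the minimum range
    ])
    def test_range_from_ratio(self, ratio, divisor, kmax):
        r = cluster_search_range(ratio)
        assert (r.divisor, r.min_clusters, r.max_clusters) == (divisor, 2, kmax)


class TestEmbedding:
    def test_identical_and_negated_features(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        X = np.column_stack([x, x, -x])
        corr = feature_embedding(X)
        assert corr[0, 1] == pytest.approx(1.0)
        assert corr[0, 2] == pytest.approx(-1.0)

    def test_block_diagonal_at_large_n(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(500), rng.standard_normal(500)
        X = np.column_stack([a, a + 0.01 * rng.standard_normal(500),
                             b, b + 0.01 * rng.standard_normal(500)])
        corr = feature_embedding(X)
        assert corr[0, 1] > 0.99 and corr[2, 3] > 0.99
        assert abs(corr[0, 2]) < 0.15 and abs(corr[1, 3]) < 0.15

    def test_constant_feature_convention(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        corr = feature_embedding(X)
        assert corr[0, 1] == 0.0 and corr[1, 0] == 0.0
        assert corr[0, 0] == 1.0

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            feature_embedding(np.ones((1, 3)))


class TestScorePartition:
    def test_hand_computed_two_cluster_example(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = np.array([1, 1, 2, 2])
        db, sil = score_partition(pts, labels, 2)
        assert db == pytest.approx(0.01, abs=1e-9)
        assert sil == pytest.approx(0.99, abs=1e-3)

    def test_identical_points_nan_pathway(self):
        pts = np.ones((4, 2))
        db, sil = score_partition(pts, np.array([1, 1, 2, 2]), 2)
        assert math.isnan(db) and math.isnan(sil)

    def test_empty_cluster_rejected(self):
        pts = np.arange(8.0).reshape(4, 2)
        with pytest.raises(ValueError):
            score_partition(pts, np.array([1, 1, 1, 1]), 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_small_embeddings(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((8, 3))
        labels = rng.integers(1, 4, size=8)
        while len(np.unique(labels)) != 3:
            labels = rng.integers(1, 4, size=8)
        db, sil = score_partition(pts, labels, 3)
        assert db == pytest.approx(brute_davies_bouldin(pts, labels), abs=1e-9)
        assert sil == pytest.approx(brute_silhouette(pts, labels), abs=1e-9)


class TestSelectOptimal:
    def _three_block_points(self, seed=0):
        rng = np.random.default_rng(seed)
        return np.concatenate([
            rng.normal(0, 0.3, (10, 2)),
            rng.normal(6, 0.3, (10, 2)),
            rng.normal((0, 9), 0.3, (10, 2)),
        ])

    def test_recovers_three_separated_groups(self):
        pts = self._three_block_points()
        model = select_optimal_clusters(pts, ClusterSearchRange(2, 5, 10, 1.0))
        assert model.num_clusters == 3

    def test_single_candidate_range(self):
        pts = self._three_block_points()
        model = select_optimal_clusters(pts, ClusterSearchRange(2, 2, 10, 1.0))
        assert model.num_clusters == 2

    def test_combined_score_in_unit_interval(self):
        pts = self._three_block_points()
        model = select_optimal_clusters(pts, ClusterSearchRange(2, 5, 10, 1.0))
        c = model.score_table.combined_score
        assert np.all((c[~np.isnan(c)] >= 0) & (c[~np.isnan(c)] <= 1))

    def test_argmin_invariant_to_affine_db_rescaling(self):
        """Min-max normalization makes the winner invariant to affine maps."""
        from acgsfe.clustering import _normalize
        db = np.array([0.8, 0.3, 0.5, np.nan])
        assert np.nanargmin(_normalize(db)) == np.nanargmin(_normalize(5 * db + 2))

    def test_degenerate_all_identical_falls_back_to_min(self):
        """Identical points: every candidate k is invalid -> min_clusters."""
        model = select_optimal_clusters(np.ones((10, 2)),
                                        ClusterSearchRange(2, 4, 10, 1.0))
        assert model.num_clusters == 2


class TestAssignFeatureClusters:
    def test_maximal_cut_every_feature_alone(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 6))
        model = assign_feature_clusters(X, 6)
        assert len(np.unique(model.feature_clusters)) == 6

    def test_duplicated_feature_groups_cocluster(self):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal(30), rng.standard_normal(30)
        X = np.column_stack([a, a, b, b])
        model = assign_feature_clusters(X, 2)
        lab = model.feature_clusters
        assert lab[0] == lab[1] and lab[2] == lab[3] and lab[0] != lab[2]

    def test_block_fixture_recovered(self, blocky_data):
        from sklearn.metrics import adjusted_rand_score
        data, truth = blocky_data
        model = assign_feature_clusters(data.values, 4)
        assert adjusted_rand_score(truth.block_labels, model.feature_clusters) >= 0.9

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError):
            assign_feature_clusters(np.random.default_rng(0).standard_normal((10, 4)), 5)

    def test_labels_partition_features(self, blocky_data):
        data, _ = blocky_data
        model = assign_feature_clusters(data.values, 3)
        counts = np.bincount(model.feature_clusters)[1:]
        assert counts.sum() == data.n_features and (counts > 0).all()


def test_ward_cut_monotonicity():
    """Cutting the same linkage at k and k+1 splits exactly one cluster."""
    from scipy.cluster.hierarchy import fcluster, linkage
    rng = np.random.default_rng(5)
    pts = rng.standard_normal((30, 4))
    Z = linkage(pts, method="ward")
    for k in range(2, 6):
        a = fcluster(Z, t=k, criterion="maxclust")
        b = fcluster(Z, t=k + 1, criterion="maxclust")
        # every k+1 cluster maps into exactly one k cluster; exactly one
        # k cluster is split in two
        parents = {tuple(np.unique(a[b == c])) for c in np.unique(b)}
        assert all(len(p) == 1 for p in parents)
        split_counts = np.array([np.sum([
            1 for c in np.unique(b) if np.unique(a[b == c])[0] == pk
        ]) for pk in np.unique(a)])
        assert np.sum(split_counts == 2) == 1 and np.sum(split_counts == 1) == k - 1
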
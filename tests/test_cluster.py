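from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from enterotyper.cluster import (
    anosim,
    calinski_harabasz,
    identify_drivers,
    pam,
    pcoa,
    select_k,
)
from enterotyper.diversity import DistanceMatrix
from enterotyper.tables import FeatureTable
from tests.conftest import euclidean_dm


def exhaustive_pam_objective(d: np.ndarray, k: int) -> float:
    """Brute-force optimum of the k-medoids objective."""
    n = d.shape[0]
    return min(d[:, list(m)].min(axis=1).sum() for m in combinations(range(n), k))


class TestPam:
    def test_two_tight_pairs(self):
        # d(A,B)=d(C,D)=0.1, all cross distances 1.0
        ids = ["A", "B", "C", "D"]
        m = np.full((4, 4), 1.0)
        np.fill_diagonal(m, 0.0)
        m[0, 1] = m[1, 0] = m[2, 3] = m[3, 2] = 0.1
        a = pam(DistanceMatrix(ids, m), 2)
        assert a.objective == pytest.approx(0.2, abs=1e-12)
        labels = a.labels
        assert labels["A"] == labels["B"]
        assert labels["C"] == labels["D"]
        assert labels["A"] != labels["C"]

    def test_k_equals_n_minus_one(self):
        rng = np.random.default_rng(3)
        pts = rng.random((6, 2))
        d = euclidean_dm(pts)
        a = pam(d, 5)
        # one pair shares a medoid; objective equals the smallest pairwise distance
        off = d.values[np.triu_indices(6, 1)]
        assert a.objective == pytest.approx(off.min(), abs=1e-12)

    def test_duplicate_samples_co_assigned(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.1, 5.0]])
        a = pam(euclidean_dm(pts), 2)
        assert a.labels.iloc[0] == a.labels.iloc[1]

    def test_matches_exhaustive_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = int(rng.integers(5, 11))
            k = int(rng.integers(2, 4))
            d = euclidean_dm(rng.random((n, 2)))
            a = pam(d, k)
            assert a.objective == pytest.approx(
                exhaustive_pam_objective(d.values, k), abs=1e-9
            )

    def test_medoids_belong_to_own_cluster_and_objective_consistent(self, fitted_default):
        res, _ = fitted_default
        a = res.assignment
        for m in a.medoid_ids:
            c = a.labels[m]
            assert m in a.members(c)
        d = res.distance
        pos = {s: i for i, s in enumerate(d.sample_ids)}
        total = sum(
            min(d.values[pos[s], pos[m]] for m in a.medoid_ids) for s in d.sample_ids
        )
        assert a.objective == pytest.approx(total, rel=1e-12)

    def test_invalid_k_rejected(self):
        d = euclidean_dm(np.random.default_rng(0).random((5, 2)))
        with pytest.raises(ValueError):
            pam(d, 1)
        with pytest.raises(ValueError):
            pam(d, 5)


class TestCalinskiHarabasz:
    def test_six_point_instance(self):
        coords = np.array([0.0, 0.1, 0.2, 10.0, 10.1, 10.2])
        d = euclidean_dm(coords)
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=d.sample_ids)
        from enterotyper.cluster import ClusterAssignment

        a = ClusterAssignment(labels, ["s0", "s3"], 0.0)
        ch = calinski_harabasz(d, a)
        # B=150, W=0.04 -> (150/1)/(0.04/4) = 15000
        assert ch == pytest.approx(15000.0, rel=1e-9)

    def test_wrong_split_scores_lower(self):
        coords = np.array([0.0, 0.1, 0.2, 10.0, 10.1, 10.2])
        d = euclidean_dm(coords)
        from enterotyper.cluster import ClusterAssignment

        wrong = ClusterAssignment(
            pd.Series([1, 1, 2, 2, 2, 2], index=d.sample_ids), ["s0", "s3"], 0.0
        )
        assert calinski_harabasz(d, wrong) < 15000.0

    def test_agrees_with_sklearn_on_embedding(self):
        from sklearn.metrics import calinski_harabasz_score

        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(4, 1, (12, 3))])
        d = euclidean_dm(pts)
        labels = pd.Series([1] * 10 + [2] * 12, index=d.sample_ids)
        from enterotyper.cluster import ClusterAssignment

        a = ClusterAssignment(labels, [d.sample_ids[0], d.sample_ids[10]], 0.0)
        ours = calinski_harabasz(d, a)
        ref = calinski_harabasz_score(pts, labels.values)
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_degenerate_within_zero(self):
        pts = np.array([[0.0], [0.0], [1.0], [1.0]])
        d = euclidean_dm(pts)
        from enterotyper.cluster import ClusterAssignment

        a = ClusterAssignment(pd.Series([1, 1, 2, 2], index=d.sample_ids), ["s0", "s2"], 0.0)
        with pytest.warns(UserWarning, match="infinite"):
            assert calinski_harabasz(d, a) == np.inf


class TestSelectK:
    def test_three_well_separated_clouds(self):
        rng = np.random.default_rng(2)
        pts = np.vstack(
            [rng.normal(c, 0.05, (8, 2)) for c in [(0, 0), (5, 0), (0, 5)]]
        )
        trace, a = select_k(euclidean_dm(pts), range(2, 7))
        assert trace.optimal_k == 3
        assert a.k == 3

    def test_trace_invariants(self, fitted_default):
        res, _ = fitted_default
        t = res.trace
        assert t.optimal_k == t.k_values[int(np.argmax(t.ch_scores))]
        assert all(np.isfinite(t.ch_scores))
        assert all(s > 0 for s in t.ch_scores)

    def test_empty_range_rejected(self):
        d = euclidean_dm(np.random.default_rng(0).random((6, 2)))
        with pytest.raises(ValueError, match="empty"):
            select_k(d, [])


class TestDrivers:
    def test_highest_mean_wins_and_tie_breaks_lexicographically(self):
        df = pd.DataFrame(
            {"s1": [0.3, 0.3, 0.4], "s2": [0.3, 0.3, 0.4], "s3": [0.1, 0.8, 0.1]},
            index=["b_feat", "a_feat", "c_feat"],
        )
        t = FeatureTable(df, kind="relative")
        from enterotyper.cluster import ClusterAssignment

        a = ClusterAssignment(
            pd.Series([1, 1, 2], index=["s1", "s2", "s3"]), ["s1", "s3"], 0.0
        )
        drv = identify_drivers(t, a)
        top1 = drv[(drv.cluster == 1) & (drv["rank"] == 1)].feature.iloc[0]
        top2 = drv[(drv.cluster == 2) & (drv["rank"] == 1)].feature.iloc[0]
        assert top1 == "c_feat"  # 0.4 beats the 0.3 tie
        assert top2 == "a_feat"
        # tie between a_feat and b_feat at 0.3 in cluster 1 -> a_feat ranks before b_feat
        r2 = drv[(drv.cluster == 1) & (drv["rank"] == 2)].feature.iloc[0]
        assert r2 == "a_feat"

    def test_clusters_can_share_a_driver(self, fitted_default):
        res, _ = fitted_default
        drv = res.drivers()
        tops = drv[drv["rank"] == 1].set_index("cluster").feature
        # the dominant pooled residual feature can top both communities
        assert tops.nunique() <= 2


class TestPcoa:
    def test_collinear_points_recover_distances(self):
        # mutual distances 1, 1, 2 -> a line; one dominant positive eigenvalue
        m = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        res = pcoa(DistanceMatrix(["a", "b", "c"], m))
        assert (res.eigenvalues > 1e-8).sum() == 1
        c = res.coordinates.to_numpy()
        rec = np.abs(c[:, 0][:, None] - c[:, 0][None, :])
        np.testing.assert_allclose(rec, m, atol=1e-9)

    def test_duplicated_sample_coincident(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0]])
        res = pcoa(euclidean_dm(pts))
        c = res.coordinates.to_numpy()
        np.testing.assert_allclose(c[0], c[1], atol=1e-9)

    def test_proportions_sum_to_at_most_one(self, fitted_default):
        res, _ = fitted_default
        pe = res.ordination.proportion_explained
        assert pe.sum() <= 1 + 1e-9
        assert (np.diff(res.ordination.eigenvalues) <= 1e-9).all()

    def test_euclidean_input_reconstructed(self):
        rng = np.random.default_rng(9)
        pts = rng.random((8, 3))
        d = euclidean_dm(pts)
        res = pcoa(d)
        c = res.coordinates.to_numpy()
        from scipy.spatial.distance import pdist, squareform

        np.testing.assert_allclose(squareform(pdist(c)), d.values, atol=1e-8)

    def test_matches_skbio_coordinates(self):
        import skbio

        rng = np.random.default_rng(13)
        pts = rng.random((10, 4))
        d = euclidean_dm(pts)
        ours = pcoa(d).coordinates.to_numpy()
        ref = skbio.stats.ordination.pcoa(d.to_skbio(), method="eigh").samples.to_numpy()
        k = min(ours.shape[1], 4)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(
            pdist(ours[:, :k]), pdist(ref[:, :k]), atol=1e-8
        )


class TestAnosim:
    def test_perfect_separation_r_one(self):
        pts = np.vstack([np.random.default_rng(1).normal(0, 0.01, (5, 2)),
                         np.random.default_rng(2).normal(10, 0.01, (5, 2))])
        d = euclidean_dm(pts)
        r, p = anosim(d, ["a"] * 5 + ["b"] * 5, n_perm=99, seed=0)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p >= 1.0 / 100.0

    def test_seed_reproducible(self, fitted_default):
        res, _ = fitted_default
        r1, p1 = anosim(res.distance, res.labels, n_perm=99, seed=5)
        r2, p2 = anosim(res.distance, res.labels, n_perm=99, seed=5)
        assert (r1, p1) == (r2, p2)

    def test_matches_handrolled_statistic(self):
        """Cross-check skbio's R against a direct rank computation."""
        from scipy.stats import rankdata

        rng = np.random.default_rng(21)
        pts = rng.random((12, 2))
        d = euclidean_dm(pts)
        groups = np.array(["a"] * 6 + ["b"] * 6)
        r, _ = anosim(d, list(groups), n_perm=9, seed=0)
        iu = np.triu_indices(12, 1)
        ranks = rankdata(d.values[iu])
        within = groups[iu[0]] == groups[iu[1]]
        n = 12
        r_ref = (ranks[~within].mean() - ranks[within].mean()) / (n * (n - 1) / 4)
        assert r == pytest.approx(r_ref, abs=1e-12)

    def test_singleton_group_rejected(self):
        d = euclidean_dm(np.random.default_rng(0).random((5, 2)))
        with pytest.raises(ValueError, match="fewer than 2"):
            anosim(d, ["a", "a", "a", "a", "b"], n_perm=9, seed=0)
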
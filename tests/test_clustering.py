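from itertools import combinations, product

import numpy as np
import pytest
from scipy.stats import norm

import actionenc as ae
from actionenc.config import DataError
from actionenc.clustering import choose_k
from conftest import pair_enumeration_dprime


def _two_group_profiles(n_per=30, dim=8, jitter=0.02, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=dim)
    profiles = np.vstack([
        a + rng.normal(0, jitter, (n_per, dim)),
        -a + rng.normal(0, jitter, (n_per, dim)),
    ])
    labels = np.repeat([0, 1], n_per)
    return profiles, labels


class TestKmeansCorrelation:
    def test_k_one_single_label(self):
        P = np.random.default_rng(0).normal(size=(20, 6))
        sol = ae.kmeans_correlation(P, 1, seed=0)
        assert set(sol.labels) == {1}

    def test_antipodal_groups_recovered(self):
        P, truth = _two_group_profiles()
        sol = ae.kmeans_correlation(P, 2, seed=1)
        # exact recovery up to label permutation
        first = sol.labels[:30]
        assert len(set(first)) == 1
        assert len(set(sol.labels[30:])) == 1
        assert sol.labels[0] != sol.labels[-1]

    def test_scaled_row_has_zero_distance_to_centroid(self):
        """Correlation distance is invariant to positive rescaling."""
        P, _ = _two_group_profiles()
        sol = ae.kmeans_correlation(P, 2, seed=2)
        row = 5.0 * P[0] + 3.0     # rescale + shift of a member profile
        rown = (row - row.mean()) / np.linalg.norm(row - row.mean())
        d = 1.0 - rown @ sol.centroids[sol.labels[0] - 1]
        assert d < 0.01

    def test_affine_profile_transform_preserves_labels(self):
        P, _ = _two_group_profiles(seed=3)
        sol1 = ae.kmeans_correlation(P, 2, seed=5)
        sol2 = ae.kmeans_correlation(3.0 * P + 7.0, 2, seed=5)
        np.testing.assert_array_equal(sol1.labels, sol2.labels)

    def test_k_exceeding_voxels_rejected(self):
        with pytest.raises(DataError):
            ae.kmeans_correlation(np.random.default_rng(0).normal(
                size=(4, 5)), 10, seed=0)

    def test_low_variance_rows_excluded(self):
        P, _ = _two_group_profiles()
        P[3] = 2.5                     # constant profile
        sol = ae.kmeans_correlation(P, 2, seed=0)
        assert sol.labels[3] == 0
        assert ae.exclude_low_variance(P)[3]
        assert not ae.exclude_low_variance(P)[0]


class TestDPrime:
    def test_four_voxel_worked_example(self):
        res = ae.coassignment_dprime(np.array([1, 1, 2, 2]),
                                     np.array([1, 2, 1, 2]))
        assert res.hit_rate == pytest.approx(1 / 12)
        assert res.fa_rate == pytest.approx(0.5)
        assert res.dprime == pytest.approx(norm.ppf(1 / 12), abs=1e-9)
        assert res.dprime == pytest.approx(-1.383, abs=1e-3)

    def test_identity_partition_clamped_maximum(self):
        a = np.array([1, 1, 2, 2, 3, 3])
        res = ae.coassignment_dprime(a, a)
        total = 15
        assert res.hit_rate == pytest.approx(1 - 1 / (2 * total))
        assert res.fa_rate == pytest.approx(1 / (2 * total))
        assert res.dprime > 0

    def test_exhaustive_bruteforce_equivalence_small_n(self):
        """Contingency-table counting agrees with full pair enumeration on
        every pair of partitions of 5 items (and a sample at n = 8)."""
        def partitions(n):
            # all label vectors in canonical (restricted growth) form
            def rec(prefix, m):
                if len(prefix) == n:
                    yield tuple(prefix)
                    return
                for v in range(m + 1):
                    yield from rec(prefix + [v], max(m, v + 1))
            yield from rec([0], 1)

        parts5 = list(partitions(5))
        assert len(parts5) == 52       # Bell(5)
        checked = 0
        for a, b in product(parts5, repeat=2):
            a, b = np.array(a), np.array(b)
            same_a = sum(a[i] == a[j] for i, j in combinations(range(5), 2))
            if same_a in (0, 10):
                with pytest.raises(DataError):
                    ae.coassignment_dprime(a, b)
                continue
            hit, fa, dp = pair_enumeration_dprime(a, b)
            res = ae.coassignment_dprime(a, b)
            assert res.hit_rate == pytest.approx(hit, abs=1e-12)
            assert res.fa_rate == pytest.approx(fa, abs=1e-12)
            assert res.dprime == pytest.approx(dp, abs=1e-12)
            checked += 1
        assert checked > 2000

    def test_random_partitions_null(self):
        rng = np.random.default_rng(0)
        vals = [ae.coassignment_dprime(rng.integers(0, 5, 4000),
                                       rng.integers(0, 5, 4000)).dprime
                for _ in range(20)]
        assert abs(np.mean(vals)) < 0.01

    def test_degenerate_conditioning_rejected(self):
        with pytest.raises(DataError):
            ae.coassignment_dprime(np.array([1, 1, 1]), np.array([1, 2, 3]))


class TestShuffledBaseline:
    def test_baseline_near_zero_and_reproducible(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 5, 3000)
        b = rng.integers(0, 5, 3000)
        res1 = ae.shuffled_baseline(a, b, n_shuffles=30, seed=3)
        res2 = ae.shuffled_baseline(a, b, n_shuffles=30, seed=3)
        assert abs(res1["mean"]) < 0.05
        np.testing.assert_array_equal(res1["values"], res2["values"])

    def test_baseline_sd_shrinks_with_voxel_count(self):
        rng = np.random.default_rng(2)
        sds = []
        for n in (500, 2000):
            a = rng.integers(0, 4, n)
            b = rng.integers(0, 4, n)
            sds.append(ae.shuffled_baseline(a, b, n_shuffles=40,
                                            seed=0)["sd"])
        assert sds[1] < sds[0]


class TestCentroidMatching:
    def test_permuted_copy_perfect_match(self):
        rng = np.random.default_rng(0)
        C = rng.normal(size=(4, 8))
        sa = ae.ClusterSolution(labels=np.ones(4, int), centroids=C,
                                k=4, inertia=0.0)
        perm = [2, 0, 3, 1]
        sb = ae.ClusterSolution(labels=np.ones(4, int), centroids=C[perm],
                                k=4, inertia=0.0)
        pairing, rs = ae.match_centroids(sa, sb)
        np.testing.assert_allclose(rs, 1.0)
        assert [p[1] for p in sorted(pairing)] == [perm.index(i)
                                                   for i in range(4)]

    def test_three_by_three_matches_exhaustive_search(self):
        rng = np.random.default_rng(3)
        Ca, Cb = rng.normal(size=(2, 3, 10))
        sa = ae.ClusterSolution(np.ones(3, int), Ca, 3, 0.0)
        sb = ae.ClusterSolution(np.ones(3, int), Cb, 3, 0.0)
        pairing, rs = ae.match_centroids(sa, sb)
        C = np.corrcoef(Ca, Cb)[:3, 3:]
        from itertools import permutations
        best = max(permutations(range(3)),
                   key=lambda p: sum(C[i, p[i]] for i in range(3)))
        assert [p[1] for p in sorted(pairing)] == list(best)

    def test_unequal_k_rejected(self):
        sa = ae.ClusterSolution(np.ones(3, int),
                                np.random.default_rng(0).normal(size=(3, 5)),
                                3, 0.0)
        sb = ae.ClusterSolution(np.ones(2, int),
                                np.random.default_rng(1).normal(size=(2, 5)),
                                2, 0.0)
        with pytest.raises(DataError):
            ae.match_centroids(sa, sb)


class TestColors:
    def test_colors_in_unit_cube(self):
        C = np.random.default_rng(0).normal(size=(5, 12))
        colors = ae.mds_colors(C)
        assert colors.shape == (5, 3)
        assert colors.min() >= 0 and colors.max() <= 1

    def test_identical_centroids_share_color(self):
        rng = np.random.default_rng(1)
        C = rng.normal(size=(3, 6))
        C[1] = C[0]
        colors = ae.mds_colors(C)
        np.testing.assert_allclose(colors[0], colors[1], atol=1e-8)

    def test_color_distance_tracks_centroid_dissimilarity(self):
        rng = np.random.default_rng(2)
        C = rng.normal(size=(6, 12))
        colors = ae.mds_colors(C)
        D = 1 - np.corrcoef(C)
        iu = np.triu_indices(6, 1)
        dc = np.linalg.norm(colors[iu[0]] - colors[iu[1]], axis=1)
        from scipy.stats import spearmanr
        rho, _ = spearmanr(D[iu], dc)
        assert rho > 0


class TestKDiagnostics:
    def test_silhouette_maximal_at_true_k(self):
        rng = np.random.default_rng(4)
        protos = rng.normal(size=(3, 10))
        P = np.vstack([p + rng.normal(0, 0.05, (25, 10)) for p in protos])
        diag = ae.k_diagnostics(P, k_range=range(2, 7), replicates=5,
                                seed=0)
        table = diag["table"]
        best = max(table, key=lambda r: r["silhouette"])
        assert best["k"] == 3
        assert choose_k(diag) == 3

    def test_k_one_rejected(self):
        P = np.random.default_rng(0).normal(size=(10, 4))
        with pytest.raises(ValueError):
            ae.k_diagnostics(P, k_range=range(1, 4))

    def test_excess_k_duplicates_centroids(self):
        """With more clusters than archetypes, centroid similarity climbs
        toward 1 (duplicate centroids)."""
        rng = np.random.default_rng(5)
        protos = rng.normal(size=(2, 8))
        P = np.vstack([p + rng.normal(0, 0.03, (30, 8)) for p in protos])
        diag = ae.k_diagnostics(P, k_range=[2, 6], replicates=5, seed=0)
        tab = {r["k"]: r["centroid_similarity"] for r in diag["table"]}
        assert tab[6] > tab[2]
        assert tab[6] > 0.5


class TestResponseClustering:
    def test_planted_networks_recovered_from_responses(self, small_study,
                                                       small_fits):
        data, truth = small_study["data"], small_study["truth"]
        sig = truth.reliable_mask
        sol = ae.cluster_responses(data.split_average(1)[sig], 5, seed=0)
        gt = truth.network_label[sig]
        res = ae.coassignment_dprime(gt, sol.labels)
        assert res.dprime > 1.5
        # feature-based and response-based solutions agree
        fsol = ae.kmeans_correlation(small_fits[1].weights[sig], 5, seed=0)
        agree = ae.coassignment_dprime(fsol.labels, sol.labels)
        assert agree.dprime > 1.5

    def test_constant_response_voxel_excluded(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(40, 60))
        P[7] = 1.25
        sol = ae.cluster_responses(P, 2, seed=0)
        assert sol.labels[7] == 0
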
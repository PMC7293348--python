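import numpy as np
import pytest

import actionenc as ae
from actionenc.config import DataError
from actionenc.features import project


class TestAverageRatings:
    def test_simple_mean(self):
        tensor = np.zeros((1, 2, 12))
        tensor[0, 0, :] = 1          # 12/12 raters select feature 0
        tensor[0, 1, :9] = 1         # 9/12 select feature 1
        rm = ae.average_ratings(tensor, ["mouth", "hand"], ["v0"])
        assert rm.values[0, 0] == 1.0
        assert rm.values[0, 1] == pytest.approx(0.75)

    def test_lateralized_collapse(self):
        # left-hand-only selections map to the single "hands" feature
        tensor = np.zeros((1, 3, 4))
        tensor[0, 0, :] = 1          # left_hand selected by all raters
        rm = ae.average_ratings(tensor, ["left_hand", "right_hand", "eyes"],
                                ["v0"])
        assert rm.feature_names == ["hands", "eyes"]
        assert rm.values[0, 0] == 1.0

    def test_unrated_video_rejected(self):
        tensor = np.full((2, 3, 4), np.nan)
        tensor[0] = 1
        with pytest.raises(DataError):
            ae.average_ratings(tensor, ["a", "b", "c"], ["v0", "v1"])


class TestPCA:
    def test_rank_one_matrix_keeps_one_component(self):
        rng = np.random.default_rng(0)
        u = rng.random(30)[:, None]
        v = rng.random(6)[None, :]
        rm = ae.RatingMatrix(u @ v / (u @ v).max(), list("abcdef"),
                             [f"v{i}" for i in range(30)])
        fs = ae.fit_pca(rm, variance_threshold=1.0 - 1e-9)
        assert fs.n_components_retained == 1

    def test_archetype_rank_recovered(self):
        """Ratings carrying 7 latent archetype directions plus small noise
        need 7 components at the 95% threshold; the count is verified by
        an independent eigendecomposition of the centered covariance."""
        rng = np.random.default_rng(42)
        # 7 orthogonal archetype directions with a prescribed variance
        # spectrum whose cumulative share crosses 95% exactly at 7
        basis = np.linalg.qr(rng.normal(size=(20, 7)))[0]
        sv = np.sqrt(np.array([30, 20, 15, 10, 9, 8, 8.0]))
        scores = rng.normal(size=(60, 7)) * sv
        X = scores @ basis.T + rng.normal(0, 0.08, (60, 20))
        # oracle: eigenvalues of the centered covariance
        Xc = X - X.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        cum = np.cumsum(evals) / evals.sum()
        oracle_m = int(np.searchsorted(cum, 0.95) + 1)
        assert oracle_m == 7
        X01 = (X - X.min()) / (X.max() - X.min())   # onto the rating scale
        rm = ae.RatingMatrix(X01, [f"f{i}" for i in range(20)],
                             [f"v{i}" for i in range(60)])
        fs = ae.fit_pca(rm, 0.95)
        assert fs.n_components_retained == oracle_m

    def test_constant_matrix_rejected(self):
        rm = ae.RatingMatrix(np.full((10, 4), 0.5), list("abcd"),
                             [f"v{i}" for i in range(10)])
        with pytest.raises(DataError):
            ae.fit_pca(rm)

    def test_scores_centered_with_diagonal_covariance(self, small_study):
        fs = ae.fit_pca(small_study["body"], 0.95)
        np.testing.assert_allclose(fs.scores.mean(axis=0), 0, atol=1e-10)
        cov = fs.scores.T @ fs.scores
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(cov)).max()

    def test_cumulative_variance_nondecreasing(self, small_study):
        fs = ae.fit_pca(small_study["body"], 0.95)
        cum = np.cumsum(fs.explained_variance)
        assert np.all(np.diff(cum) >= -1e-15)
        assert cum[-1] <= 1 + 1e-9


class TestCombineAndBackproject:
    def test_column_counts_add(self, small_study):
        body = ae.fit_pca(small_study["body"], 0.95)
        target = ae.fit_pca(small_study["target"], 0.95)
        dm = ae.combine_spaces(body, target)
        assert dm.values.shape[1] == (body.n_components_retained
                                      + target.n_components_retained)
        assert len(dm.column_provenance) == dm.values.shape[1]

    def test_video_mismatch_rejected(self, small_study):
        body = ae.fit_pca(small_study["body"], 0.95)
        target = ae.fit_pca(small_study["target"], 0.95)
        target.video_ids = list(target.video_ids)[::-1]
        with pytest.raises(DataError):
            ae.combine_spaces(body, target)

    def test_backproject_zero_profile(self, small_study):
        body = ae.fit_pca(small_study["body"], 0.95)
        target = ae.fit_pca(small_study["target"], 0.95)
        F = body.n_components_retained + target.n_components_retained
        out = ae.backproject(np.zeros(F), body, target)
        assert out.shape == (25,)
        np.testing.assert_allclose(out, 0)

    def test_full_retention_roundtrip(self, small_study):
        """With every component retained, projecting then back-projecting
        reproduces the centered ratings (orthogonality of the loadings)."""
        body = ae.fit_pca(small_study["body"], 1.0)
        target = ae.fit_pca(small_study["target"], 1.0)
        xb = small_study["body"].values[3]
        xt = small_study["target"].values[3]
        profile = np.concatenate([project(body, xb), project(target, xt)])
        back = ae.backproject(profile, body, target)
        expected = np.concatenate([xb - body.feature_means,
                                   xt - target.feature_means])
        np.testing.assert_allclose(back, expected, atol=1e-10)

    def test_backproject_matches_matmul_oracle_and_linearity(self,
                                                             small_study):
        body = ae.fit_pca(small_study["body"], 0.95)
        target = ae.fit_pca(small_study["target"], 0.95)
        nb, nt = body.n_components_retained, target.n_components_retained
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=(2, nb + nt))
        direct = np.concatenate([body.loadings @ x[:nb],
                                 target.loadings @ x[nb:]])
        np.testing.assert_allclose(ae.backproject(x, body, target), direct)
        lhs = ae.backproject(2.0 * x - 3.0 * y, body, target)
        rhs = 2.0 * ae.backproject(x, body, target) \
            - 3.0 * ae.backproject(y, body, target)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_backproject_length_mismatch_rejected(self, small_study):
        body = ae.fit_pca(small_study["body"], 0.95)
        target = ae.fit_pca(small_study["target"], 0.95)
        with pytest.raises(DataError):
            ae.backproject(np.zeros(3), body, target)


class TestFeatureCorrelations:
    def test_duplicated_column_r_one(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=12)
        other = rng.normal(size=12)
        dm = ae.DesignMatrix(
            values=np.column_stack([col, col, other]),
            column_provenance=[{"space": "body", "component": 0},
                               {"space": "tgt", "component": 0},
                               {"space": "tgt", "component": 1}],
            video_ids=[f"v{i}" for i in range(12)])
        res = ae.feature_correlations(dm)
        assert res["pairs"][0, 0] == pytest.approx(1.0)

    def test_cross_space_columns_nearly_uncorrelated(self, small_study):
        res = ae.feature_correlations(small_study["design"])
        assert abs(res["mean"]) < 0.15
        assert res["min"] <= res["mean"] <= res["max"]

    def test_zero_variance_column_flagged(self):
        rng = np.random.default_rng(4)
        dm = ae.DesignMatrix(
            values=np.column_stack([np.ones(10), rng.normal(size=10),
                                    rng.normal(size=10)]),
            column_provenance=[{"space": "a", "component": 0},
                               {"space": "a", "component": 1},
                               {"space": "b", "component": 0}],
            video_ids=[f"v{i}" for i in range(10)])
        with pytest.warns(RuntimeWarning):
            res = ae.feature_correlations(dm)
        assert res["pairs"].shape == (1, 1)   # constant column excluded


class TestRDM:
    def test_identical_features_give_r_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 6))
        assert ae.rdm_correlation(X, X) == pytest.approx(1.0)

    def test_independent_features_near_zero(self):
        rng = np.random.default_rng(2)
        r = ae.rdm_correlation(rng.normal(size=(60, 8)),
                               rng.normal(size=(60, 8)))
        assert abs(r) < 0.2

    def test_four_video_toy_matches_hand_enumeration(self):
        rng = np.random.default_rng(3)
        A, B = rng.normal(size=(2, 4, 5))
        # oracle: all 6 unordered video pairs, correlation of 1-r entries
        da, db = [], []
        for i in range(4):
            for j in range(i):
                da.append(1 - np.corrcoef(A[i], A[j])[0, 1])
                db.append(1 - np.corrcoef(B[i], B[j])[0, 1])
        expected = np.corrcoef(da, db)[0, 1]
        assert ae.rdm_correlation(A, B) == pytest.approx(expected)

    def test_constant_feature_vector_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 4))
        X[2] = 1.0
        with pytest.raises(DataError):
            ae.rdm_correlation(X, X)
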
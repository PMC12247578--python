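"""Mean-centered and seed PLS: builders, SVD, permutation, bootstrap, clusters."""
import numpy as np
import pytest

import hippopls as hp
from hippopls.pls import StackedBrainMatrix, _build


def make_stack(rows, n_subjects=None):
    rows = np.asarray(rows, float)
    n = rows.shape[0] // 2
    return StackedBrainMatrix(
        X=rows,
        conditions=np.array(["AM", "MA"] * n),
        subjects=np.repeat(np.arange(n), 2),
    )


def null_stack(rng, n=24, v=200):
    return hp.simulate_group_null(n, v, rng)


class TestStackedMatrix:
    def test_requires_full_condition_sets(self):
        with pytest.raises(ValueError, match="one row per condition"):
            StackedBrainMatrix(
                X=np.zeros((3, 4)),
                conditions=np.array(["AM", "MA", "AM"]),
                subjects=np.array([0, 0, 1]),
            )

    def test_stack_contrast_maps_drops_zero_columns(self, caplog):
        ones = np.ones((2, 2, 2))
        ones[0, 0, 0] = 0.0  # voxel 0 is zero in every map
        maps = {
            (0, "AM"): np.arange(8.0).reshape(2, 2, 2),
            (0, "MA"): np.arange(8.0).reshape(2, 2, 2),
            (1, "AM"): ones,
            (1, "MA"): ones,
        }
        mask = np.ones((2, 2, 2), bool)
        X = hp.stack_contrast_maps(maps, mask)
        # voxel 0 is zero in every map and gets masked out
        assert X.X.shape == (4, 7)
        assert 0 not in X.mask_flat


class TestMeanCentered:
    def test_arithmetic_example(self):
        X = make_stack([[1, 2, 3], [3, 2, 1]])
        M = hp.build_mean_centered(X)
        np.testing.assert_allclose(M, [[-1, 0, 1], [1, 0, -1]])

    def test_identical_conditions_give_zero(self):
        row = np.array([2.0, 5.0, 7.0])
        X = make_stack([row, row, row + 1, row + 1])
        M = hp.build_mean_centered(X)
        np.testing.assert_allclose(M, 0.0, atol=1e-12)

    def test_columns_sum_to_zero_three_conditions(self):
        rng = np.random.default_rng(0)
        n = 6
        X = StackedBrainMatrix(
            X=rng.standard_normal((3 * n, 40)),
            conditions=np.array(["A", "B", "C"] * n),
            subjects=np.repeat(np.arange(n), 3),
        )
        M = hp.build_mean_centered(X)
        np.testing.assert_allclose(M.sum(axis=0), 0.0, atol=1e-12)

    def test_single_condition_rejected(self):
        X = StackedBrainMatrix(
            X=np.zeros((2, 3)), conditions=np.array(["AM", "AM"]),
            subjects=np.array([0, 1]),
        )
        with pytest.raises(ValueError, match="two conditions"):
            hp.build_mean_centered(X)

    def test_two_conditions_one_latent_variable(self):
        """Rank-1 structure: LV1 voxel salience is the AM-minus-MA map."""
        rng = np.random.default_rng(1)
        X = null_stack(rng, n=10, v=50)
        M = hp.build_mean_centered(X)
        U, S, V = hp.pls_svd(M)
        assert S[1] == pytest.approx(0.0, abs=1e-10)
        diff = X.X[X.conditions == "AM"].mean(0) - X.X[X.conditions == "MA"].mean(0)
        direction = diff / np.linalg.norm(diff)
        assert abs(abs(direction @ V[:, 0]) - 1.0) < 1e-10


class TestSvd:
    def test_oracle_example(self):
        U, S, V = hp.pls_svd(np.array([[-1.0, 0.0, 1.0], [1.0, 0.0, -1.0]]))
        assert S[0] == pytest.approx(2.0)
        assert S[1] == pytest.approx(0.0, abs=1e-12)
        v1 = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2)
        np.testing.assert_allclose(np.abs(V[:, 0]), np.abs(v1), atol=1e-12)
        # sign convention: dominant design salience positive
        assert U[np.argmax(np.abs(U[:, 0])), 0] > 0

    def test_zero_matrix(self):
        _, S, _ = hp.pls_svd(np.zeros((2, 5)))
        np.testing.assert_allclose(S, 0.0)

    def test_rotation_invariance_of_singular_values(self):
        rng = np.random.default_rng(2)
        M = rng.standard_normal((3, 20))
        Q, _ = np.linalg.qr(rng.standard_normal((20, 20)))
        _, S1, _ = hp.pls_svd(M)
        _, S2, _ = hp.pls_svd(M @ Q)
        np.testing.assert_allclose(S1, S2, atol=1e-10)

    def test_reconstruction(self):
        rng = np.random.default_rng(3)
        M = rng.standard_normal((4, 30))
        U, S, V = hp.pls_svd(M)
        np.testing.assert_array_less(
            np.linalg.norm(M - U @ np.diag(S) @ V.T), 1e-10 * np.linalg.norm(M)
        )


class TestSeedMatrix:
    def test_voxel_copy_of_seed_has_unit_correlation(self):
        rng = np.random.default_rng(4)
        X = null_stack(rng, n=8, v=10)
        seed = X.X[:, 3].copy()
        R = hp.build_seed_matrix(X, seed)
        assert R[0, 3] == pytest.approx(1.0)
        assert R[1, 3] == pytest.approx(1.0)

    def test_perfect_linear_relation(self):
        X = make_stack([[2.0, 9], [1, 8], [4, 7], [3, 6], [6, 5], [5, 4], [8, 3], [7, 2]])
        seed = np.array([1.0, 0.5, 2, 1.5, 3, 2.5, 4, 3.5])  # voxel0 = 2*seed
        R = hp.build_seed_matrix(X, seed)
        assert R[0, 0] == pytest.approx(1.0)
        assert R[1, 0] == pytest.approx(1.0)

    def test_matches_naive_loop(self):
        """Vectorized rows equal an independent per-voxel correlation loop."""
        rng = np.random.default_rng(5)
        X = null_stack(rng, n=12, v=30)
        seed = rng.standard_normal(24)
        R = hp.build_seed_matrix(X, seed)
        for ci, cond in enumerate(X.condition_list):
            idx = X.conditions == cond
            for v in range(30):
                r_ref = np.corrcoef(seed[idx], X.X[idx, v])[0, 1]
                assert R[ci, v] == pytest.approx(r_ref, abs=1e-12)

    def test_independent_seed_null_distribution(self):
        """Null correlations have mean ~0 and SD ~1/sqrt(n-1) (Fisher)."""
        rng = np.random.default_rng(6)
        n = 24
        X = null_stack(rng, n=n, v=2000)
        seed = rng.standard_normal(2 * n)
        R = hp.build_seed_matrix(X, seed)
        assert abs(R.mean()) < 0.01
        assert R.std() == pytest.approx(1 / np.sqrt(n - 1), rel=0.1)

    def test_zero_variance_voxel_masked(self, caplog):
        X = make_stack(np.tile([[1.0, 3.0], [2.0, 4.0]], (4, 1)))
        X.X[:, 1] = 5.0  # constant voxel
        seed = np.arange(8.0)
        with caplog.at_level("WARNING"):
            R = hp.build_seed_matrix(X, seed)
        assert np.all(R[:, 1] == 0.0)
        assert "zero-variance" in caplog.text

    def test_too_few_subjects_rejected(self):
        X = make_stack(np.random.default_rng(7).standard_normal((4, 5)))
        with pytest.raises(ValueError, match="three subjects"):
            hp.build_seed_matrix(X, np.arange(4.0))


class TestPermutation:
    def test_identity_relabelling_reproduces_observed(self):
        rng = np.random.default_rng(8)
        X = null_stack(rng, n=6, v=40)
        rows = X.rows_by_subject()
        _, s_obs, _ = hp.pls_svd(_build(X, None, None))
        _, s_id, _ = hp.pls_svd(_build(X, rows, None))
        np.testing.assert_allclose(s_id, s_obs, atol=1e-12)

    def test_best_case_p_is_one_over_nperm_plus_one(self):
        """A dominant planted effect is never exceeded: p = 1/201 at 200 perms."""
        rng = np.random.default_rng(9)
        n, v = 24, 100
        mu = np.zeros(v)
        mu[:20] = 5.0  # overwhelming condition effect
        rows = []
        for s in range(n):
            rows.append(mu + 0.1 * rng.standard_normal(v))
            rows.append(0.1 * rng.standard_normal(v))
        X = make_stack(np.array(rows))
        p = hp.permute_significance(X, n_perm=200, rng=rng)
        assert p[0] == pytest.approx(1.0 / 201.0)

    def test_single_subject_degenerates_to_p_one(self):
        rng = np.random.default_rng(10)
        X = StackedBrainMatrix(
            X=rng.standard_normal((2, 30)),
            conditions=np.array(["AM", "MA"]),
            subjects=np.array([0, 0]),
        )
        with pytest.warns(UserWarning, match="distinct"):
            p = hp.permute_significance(X, n_perm=50, rng=rng)
        assert p[0] == pytest.approx(1.0)

    def test_null_pvalues_approximately_uniform(self):
        """Kolmogorov-Smirnov check of the permutation null, seeded."""
        from scipy import stats

        rng = np.random.default_rng(11)
        ps = []
        for _ in range(150):
            X = null_stack(rng, n=8, v=50)
            ps.append(hp.permute_significance(X, n_perm=99, rng=rng)[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.001


class TestBootstrap:
    def test_bsr_arithmetic(self):
        boots = np.array([[[0.4], [0.1]], [[0.5], [0.2]], [[0.6], [0.3]]])  # sd=0.1
        bsr = hp.compute_bsr(np.array([[0.5], [1.0]]), boots)
        assert bsr[0, 0] == pytest.approx(5.0)
        assert bsr[1, 0] == pytest.approx(10.0)

    def test_zero_bootstrap_se_masked(self):
        boots = np.ones((5, 3, 1))
        bsr = hp.compute_bsr(np.full((3, 1), 0.7), boots)
        assert np.isnan(bsr).all()

    def test_exact_repeat_resample_leaves_saliences_unchanged(self, monkeypatch):
        """If every bootstrap draw repeats the original cohort, Procrustes
        alignment is the identity and the bootstrap SD collapses to zero."""
        rng = np.random.default_rng(12)
        X = null_stack(rng, n=6, v=25)

        class FixedRng:
            def integers(self, low, high, size):
                return np.arange(size)

            def permutation(self, n):  # pragma: no cover
                return np.arange(n)

        res = hp.bootstrap_bsr(X, n_boot=5, rng=np.random.default_rng(0))
        fixed = hp.bootstrap_bsr(X, n_boot=5, rng=FixedRng())
        np.testing.assert_allclose(fixed.boot_sd, 0.0, atol=1e-12)
        assert np.isnan(fixed.bsr).all()
        np.testing.assert_allclose(fixed.saliences, res.saliences, atol=1e-12)

    def test_duplicate_subject_resamples_handled(self):
        rng = np.random.default_rng(13)
        X = null_stack(rng, n=3, v=15)
        out = hp.bootstrap_bsr(X, n_boot=25, rng=rng)
        assert out.bsr.shape == (15, 2)

    def test_strong_planted_effect_reliably_exceeds_threshold(self):
        """Mean-centered BSR: planted voxels |BSR|>3 in >=90%, nulls <=5%."""
        rng = np.random.default_rng(14)
        n, v, k = 24, 500, 50
        mu = np.zeros(v)
        mu[:k] = 0.5
        rows = []
        for _ in range(n):
            rows.append(mu + 0.25 * rng.standard_normal(v))
            rows.append(0.25 * rng.standard_normal(v))
        X = make_stack(np.array(rows))
        out = hp.bootstrap_bsr(X, n_boot=100, rng=rng)
        bsr1 = out.bsr[:, 0]
        assert np.mean(np.abs(bsr1[:k]) > 3) >= 0.90
        assert np.mean(np.abs(bsr1[k:]) > 3) <= 0.05


class TestClusters:
    @staticmethod
    def _map_with_blob(shape, blobs):
        vol = np.zeros(shape)
        for sl, val in blobs:
            vol[sl] = val
        mask_flat = np.arange(int(np.prod(shape)))
        return vol.reshape(-1), mask_flat

    def test_minimum_size_boundary(self):
        shape = (10, 10, 10)
        bsr, mask = self._map_with_blob(shape, [((slice(0, 7), slice(0, 7), slice(0, 1)), 4.0)])
        table49 = hp.cluster_bsr(bsr, mask, shape, threshold=3, min_size=50)
        assert len(table49) == 0  # 49 voxels: excluded
        bsr, mask = self._map_with_blob(shape, [((slice(0, 5), slice(0, 5), slice(0, 2)), 4.0)])
        table50 = hp.cluster_bsr(bsr, mask, shape, threshold=3, min_size=50)
        assert len(table50) == 1
        assert table50["n_voxels"].iloc[0] == 50

    def test_subthreshold_plane_separates_clusters(self):
        shape = (9, 4, 4)
        blobs = [
            ((slice(0, 4), slice(None), slice(None)), 5.0),
            ((slice(5, 9), slice(None), slice(None)), 5.0),
        ]
        bsr, mask = self._map_with_blob(shape, blobs)
        table = hp.cluster_bsr(bsr, mask, shape, threshold=3, min_size=10)
        assert len(table) == 2

    def test_signs_clustered_separately_and_peak_reported(self):
        shape = (8, 8, 2)
        vol = np.zeros(shape)
        vol[:4] = 4.0
        vol[1, 1, 0] = 6.5
        vol[4:] = -4.0
        table = hp.cluster_bsr(vol.reshape(-1), np.arange(vol.size), shape,
                               threshold=3, min_size=10)
        assert sorted(table["sign"]) == [-1, 1]
        pos = table[table.sign == 1].iloc[0]
        assert pos["peak_bsr"] == pytest.approx(6.5)
        assert (pos["peak_x"], pos["peak_y"], pos["peak_z"]) == (1, 1, 0)

    def test_empty_map_gives_empty_table(self):
        table = hp.cluster_bsr(np.zeros(27), np.arange(27), (3, 3, 3))
        assert table.empty


class TestFitPls:
    def test_model_assembly_and_brain_scores(self):
        rng = np.random.default_rng(15)
        X = null_stack(rng, n=8, v=60)
        model = hp.fit_pls(X, n_perm=50, n_boot=10, rng=rng)
        assert model.method == "mean_centered"
        assert model.singular_values.shape == (2,)
        assert model.brain_scores.shape == (16, 2)
        assert np.all((model.perm_p >= 0) & (model.perm_p <= 1))
        np.testing.assert_allclose(
            np.linalg.norm(model.design_saliences, axis=0), 1.0, atol=1e-10
        )
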
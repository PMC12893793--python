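"""dDR basis construction and cross-validated discriminability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

import popax
from popax.ddr import _pooled_cov, scaled_split
from popax.errors import (
    DegenerateBasisError,
    InsufficientDataError,
    ParameterError,
    ShapeError,
)


def _cloud(mean, cov, n, seed):
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(mean, cov, size=n).T  # cells x trials


class TestComputeDU:
    def test_direct_subtraction(self):
        a = np.array([[1.0, 1.0], [2.0, 2.0]])
        b = np.array([[3.0, 3.0], [2.0, 2.0]])
        np.testing.assert_array_equal(popax.compute_dU(a, b), [2.0, 0.0])

    def test_identical_conditions_zero_vector(self):
        a = np.random.default_rng(0).normal(size=(5, 10))
        np.testing.assert_array_equal(popax.compute_dU(a, a), np.zeros(5))

    def test_single_cell(self):
        assert popax.compute_dU(np.zeros((1, 3)), np.ones((1, 3))) == pytest.approx([1.0])

    def test_mismatched_cells_rejected(self):
        with pytest.raises(ShapeError):
            popax.compute_dU(np.zeros((3, 4)), np.zeros((2, 4)))


class TestNoiseMatrix:
    def test_zero_mean_input_passes_through(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(4, 10))
        a -= a.mean(axis=1, keepdims=True)
        b = rng.normal(size=(4, 8))
        b -= b.mean(axis=1, keepdims=True)
        noise = popax.build_noise_matrix(a, b)
        np.testing.assert_allclose(noise, np.concatenate([a, b], axis=1), atol=1e-12)

    def test_block_row_means_zero_and_size(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(1, 1, (6, 40)), rng.normal(3, 1, (6, 40))
        noise = popax.build_noise_matrix(a, b)
        assert noise.shape == (6, 80)  # N_cells x 2*N_trials
        np.testing.assert_allclose(noise[:, :40].mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(noise[:, 40:].mean(axis=1), 0, atol=1e-12)

    def test_single_trial_rejected(self):
        with pytest.raises(InsufficientDataError):
            popax.build_noise_matrix(np.zeros((3, 1)), np.zeros((3, 5)))


class TestFitBasis:
    def test_orthogonal_e1_passes_through(self):
        # signal along cell 1, noise along cell 2: n1 == e1
        rng = np.random.default_rng(3)
        n = 200
        a = np.vstack([np.zeros(n), rng.normal(0, 1, n)])
        b = np.vstack([np.full(n, 5.0), rng.normal(0, 1, n)])
        basis = popax.fit_basis(a, b)
        np.testing.assert_allclose(np.abs(basis.n1), [0, 1], atol=0.05)
        np.testing.assert_allclose(basis.n1, basis.e1, atol=0.05)

    def test_gram_schmidt_hand_case(self):
        # dU = (1, 0); noise equally loads both cells -> e1 ~ (1,1)/sqrt(2)
        rng = np.random.default_rng(4)
        n = 2000
        shared = rng.normal(0, 1, n)
        eps = 0.01 * rng.standard_normal((2, n))
        a = np.vstack([shared, shared]) + eps
        b = a + np.array([[1.0], [0.0]]) + 0.01 * rng.standard_normal((2, n))
        basis = popax.fit_basis(a, b)
        assert abs(basis.dU_unit @ np.array([1.0, 0.0])) > 0.999
        np.testing.assert_allclose(np.abs(basis.n1), [0.0, 1.0], atol=0.05)

    def test_rank_one_noise_recovered(self):
        # eigen-decomposition oracle: loading vector of rank-1 + diagonal noise
        rng = np.random.default_rng(5)
        n_cells, n = 40, 400
        loading = rng.normal(0, 1, n_cells)
        loading /= np.linalg.norm(loading)
        shared = rng.normal(0, 2.0, n)
        a = loading[:, None] * shared[None, :] + 0.05 * rng.standard_normal((n_cells, n))
        b = (a[:, ::-1] + rng.normal(0.5, 0.05, n_cells)[:, None])
        basis = popax.fit_basis(a, b)
        assert abs(basis.e1 @ loading) > 0.99

    def test_zero_dU_degenerate(self):
        a = np.random.default_rng(0).normal(size=(4, 10))
        with pytest.raises(DegenerateBasisError):
            popax.fit_basis(a, a.copy())

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        n_cells=st.integers(2, 15),
        n_trials=st.integers(3, 12),
        seed=st.integers(0, 10_000),
    )
    def test_orthonormality_property(self, n_cells, n_trials, seed):
        """Every fitted basis is orthonormal within 1e-10."""
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, (n_cells, n_trials))
        b = rng.normal(0.5, 1.0, (n_cells, n_trials))
        basis = popax.fit_basis(a, b)
        assert abs(np.linalg.norm(basis.dU_unit) - 1) < 1e-10
        assert abs(np.linalg.norm(basis.n1) - 1) < 1e-10
        assert abs(basis.dU_unit @ basis.n1) < 1e-10


class TestProject:
    def test_basis_vectors_project_to_unit_axes(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, (5, 20)), rng.normal(1, 1, (5, 20))
        basis = popax.fit_basis(a, b)
        np.testing.assert_allclose(
            popax.project(basis.dU_unit[:, None], basis).ravel(), [1.0, 0.0], atol=1e-12
        )
        np.testing.assert_allclose(
            popax.project(basis.n1[:, None], basis).ravel(), [0.0, 1.0], atol=1e-12
        )

    def test_orthogonal_trial_maps_to_origin(self):
        basis = popax.DecodingBasis(
            dU_raw=np.array([2.0, 0, 0]),
            dU_unit=np.array([1.0, 0, 0]),
            e1=np.array([0.0, 1, 0]),
            n1=np.array([0.0, 1, 0]),
        )
        out = popax.project(np.array([[0.0], [0.0], [3.0]]), basis)
        np.testing.assert_array_equal(out.ravel(), [0.0, 0.0])

    def test_in_plane_distances_preserved(self):
        # brute-force dot-product oracle
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, (6, 30)), rng.normal(1, 1, (6, 30))
        basis = popax.fit_basis(a, b)
        proj = popax.project(a, basis)
        B = np.vstack([basis.dU_unit, basis.n1])
        in_plane = B.T @ (B @ a)  # component of each trial inside the plane
        for i in range(5):
            for j in range(i + 1, 5):
                d_full = np.linalg.norm(in_plane[:, i] - in_plane[:, j])
                d_proj = np.linalg.norm(proj[:, i] - proj[:, j])
                assert d_proj == pytest.approx(d_full, abs=1e-10)


class TestDprime2d:
    def test_unit_variance_separation(self):
        pa = np.array([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]])  # mean (0,0)
        pb = pa + np.array([[2.0], [0.0]])
        d = popax.dprime_2d(pa, pb, sigma=np.eye(2))
        assert d == pytest.approx(2.0)

    def test_identical_clouds_zero(self):
        pa = np.random.default_rng(0).normal(size=(2, 50))
        assert popax.dprime_2d(pa, pa.copy()) == 0.0

    def test_closed_form_mahalanobis(self):
        pa = np.array([[1.0, -1.0], [2.0, -2.0]])  # mean (0, 0)
        pb = pa + 1.0  # ΔU = (1, 1)
        d = popax.dprime_2d(pa, pb, sigma=np.diag([1.0, 4.0]))
        assert d == pytest.approx(np.sqrt(1.25))

    def test_pooled_covariance_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        pa, pb = rng.normal(0, 1, (2, 30)), rng.normal(1, 2, (2, 25))
        # independent oracle: explicit pooled covariance and quadratic form
        ca = pa - pa.mean(axis=1, keepdims=True)
        cb = pb - pb.mean(axis=1, keepdims=True)
        sigma = (ca @ ca.T + cb @ cb.T) / (30 + 25 - 2)
        du = pb.mean(axis=1) - pa.mean(axis=1)
        expected = np.sqrt(du @ np.linalg.inv(sigma) @ du)
        assert popax.dprime_2d(pa, pb) == pytest.approx(expected, abs=1e-10)

    def test_raw_quadratic_variant(self):
        pa = np.array([[1.0, -1.0], [2.0, -2.0]])
        pb = pa + 1.0
        d = popax.dprime_2d(pa, pb, method="raw_quadratic", sigma=np.diag([1.0, 4.0]))
        assert d == pytest.approx(5.0)  # (1,1) diag(1,4) (1,1)^T


class TestCvDprime:
    def test_deterministic_given_seed(self, gaussian_pair):
        a, b = gaussian_pair
        r1 = popax.cv_dprime(a, b, n_train=40, n_iterations=10, seed=42)
        r2 = popax.cv_dprime(a, b, n_train=40, n_iterations=10, seed=42)
        np.testing.assert_array_equal(r1.per_iteration_dprime, r2.per_iteration_dprime)
        assert r1.mean_dprime == pytest.approx(
            r1.per_iteration_dprime.mean()
        )
        assert (r1.per_iteration_dprime >= 0).all()

    def test_isotropic_recovery(self):
        # closed form: d' = ||ΔU|| / sigma for isotropic noise
        rng = np.random.default_rng(9)
        n_cells, s = 2, 3.0
        du = rng.normal(0, 1, n_cells)
        du *= s / np.linalg.norm(du)
        a = rng.standard_normal((n_cells, 1000))
        b = du[:, None] + rng.standard_normal((n_cells, 1000))
        res = popax.cv_dprime(a, b, n_train=500, n_iterations=20, seed=1)
        assert res.mean_dprime == pytest.approx(s, rel=0.10)

    def test_null_far_below_true_separation(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal((2, 50))
        b = rng.standard_normal((2, 50))
        null = popax.cv_dprime(a, b, n_train=40, n_iterations=20, seed=2).mean_dprime
        strong_b = np.array([3.0, 0.0])[:, None] + rng.standard_normal((2, 50))
        strong = popax.cv_dprime(a, strong_b, n_train=40, n_iterations=20, seed=2).mean_dprime
        assert null < 0.2 * strong

    def test_insufficient_trials_rejected(self):
        a = np.random.default_rng(0).normal(size=(3, 20))
        with pytest.raises(ParameterError):
            popax.cv_dprime(a, a, n_train=40)

    def test_permutation_and_scale_invariance(self, gaussian_pair):
        a, b = gaussian_pair
        base = popax.cv_dprime(a, b, n_train=40, n_iterations=10, seed=5)
        perm = np.random.default_rng(11).permutation(a.shape[0])
        permuted = popax.cv_dprime(a[perm], b[perm], n_train=40, n_iterations=10, seed=5)
        scaled = popax.cv_dprime(2.0 * a, 2.0 * b, n_train=40, n_iterations=10, seed=5)
        np.testing.assert_allclose(
            permuted.per_iteration_dprime, base.per_iteration_dprime, rtol=1e-9
        )
        np.testing.assert_array_equal(
            scaled.per_iteration_dprime, base.per_iteration_dprime
        )

    def test_two_cell_projection_lossless(self):
        """With 2 cells the dDR plane is the full space, so the projected d'
        equals the direct full-dimensional Mahalanobis d'."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            a = rng.normal(0, 1, (2, 40))
            b = rng.normal(0.8, 1.3, (2, 40))
            basis = popax.fit_basis(a, b)
            d_proj = popax.dprime_2d(popax.project(a, basis), popax.project(b, basis))
            du = b.mean(axis=1) - a.mean(axis=1)
            sigma = _pooled_cov(a, b)
            d_full = np.sqrt(du @ np.linalg.solve(sigma, du))
            assert d_proj == pytest.approx(d_full, abs=1e-8)

    def test_monotone_in_true_separation(self):
        rng = np.random.default_rng(13)
        means = []
        for s in (0.0, 1.0, 2.0, 3.0):
            vals = []
            for seed in range(10):
                a = rng.standard_normal((2, 60))
                b = np.array([s, 0.0])[:, None] + rng.standard_normal((2, 60))
                vals.append(
                    popax.cv_dprime(a, b, n_train=40, n_iterations=10, seed=seed).mean_dprime
                )
            means.append(np.mean(vals))
        assert means == sorted(means)


class TestMovieDprime:
    @staticmethod
    def _binned(offset, n_repeats=30, n_cells=20, n_bins=6, seed=0):
        rng = np.random.default_rng(seed)
        data = {}
        for b in range(n_bins):
            base = rng.uniform(0.2, 1.0, n_cells)
            for lum, delta in (("scotopic", 0.0), ("photopic", offset)):
                arr = (base + delta)[:, None] + 0.3 * rng.standard_normal(
                    (n_cells, n_repeats)
                )
                data[popax.Condition(movie_id="m", movie_bin=b, luminance=lum)] = arr
        return popax.ResponseMatrix(data)

    def test_planted_offset_beats_shuffled_null(self):
        binned = self._binned(offset=1.0)
        observed = popax.movie_luminance_dprime(binned, n_iterations=20, seed=1)
        nulls = []
        for b in range(4):
            cond = lambda lum: popax.Condition(movie_id="m", movie_bin=b, luminance=lum)
            nulls.append(
                popax.shuffled_null_dprime(
                    binned[cond("scotopic")], binned[cond("photopic")],
                    n_shuffles=50, seed=b, n_train=24, n_iterations=10,
                )
            )
        threshold = np.percentile(np.concatenate(nulls), 99)
        assert (observed["dprime"] > threshold).all()

    def test_shuffled_labels_at_null_level(self):
        binned = self._binned(offset=0.0, seed=3)
        observed = popax.movie_luminance_dprime(binned, n_iterations=20, seed=2)
        cond = lambda b, lum: popax.Condition(movie_id="m", movie_bin=b, luminance=lum)
        null = popax.shuffled_null_dprime(
            binned[cond(0, "scotopic")], binned[cond(0, "photopic")],
            n_shuffles=100, seed=0, n_train=24, n_iterations=10,
        )
        assert observed["dprime"].mean() < np.percentile(null, 99)

    def test_too_few_repeats_skipped(self):
        binned = self._binned(offset=1.0, n_repeats=2)
        with pytest.warns(UserWarning, match="skipped"):
            out = popax.movie_luminance_dprime(binned, min_repeats=4)
        assert out.empty


class TestSklearnEstimators:
    def test_ddr_basis_transformer(self, gaussian_pair):
        a, b = gaussian_pair
        X = np.concatenate([a.T, b.T])
        y = np.array([0] * a.shape[1] + [1] * b.shape[1])
        est = popax.DDRBasis().fit(X, y)
        assert est.dU_unit_ @ est.n1_ == pytest.approx(0.0, abs=1e-10)
        proj = est.transform(X)
        assert proj.shape == (X.shape[0], 2)
        # matches the functional path
        basis = popax.fit_basis(a, b)
        np.testing.assert_allclose(proj.T, popax.project(np.vstack([a.T, b.T]).T, basis))

    def test_dprime_decoder_params_and_clone(self, gaussian_pair):
        a, b = gaussian_pair
        X = np.concatenate([a.T, b.T])
        y = np.array(["scot"] * a.shape[1] + ["phot"] * b.shape[1])
        dec = popax.DPrimeDecoder(n_train=40, n_iterations=10, random_state=3)
        assert clone(dec).get_params()["n_train"] == 40
        dec.fit(X, y)
        ref = popax.cv_dprime(
            X[y == "phot"].T, X[y == "scot"].T, n_train=40, n_iterations=10, seed=3
        )
        assert dec.mean_dprime_ == pytest.approx(ref.mean_dprime)

    def test_split_scaling_keeps_two_test_trials(self):
        assert scaled_split(50) == 40
        assert scaled_split(10) == 8
        assert scaled_split(4) == 2
        assert scaled_split(5) == 3
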
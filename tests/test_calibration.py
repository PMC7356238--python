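"""Checker calibration fit and per-pixel spectral reconstruction."""

import numpy as np
import pytest

from hsoi import colorimetry as cm
from hsoi.calibration import (
    CalibrationError,
    CalibrationModel,
    calibrate,
    correct_rgb,
    fit_basis,
    fit_color_correction,
    fit_transformation,
    image_to_cube,
    polynomial_expand,
    reconstruct_spectrum,
    spectral_coefficients,
)
from hsoi.phantom import simulate_capture


class TestBasis:
    def test_rows_orthonormal_and_ordered(self, checker_rank6):
        e = fit_basis(checker_rank6)
        np.testing.assert_allclose(e @ e.T, np.eye(6), atol=1e-10)

    def test_rank_one_input_gives_first_eigenvector_along_spectrum(self):
        s = np.linspace(0.1, 0.9, 401)
        d = np.tile(s[:, None], (1, 24))
        with pytest.raises(CalibrationError, match="rank 1"):
            fit_basis(d)  # six components cannot be extracted
        e = fit_basis(d, n_basis=1)
        cos = abs(e[0] @ s) / np.linalg.norm(s)
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_matches_full_eigendecomposition_oracle(self, checker_rank6):
        e = fit_basis(checker_rank6)
        # oracle: eigenvectors of the uncentered second-moment matrix D D^T
        evals, evecs = np.linalg.eigh(checker_rank6 @ checker_rank6.T)
        top = evecs[:, np.argsort(evals)[::-1][:6]].T
        explained_fit = np.sum((e @ checker_rank6) ** 2)
        explained_oracle = np.sum((top @ checker_rank6) ** 2)
        assert explained_fit == pytest.approx(explained_oracle, rel=1e-10)

    def test_sign_convention_largest_loading_positive(self, checker_rank6):
        e = fit_basis(checker_rank6)
        for row in e:
            assert row[np.argmax(np.abs(row))] > 0


class TestCoefficients:
    def test_basis_columns_give_identity_block(self, checker_rank6):
        e = fit_basis(checker_rank6)
        alpha = spectral_coefficients(e.T, e)  # columns are the basis rows
        np.testing.assert_allclose(alpha, np.eye(6), atol=1e-8)

    def test_zero_spectrum_gives_zero_coefficients(self, checker_rank6):
        e = fit_basis(checker_rank6)
        d = np.zeros((401, 3))
        np.testing.assert_allclose(spectral_coefficients(d, e), 0.0)

    def test_reproduces_orthogonal_projection(self, checker_rank6, rng):
        e = fit_basis(checker_rank6)
        d = rng.uniform(0, 1, (401, 10))
        alpha = spectral_coefficients(d, e)
        # normal-equations oracle for the projection onto span(E)
        proj = e.T @ np.linalg.solve(e @ e.T, e @ d)
        np.testing.assert_allclose(e.T @ alpha, proj, atol=1e-8)


class TestPolynomialExpand:
    def test_zero_gives_unit_bias_only(self):
        f = polynomial_expand([0.0, 0.0, 0.0])
        assert f[0] == 1.0 and np.all(f[1:] == 0.0)

    def test_ones_give_all_ones(self):
        np.testing.assert_array_equal(polynomial_expand([1.0, 1.0, 1.0]), 1.0)

    def test_pure_red_powers(self):
        f = polynomial_expand([2.0, 0.0, 0.0])
        expected = np.zeros(20)
        expected[[0, 1, 7, 11]] = [1.0, 2.0, 4.0, 8.0]  # 1, R, R^2, R^3
        np.testing.assert_array_equal(f, expected)

    def test_order_matches_monomial_list(self, rng):
        r, g, b = rng.uniform(0.1, 0.9, 3)
        expected = [
            1, r, g, b, r * g, g * b, b * r, r**2, g**2, b**2, r * g * b,
            r**3, g**3, b**3, r * g**2, r * b**2, g * r**2, g * b**2,
            b * r**2, b * g**2,
        ]
        np.testing.assert_allclose(polynomial_expand([r, g, b]), expected, rtol=1e-12)


class TestColorCorrection:
    def test_zero_target_gives_zero_matrix(self, rng):
        f = polynomial_expand(rng.uniform(0, 1, (24, 3))).T
        np.testing.assert_allclose(fit_color_correction(np.zeros((3, 24)), f), 0.0)

    def test_recovers_constructed_matrix(self, rng):
        f = polynomial_expand(rng.uniform(0, 1, (24, 3))).T
        c0 = rng.normal(0, 1, (3, 20))
        c = fit_color_correction(c0 @ f, f)
        np.testing.assert_allclose(c @ f, c0 @ f, atol=1e-8)

    def test_least_squares_optimality(self, rng):
        f = polynomial_expand(rng.uniform(0, 1, (24, 3))).T
        a = rng.uniform(0, 1, (3, 24))
        c = fit_color_correction(a, f)
        base = np.linalg.norm(a - c @ f)
        for _ in range(100):
            perturbed = c + rng.normal(0, 1e-3, c.shape)
            assert np.linalg.norm(a - perturbed @ f) >= base - 1e-12

    def test_correct_rgb_identity_and_zero(self, rng):
        identity_c = np.zeros((3, 20))
        identity_c[:, 1:4] = np.eye(3)
        rgb = rng.uniform(0, 1, 3)
        np.testing.assert_allclose(correct_rgb(identity_c, rgb), rgb, atol=1e-12)
        np.testing.assert_allclose(correct_rgb(np.zeros((3, 20)), rgb), 0.0)

    def test_correct_rgb_matches_hand_product(self, rng):
        c = rng.uniform(0, 0.05, (3, 20))
        rgb = rng.uniform(0, 1, 3)
        np.testing.assert_allclose(
            correct_rgb(c, rgb), np.clip(c @ polynomial_expand(rgb), 0, 1), atol=1e-12
        )


class TestTransformation:
    def test_recovers_constructed_matrix(self, rng):
        beta = rng.uniform(1, 90, (3, 24))
        m0 = rng.normal(0, 1, (6, 3))
        m = fit_transformation(m0 @ beta, beta)
        np.testing.assert_allclose(m, m0, atol=1e-8)

    def test_zero_alpha_gives_zero(self, rng):
        beta = rng.uniform(1, 90, (3, 24))
        np.testing.assert_allclose(fit_transformation(np.zeros((6, 24)), beta), 0.0)

    def test_rank_deficient_beta_rejected(self):
        beta = np.ones((3, 24))
        with pytest.raises(CalibrationError, match="rank"):
            fit_transformation(np.zeros((6, 24)), beta)

    def test_least_squares_optimality(self, rng):
        beta = rng.uniform(1, 90, (3, 24))
        alpha = rng.normal(0, 1, (6, 24))
        m = fit_transformation(alpha, beta)
        base = np.linalg.norm(alpha - m @ beta)
        for _ in range(100):
            perturbed = m + rng.normal(0, 1e-4, m.shape)
            assert np.linalg.norm(alpha - perturbed @ beta) >= base - 1e-12


def _closed_loop_rmse(d, ill, cmf, n_basis, noise_sigma=0.0, seed=0):
    rgb = simulate_capture(d, ill, noise_sigma, seed, cmf)
    model = calibrate(d, rgb, ill, cmf, n_basis=n_basis)
    rec = reconstruct_spectrum(model, model.regressor_from_rgb(rgb))
    return float(np.sqrt(np.mean((rec - d.T) ** 2))), model, rgb


class TestCalibratePipeline:
    def test_closed_loop_exact_for_rank3_spectra(self, checker_rank3, d65, cmf):
        """Three spectral degrees of freedom survive the XYZ bottleneck exactly."""
        rmse, _, _ = _closed_loop_rmse(checker_rank3, d65, cmf, n_basis=3)
        assert rmse < 1e-9

    def test_rank6_reconstruction_bounded_by_spectral_bottleneck(
        self, checker_rank6, d65, cmf
    ):
        """Rank-6 spectra reconstruct approximately (metamerism residual)."""
        rmse, _, _ = _closed_loop_rmse(checker_rank6, d65, cmf, n_basis=6)
        assert 1e-4 < rmse < 0.05

    def test_noise_degrades_rank3_loop_monotonically(self, checker_rank3, d65, cmf):
        means = []
        for sigma in (0.0, 0.002, 0.01):
            r = [
                _closed_loop_rmse(checker_rank3, d65, cmf, 3, sigma, seed)[0]
                for seed in range(10)
            ]
            means.append(np.mean(r))
        assert means[0] < means[1] < means[2]

    def test_checker_permutation_leaves_new_pixel_reconstruction_unchanged(
        self, checker_rank6, d65, cmf, rng
    ):
        rgb = simulate_capture(checker_rank6, d65, 0.0, 0, cmf)
        perm = rng.permutation(24)
        m1 = calibrate(checker_rank6, rgb, d65, cmf)
        m2 = calibrate(checker_rank6[:, perm], rgb[perm], d65, cmf)
        probe = rng.uniform(0.2, 0.8, (5, 3))
        r1 = reconstruct_spectrum(m1, m1.regressor_from_rgb(probe))
        r2 = reconstruct_spectrum(m2, m2.regressor_from_rgb(probe))
        np.testing.assert_allclose(r1, r2, atol=1e-6)

    def test_pinv_fits_match_normal_equations(self, checker_rank6, rng):
        e = fit_basis(checker_rank6)
        alpha = spectral_coefficients(checker_rank6, e)
        oracle = np.linalg.solve(e @ e.T, e @ checker_rank6)
        np.testing.assert_allclose(alpha, oracle, atol=1e-8)

    def test_model_json_round_trip_reproduces_reconstructions(
        self, checker_rank6, d65, cmf, tmp_path, rng
    ):
        _, model, rgb = _closed_loop_rmse(checker_rank6, d65, cmf, 6)
        path = tmp_path / "model.json"
        model.save(path)
        reloaded = CalibrationModel.load(path)
        np.testing.assert_array_equal(reloaded.basis, model.basis)
        probe = rng.uniform(0, 1, (7, 3))
        np.testing.assert_array_equal(
            reconstruct_spectrum(reloaded, reloaded.regressor_from_rgb(probe)),
            reconstruct_spectrum(model, model.regressor_from_rgb(probe)),
        )


class TestImageToCube:
    def test_single_pixel_matches_direct_reconstruction(self, checker_rank6, d65, cmf):
        _, model, _ = _closed_loop_rmse(checker_rank6, d65, cmf, 6)
        img = np.array([[[120, 80, 60]]], dtype=np.uint8)
        cube = image_to_cube(img, model)
        direct = reconstruct_spectrum(
            model, model.regressor_from_rgb(np.array([120, 80, 60]) / 255.0)
        )
        np.testing.assert_allclose(cube[0, 0], direct, atol=1e-5)

    def test_constant_image_gives_constant_cube(self, checker_rank6, d65, cmf):
        _, model, _ = _closed_loop_rmse(checker_rank6, d65, cmf, 6)
        img = np.full((4, 5, 3), 100, dtype=np.uint8)
        cube = image_to_cube(img, model)
        assert cube.shape == (4, 5, 401)
        np.testing.assert_allclose(
            cube, np.broadcast_to(cube[0, 0], cube.shape), atol=1e-6
        )

    def test_rank3_phantom_pixels_reconstruct_closely(self, checker_rank3, d65, cmf):
        _, model, _ = _closed_loop_rmse(checker_rank3, d65, cmf, 3)
        # render pixels whose spectra lie in the checker subspace
        mix = checker_rank3[:, :4] @ np.array(
            [[0.5, 0.2], [0.2, 0.5], [0.2, 0.1], [0.1, 0.2]]
        )
        rgb = simulate_capture(mix, d65, 0.0, 0, cmf)
        img = np.round(rgb.reshape(1, 2, 3) * 255).astype(np.uint8)
        cube = image_to_cube(img, model)
        rmse = np.sqrt(np.mean((cube.reshape(2, 401) - mix.T) ** 2))
        assert rmse < 5e-3  # 8-bit quantization dominates

    def test_non_rgb_input_rejected(self, checker_rank6, d65, cmf):
        _, model, _ = _closed_loop_rmse(checker_rank6, d65, cmf, 6)
        with pytest.raises(ValueError):
            image_to_cube(np.zeros((4, 4)), model)
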
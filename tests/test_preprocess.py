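"""Preprocessing chain: truncation, SG derivative, MSC, normalization, scaling."""

import numpy as np
import pandas as pd
import pytest

from serofir.dataset import SpectralDataset
from serofir.preprocess import (
    MultiplicativeScatterCorrection, PreprocessError, PreprocessParams,
    SpectrumScaler, apply_scaler, fit_scaler, msc, preprocess_pipeline,
    sg_second_derivative, truncate, vector_normalize,
)
from serofir.simulate import SimConfig, generate_dataset


def make_dataset(grid, rows):
    rows = np.atleast_2d(rows)
    meta = pd.DataFrame({
        "spectrum_id": [f"s{i}" for i in range(rows.shape[0])],
        "subject_id": [f"u{i}" for i in range(rows.shape[0])],
        "group": "g", "batch": "b0", "replicate": 0,
    })
    return SpectralDataset(grid, rows, meta)


class TestTruncate:
    def test_fingerprint_window_point_count(self):
        """Brute-force count of default-grid points in the closed window."""
        cfg = SimConfig()
        grid = cfg.grid()
        expected = int(np.sum((grid >= 900.0) & (grid <= 1800.0)))
        ds = make_dataset(grid, np.zeros((1, grid.size)))
        out = truncate(ds, 900.0, 1800.0)
        assert out.n_points == expected == 601

    def test_full_span_is_identity(self):
        grid = np.arange(100.0, 200.0, 2.0)
        ds = make_dataset(grid, np.random.default_rng(0).random((2, grid.size)))
        out = truncate(ds, grid[0], grid[-1])
        np.testing.assert_array_equal(out.intensities, ds.intensities)

    def test_reversed_window_rejected(self):
        grid = np.arange(100.0, 200.0, 2.0)
        ds = make_dataset(grid, np.zeros((1, grid.size)))
        with pytest.raises(PreprocessError, match="reversed"):
            truncate(ds, 1800.0, 900.0)

    def test_disjoint_window_rejected(self):
        grid = np.arange(100.0, 200.0, 2.0)
        ds = make_dataset(grid, np.zeros((1, grid.size)))
        with pytest.raises(PreprocessError, match="intersect"):
            truncate(ds, 900.0, 1800.0)


class TestSavitzkyGolay:
    def test_polynomial_annihilation_and_exactness(self):
        grid = np.arange(900.0, 1800.0, 1.5)
        linear = 0.3 * grid + 2.0
        quadratic = grid ** 2
        ds = make_dataset(grid, np.vstack([linear, quadratic]))
        out = sg_second_derivative(ds, 15, 3)
        np.testing.assert_allclose(out.intensities[0], 0.0, atol=1e-8)
        np.testing.assert_allclose(out.intensities[1], 2.0, atol=1e-6)

    def test_gaussian_analytic_oracle(self):
        """SG 15/3 second derivative of a Gaussian matches the analytic one
        within 2 % over +/-2 sigma."""
        grid = np.arange(900.0, 1800.0, 1.5)
        mu, sig = 1350.0, 40.0
        g = np.exp(-0.5 * ((grid - mu) / sig) ** 2)
        analytic = g * (((grid - mu) / sig ** 2) ** 2 - 1.0 / sig ** 2)
        ds = make_dataset(grid, g)
        out = sg_second_derivative(ds, 15, 3)
        core = np.abs(out.wavenumbers - mu) <= 2 * sig
        ana = analytic[np.isin(grid, out.wavenumbers)]
        rel = np.abs(out.intensities[0][core] - ana[core]) / np.abs(ana[core]).max()
        assert rel.max() < 0.02

    def test_linearity(self):
        rng = np.random.default_rng(2)
        grid = np.arange(0.0, 300.0, 1.5)
        x, y = rng.random(grid.size), rng.random(grid.size)
        d = lambda v: sg_second_derivative(make_dataset(grid, v)).intensities[0]
        np.testing.assert_allclose(d(x + y), d(x) + d(y), atol=1e-10)
        np.testing.assert_allclose(d(3.5 * x), 3.5 * d(x), atol=1e-10)

    def test_edges_dropped(self):
        grid = np.arange(0.0, 150.0, 1.5)
        ds = make_dataset(grid, np.zeros((1, grid.size)))
        out = sg_second_derivative(ds, 15, 3)
        assert out.n_points == grid.size - 14
        assert out.wavenumbers[0] == grid[7]

    def test_truncate_commutes_on_interior(self):
        rng = np.random.default_rng(3)
        grid = np.arange(500.0, 2500.0, 1.5)
        x = rng.random(grid.size)
        ds = make_dataset(grid, x)
        before = sg_second_derivative(truncate(ds, 900.0, 1800.0))
        after = truncate(sg_second_derivative(ds), 900.0, 1800.0)
        common = np.intersect1d(before.wavenumbers, after.wavenumbers)
        interior = common[7:-7]
        bi = np.isin(before.wavenumbers, interior)
        ai = np.isin(after.wavenumbers, interior)
        np.testing.assert_allclose(before.intensities[0][bi],
                                   after.intensities[0][ai], atol=1e-10)

    def test_non_uniform_grid_rejected(self):
        grid = np.array([1.0, 2.0, 3.0, 5.0] + list(np.arange(6.0, 30.0)))
        ds = make_dataset(grid, np.zeros((1, grid.size)))
        with pytest.raises(PreprocessError, match="not uniform"):
            sg_second_derivative(ds)


class TestMSC:
    def test_identity_when_equal_to_reference(self):
        grid = np.arange(0.0, 50.0)
        ref = np.sin(grid / 5) + 2
        ds = make_dataset(grid, ref)
        out, coef = msc(ds, reference=ref)
        np.testing.assert_allclose(coef[0], [0.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(out.intensities[0], ref, atol=1e-12)

    def test_closed_form_affine_recovery(self):
        grid = np.arange(0.0, 50.0)
        ref = np.sin(grid / 5) + 2
        ds = make_dataset(grid, 2.0 * ref + 5.0)
        out, coef = msc(ds, reference=ref)
        np.testing.assert_allclose(coef[0], [5.0, 2.0], atol=1e-10)
        np.testing.assert_allclose(out.intensities[0], ref, atol=1e-10)

    def test_normal_equations_oracle(self):
        """(a, b) match an explicit normal-equation solve per spectrum."""
        rng = np.random.default_rng(7)
        grid = np.arange(0.0, 80.0)
        X = rng.random((5, grid.size))
        ds = make_dataset(grid, X)
        _, coef = msc(ds)  # dataset-mean reference
        ref = X.mean(axis=0)
        A = np.column_stack([np.ones_like(ref), ref])
        for i in range(5):
            ab = np.linalg.solve(A.T @ A, A.T @ X[i])
            np.testing.assert_allclose(coef[i], ab, atol=1e-8)

    def test_degenerate_slope_rejected(self):
        grid = np.arange(0.0, 30.0)
        ref = np.sin(grid / 3)
        flat = np.full_like(grid, 0.7) + 1e-15 * grid
        tr = MultiplicativeScatterCorrection(reference=ref).fit(ref[None, :])
        with pytest.raises(PreprocessError, match="degenerate"):
            tr.transform(flat[None, :])


class TestVectorNormalize:
    def test_three_four_five(self):
        grid = np.arange(0.0, 6.0)
        row = np.array([3.0, 4.0, 0.0, 0.0, 0.0, 0.0])
        out = vector_normalize(make_dataset(grid, row))
        np.testing.assert_allclose(out.intensities[0][:2], [0.6, 0.8])

    def test_idempotent_and_scale_invariant(self):
        rng = np.random.default_rng(5)
        grid = np.arange(0.0, 40.0)
        x = rng.random(grid.size)
        once = vector_normalize(make_dataset(grid, x)).intensities[0]
        twice = vector_normalize(make_dataset(grid, once)).intensities[0]
        scaled = vector_normalize(make_dataset(grid, 17.3 * x)).intensities[0]
        np.testing.assert_allclose(once, twice, atol=1e-12)
        np.testing.assert_allclose(once, scaled, atol=1e-12)
        assert np.linalg.norm(once) == pytest.approx(1.0, abs=1e-12)

    def test_zero_norm_rejected(self):
        grid = np.arange(0.0, 5.0)
        with pytest.raises(PreprocessError, match="zero-norm"):
            vector_normalize(make_dataset(grid, np.zeros((1, 5))))


class TestScaler:
    def test_mean_center_and_standardize_postconditions(self):
        rng = np.random.default_rng(9)
        grid = np.arange(0.0, 20.0)
        ds = make_dataset(grid, rng.random((30, grid.size)))
        centered = apply_scaler(fit_scaler(ds, "mean-center"), ds)
        np.testing.assert_allclose(centered.intensities.mean(axis=0), 0, atol=1e-10)
        std = apply_scaler(fit_scaler(ds, "standardize"), ds)
        np.testing.assert_allclose(std.intensities.std(axis=0, ddof=1), 1,
                                   atol=1e-10)

    def test_train_statistics_reused_on_shifted_test_set(self):
        rng = np.random.default_rng(9)
        grid = np.arange(0.0, 20.0)
        train = make_dataset(grid, rng.random((30, grid.size)))
        scaler = fit_scaler(train, "mean-center")
        shift = 0.37
        test = make_dataset(grid, train.intensities[:10] + shift)
        out = apply_scaler(scaler, test)
        col_means = out.intensities.mean(axis=0)
        np.testing.assert_allclose(
            col_means,
            train.intensities[:10].mean(axis=0) + shift - scaler.means_,
            atol=1e-10,
        )

    def test_zero_sd_column_named(self):
        grid = np.arange(0.0, 4.0)
        X = np.ones((5, 4))
        X[:, 1] = np.arange(5)
        with pytest.raises(PreprocessError, match="column"):
            SpectrumScaler(mode="standardize").fit(X)


class TestFullChain:
    def test_replicate_determinism_with_artifacts_off(self, clean_config):
        ds, _ = generate_dataset(clean_config)
        out = preprocess_pipeline(ds, PreprocessParams(scale_mode="none"))
        reps = out.metadata["subject_id"] == out.metadata["subject_id"].iloc[0]
        rows = out.intensities[reps.to_numpy()]
        np.testing.assert_array_equal(rows[0], rows[1])

    def test_bit_identical_across_runs(self, small_config):
        ds, _ = generate_dataset(small_config)
        a = preprocess_pipeline(ds)
        b = preprocess_pipeline(ds)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_affine_distortion_removed(self, clean_config):
        """b*x + a distortion of one spectrum changes its preprocessed row by
        < 1 % RMS (MSC + vector normalization jointly remove scatter)."""
        ds, _ = generate_dataset(clean_config)
        distorted = ds.intensities.copy()
        distorted[0] = 1.3 * distorted[0] + 0.1
        ds2 = ds.with_intensities(distorted)
        params = PreprocessParams(scale_mode="none")
        ref = preprocess_pipeline(ds, params).intensities[0]
        got = preprocess_pipeline(ds2, params).intensities[0]
        rms = np.sqrt(np.mean((got - ref) ** 2)) / np.sqrt(np.mean(ref ** 2))
        assert rms < 0.01

    def test_invalid_params_rejected(self):
        with pytest.raises(PreprocessError):
            PreprocessParams(sg_points=14)
        with pytest.raises(PreprocessError):
            PreprocessParams(sg_points=3, sg_polyorder=3)
        with pytest.raises(PreprocessError):
            PreprocessParams(window_low=1800.0, window_high=900.0)
        with pytest.raises(PreprocessError):
            PreprocessParams(scale_mode="robust")
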
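"""Synthetic-data generator: spectra construction, artifacts, determinism."""

import numpy as np
import pytest
from dataclasses import replace

from serofir.simulate import (
    BandSpec, SimConfig, SimulationError, default_bands, generate_dataset,
    inject_artifacts, inject_outliers, make_base_spectrum, n_outliers, preset,
)


def one_band_config(**kw):
    band = BandSpec(center=1500.0, width=12.0, amplitude=0.7)
    defaults = dict(grid_step=1.5, bands=(band,), n_subjects_per_class=2,
                    n_replicates_per_subject=2, seed=1)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestBaseSpectrum:
    def test_peak_value_equals_amplitude(self):
        cfg = one_band_config()
        spec = make_base_spectrum(cfg, "allergic", np.ones(1))
        grid = cfg.grid()
        assert spec[np.argmin(np.abs(grid - 1500.0))] == pytest.approx(0.7)

    def test_zero_amplitudes_give_zero_spectrum(self):
        band = BandSpec(center=1500.0, width=12.0, amplitude=0.0)
        cfg = one_band_config(bands=(band,))
        assert not make_base_spectrum(cfg, "sit", np.ones(1)).any()

    def test_class_effect_localised_to_band(self):
        """Two classes differing by 1.10 on the 1740 band: identical outside
        +/-4 sigma, exact 1.10 ratio at the centre."""
        bands = (BandSpec(1740.0, 10.0, 0.5, {"allergic": 1.10}),
                 BandSpec(1100.0, 15.0, 0.4))
        cfg = one_band_config(bands=bands)
        grid = cfg.grid()
        a = make_base_spectrum(cfg, "allergic", np.ones(2))
        b = make_base_spectrum(cfg, "non_allergic", np.ones(2))
        inside = np.abs(grid - 1740.0) <= 40.0
        assert np.array_equal(a[~inside], b[~inside])
        center = np.argmin(np.abs(grid - 1740.0))
        assert a[center] / b[center] == pytest.approx(1.10)

    def test_unknown_class_label_rejected(self):
        cfg = one_band_config()
        with pytest.raises(SimulationError, match="unknown class"):
            make_base_spectrum(cfg, "martian", np.ones(1))

    def test_non_negative_everywhere(self):
        cfg = preset("human")
        spec = make_base_spectrum(cfg, "sit", np.full(len(cfg.bands), 1.3))
        assert (spec >= 0).all()


class TestArtifacts:
    def test_all_zero_artifacts_identity(self, clean_config):
        grid = clean_config.grid()
        x = np.exp(-0.5 * ((grid - 1500) / 20) ** 2)
        out = inject_artifacts(x, clean_config, np.random.default_rng(0))
        np.testing.assert_array_equal(out, x)

    def test_noise_moment(self):
        """With only white noise on, sd(out - in) matches noise_sd."""
        cfg = SimConfig(grid_start=100.0, grid_end=4000.0, grid_step=0.3,
                        scatter_slope_sd=0, scatter_offset_sd=0, baseline_sd=0,
                        water_vapor_amplitude=0, noise_sd=0.01)
        grid = cfg.grid()
        assert grid.size >= 10_000
        x = np.zeros_like(grid)
        out = inject_artifacts(x, cfg, np.random.default_rng(3))
        assert np.std(out - x) == pytest.approx(0.01, rel=0.05)

    def test_one_step_batch_shift(self, clean_config):
        cfg = replace(clean_config, batch_shift=clean_config.grid_step,
                      batch_gain=1.0)
        grid = cfg.grid()
        x = np.exp(-0.5 * ((grid - 1500) / 30) ** 2)
        out = inject_artifacts(x, cfg, np.random.default_rng(0), batch_index=1)
        np.testing.assert_allclose(out[1:], x[:-1], atol=1e-12)


class TestDatasetAssembly:
    def test_row_counts(self, small_config):
        ds, truth = generate_dataset(small_config)
        expected = 3 * 4 * 5
        assert ds.n_spectra == expected
        assert len(truth) == expected

    def test_determinism_bit_identical(self, small_config):
        d1, t1 = generate_dataset(small_config)
        d2, t2 = generate_dataset(small_config)
        assert np.array_equal(d1.intensities, d2.intensities)
        assert t1.equals(t2)

    def test_replicate_scaling_preserves_subject_draws(self, small_config):
        """Doubling replicates only appends rows; existing draws unchanged."""
        d1, _ = generate_dataset(small_config)
        d2, _ = generate_dataset(replace(small_config,
                                         n_replicates_per_subject=10))
        assert d2.n_spectra == 2 * d1.n_spectra
        ids1 = d1.metadata["spectrum_id"]
        lookup = {sid: i for i, sid in enumerate(d2.metadata["spectrum_id"])}
        rows2 = [lookup[sid] for sid in ids1]
        np.testing.assert_array_equal(d1.intensities, d2.intensities[rows2])

    def test_class_signal_locality(self, clean_config):
        """Artifacts off: between-class differences vanish exactly outside
        +/-4 sigma of the bands whose class effects differ."""
        ds, _ = generate_dataset(replace(clean_config, subject_sd=0.0))
        grid = ds.wavenumbers
        groups = ds.metadata["group"].to_numpy()
        mean = {g: ds.intensities[groups == g].mean(axis=0)
                for g in np.unique(groups)}
        differing = np.zeros_like(grid, dtype=bool)
        for band in clean_config.bands:
            if len(set(band.class_effects.get(c, 1.0)
                       for c in clean_config.classes)) > 1:
                differing |= np.abs(grid - band.center) <= 4 * band.width
        for a in mean:
            for b in mean:
                diff = mean[a] - mean[b]
                assert not diff[~differing].any()

    def test_human_preset_has_larger_subject_variance(self):
        """Between-subject amplitude variance is larger for the human preset."""
        spread = {}
        for name in ("mouse", "human"):
            cfg = preset(name, n_subjects_per_class=20 if name == "human" else 10)
            cfg = replace(cfg, n_subjects_per_class=20,
                          n_replicates_per_subject=1, grid_step=3.0,
                          scatter_slope_sd=0, scatter_offset_sd=0,
                          baseline_sd=0, noise_sd=0, water_vapor_amplitude=0,
                          seed=77)
            ds, _ = generate_dataset(cfg)
            amide = np.argmin(np.abs(ds.wavenumbers - 1655.0))
            grp = ds.metadata["group"] == "non_allergic"
            spread[name] = np.var(ds.intensities[grp.to_numpy(), amide])
        assert preset("human").subject_sd > preset("mouse").subject_sd
        assert spread["human"] > spread["mouse"]


class TestOutliers:
    def test_count_rule(self):
        assert n_outliers(0.0, 1200) == 0
        assert n_outliers(0.02, 1200) == 24
        assert n_outliers(0.001, 100) == 1  # at least one when fraction > 0
        assert n_outliers(0.5, 10) == 5

    def test_zero_fraction_no_change(self, small_config):
        ds, _ = generate_dataset(small_config)
        out, mask = inject_outliers(ds, 0.0, np.random.default_rng(0))
        assert not mask.any()
        np.testing.assert_array_equal(out.intensities, ds.intensities)

    def test_corruption_is_gross(self, small_config):
        ds, _ = generate_dataset(small_config)
        out, mask = inject_outliers(ds, 0.2, np.random.default_rng(4))
        clean_p99 = np.percentile(ds.intensities, 99)
        assert mask.sum() == n_outliers(0.2, ds.n_spectra)
        assert (out.intensities[mask].max(axis=1) > 5 * clean_p99).all()

    def test_flagged_in_truth_table(self, small_config):
        cfg = replace(small_config, outlier_fraction=0.1)
        ds, truth = generate_dataset(cfg)
        assert truth["is_outlier"].sum() == n_outliers(0.1, ds.n_spectra)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"grid_start": 2000.0, "grid_end": 1000.0},
        {"grid_step": -1.0},
        {"n_replicates_per_subject": 0},
        {"outlier_fraction": 1.0},
        {"noise_sd": -0.1},
        {"n_batches": 0},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(SimulationError):
            SimConfig(**kw)

    def test_band_invariants(self):
        with pytest.raises(SimulationError):
            BandSpec(1500.0, -1.0, 0.5)
        with pytest.raises(SimulationError):
            BandSpec(1500.0, 10.0, 0.5, {"allergic": 0.0})

    def test_separation_levels_scale_effects(self):
        lo = default_bands("low")[2].class_effects["allergic"]
        hi = default_bands("high")[2].class_effects["allergic"]
        mod = default_bands("moderate")[2].class_effects["allergic"]
        assert (lo - 1) == pytest.approx((mod - 1) * 0.5)
        assert (hi - 1) == pytest.approx((mod - 1) * 2.0)
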
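"""Splits, CNN architecture/training contracts, Bayesian optimization."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from serofir.classify import (
    ClassificationError, CNNArchitecture, CNNSpectralClassifier,
    HyperparamSpace, SUBSETS, TrainingParams, bayes_optimize, build_cnn,
    make_splits, run_classification, train_cnn,
)
from serofir.dataset import SpectralDataset
from serofir.simulate import generate_dataset


def label_only_dataset(n_subjects=60, n_replicates=20, n_classes=3):
    """Cheap dataset (2-point grid) carrying only the split-relevant metadata."""
    rows = []
    for c in range(n_classes):
        for s in range(n_subjects // n_classes):
            for r in range(n_replicates):
                rows.append({
                    "spectrum_id": f"c{c}s{s}r{r}",
                    "subject_id": f"c{c}s{s}",
                    "group": f"class{c}",
                    "batch": "b0",
                    "replicate": r,
                })
    meta = pd.DataFrame(rows)
    return SpectralDataset(np.array([1.0, 2.0]),
                           np.zeros((len(meta), 2)), meta)


class TestSplits:
    def test_spectrum_mode_subset_sizes(self):
        ds = label_only_dataset()
        (split,) = make_splits(ds, grouping="spectrum", n_repeats=1, seed=0)
        sizes = {s: (split.assignment == s).sum() for s in SUBSETS}
        assert sizes == {"train": 780, "validation": 240, "test": 180}

    def test_subject_mode_keeps_replicates_together(self):
        ds = label_only_dataset()
        splits = make_splits(ds, grouping="subject", n_repeats=3, seed=1)
        for split in splits:
            table = pd.DataFrame({
                "subject": ds.metadata["subject_id"],
                "subset": split.assignment,
            })
            assert (table.groupby("subject")["subset"].nunique() == 1).all()

    def test_determinism_and_repeat_variation(self):
        ds = label_only_dataset()
        a = make_splits(ds, grouping="spectrum", n_repeats=2, seed=5)
        b = make_splits(ds, grouping="spectrum", n_repeats=2, seed=5)
        assert np.array_equal(a[0].assignment, b[0].assignment)
        assert np.array_equal(a[1].assignment, b[1].assignment)
        assert not np.array_equal(a[0].assignment, a[1].assignment)

    def test_stratification_by_class(self):
        ds = label_only_dataset()
        (split,) = make_splits(ds, grouping="spectrum", n_repeats=1, seed=2)
        for cls in ds.metadata["group"].unique():
            in_class = (ds.metadata["group"] == cls).to_numpy()
            n_test = (split.assignment[in_class] == "test").sum()
            assert n_test == 60  # 400 * 0.15

    def test_kfold_mode_covers_every_unit_once(self):
        ds = label_only_dataset(n_subjects=30, n_replicates=2)
        splits = make_splits(ds, grouping="subject", n_repeats=5, seed=3,
                             mode="kfold")
        test_units = [set(ds.metadata.loc[s.assignment == "test", "subject_id"])
                      for s in splits]
        all_units = set(ds.metadata["subject_id"])
        assert set.union(*test_units) == all_units
        for a in range(5):
            for b in range(a + 1, 5):
                assert not test_units[a] & test_units[b]

    def test_tiny_class_rejected(self):
        ds = label_only_dataset(n_subjects=6, n_replicates=2)
        with pytest.raises(ClassificationError, match="units"):
            make_splits(ds, grouping="subject", n_repeats=1)


class TestArchitecture:
    def test_probabilities_valid(self, rng):
        net, _ = build_cnn(CNNArchitecture(), 64, rng)
        from serofir.nn import softmax
        p = softmax(net.forward(rng.standard_normal((5, 64, 1))))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert ((p >= 0) & (p <= 1)).all()

    def test_conv_stack_parameters_grow_with_depth(self, rng):
        """Deeper sections add conv blocks, so the feature-extraction stack
        strictly gains parameters (the flatten-dense head shrinks with extra
        pooling, so total counts need not grow)."""
        counts = []
        for depth in (1, 2, 3):
            _, desc = build_cnn(CNNArchitecture(section_depth=depth), 128, rng)
            counts.append(sum(d["n_params"] for d in desc
                              if d["layer"].startswith("conv")))
        assert counts[0] < counts[1] < counts[2]

    def test_zero_input_gives_uniform_probabilities(self, rng):
        net, _ = build_cnn(CNNArchitecture(), 64, rng)
        from serofir.nn import softmax
        p = softmax(net.forward(np.zeros((2, 64, 1))))
        np.testing.assert_allclose(p, 1 / 3, atol=1e-6)

    def test_exhausted_pooling_rejected(self, rng):
        with pytest.raises(ClassificationError, match="pooled length"):
            build_cnn(CNNArchitecture(section_depth=3), 8, rng)

    def test_description_lists_all_blocks(self, rng):
        arch = CNNArchitecture(section_depth=2)
        _, desc = build_cnn(arch, 128, rng)
        conv_blocks = [d for d in desc if d["layer"].startswith("conv")]
        assert len(conv_blocks) == arch.section_depth + arch.extra_conv_blocks


class TestTraining:
    def test_zero_learning_rate_flat_history(self, rng):
        net, _ = build_cnn(CNNArchitecture(section_depth=1, n_filters=2,
                                           dense_units=4), 32, rng)
        X = rng.standard_normal((20, 32))
        y = rng.integers(0, 3, 20)
        params = TrainingParams(learning_rate=0.0, max_epochs=3, patience=5)
        hist = train_cnn(net, X, y, X, y, params)
        assert hist["train_loss"].nunique() == 1

    def test_patience_zero_stops_immediately_without_improvement(self, rng):
        net, _ = build_cnn(CNNArchitecture(section_depth=1, n_filters=2,
                                           dense_units=4), 32, rng)
        X = rng.standard_normal((20, 32))
        y = rng.integers(0, 3, 20)
        params = TrainingParams(learning_rate=0.0, max_epochs=20, patience=0)
        hist = train_cnn(net, X, y, X, y, params)
        assert len(hist) == 2  # epoch 1 sets the best; epoch 2 cannot improve
        assert hist.attrs["best_epoch"] == 1

    def test_divergence_reported_with_epoch(self, rng):
        net, _ = build_cnn(CNNArchitecture(section_depth=1), 32, rng)
        X = 1e3 * rng.standard_normal((30, 32))
        y = rng.integers(0, 3, 30)
        params = TrainingParams(learning_rate=1e4, max_epochs=5, patience=2)
        with pytest.raises(ClassificationError, match="diverged"):
            train_cnn(net, X, y, X, y, params)

    def test_high_separation_benchmark(self, high_separation_config):
        """Well-separated synthetic classes: held-out accuracy >= 0.95."""
        ds, _ = generate_dataset(high_separation_config)
        run = run_classification(ds, grouping="spectrum", n_repeats=1,
                                 bayes_budget=0, seed=3)
        assert run.metrics["accuracy"].iloc[0] >= 0.95
        hist = run.histories[0]
        assert hist["val_accuracy"].max() >= 0.95

    def test_predictions_deterministic_and_row_consistent(self, rng):
        X = rng.standard_normal((30, 48))
        y = np.array(["a", "b", "c"] * 10)
        clf = CNNSpectralClassifier(
            arch=CNNArchitecture(section_depth=1, n_filters=2, dense_units=8),
            training=TrainingParams(max_epochs=2, patience=1), seed=0)
        clf.fit(X, y)
        p1 = clf.predict_proba(X[:5])
        p2 = clf.predict_proba(np.vstack([X[:5], X[:1]]))
        np.testing.assert_array_equal(p1, p2[:5])
        np.testing.assert_array_equal(p2[0], p2[5])  # duplicated row
        np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-6)

    def test_input_length_mismatch_rejected(self, rng):
        X = rng.standard_normal((12, 48))
        y = np.array(["a", "b", "c"] * 4)
        clf = CNNSpectralClassifier(
            arch=CNNArchitecture(section_depth=1, n_filters=2, dense_units=8),
            training=TrainingParams(max_epochs=1, patience=0), seed=0)
        clf.fit(X, y)
        with pytest.raises(ClassificationError, match="length"):
            clf.predict(rng.standard_normal((2, 50)))


class TestBayesOptimize:
    def test_budget_one_returns_single_point(self):
        space = HyperparamSpace(budget=1)
        best, trace = bayes_optimize(space, lambda p: p["momentum"], seed=0)
        assert len(trace) == 1
        assert best["momentum"] == trace["momentum"].iloc[0]

    def test_trace_records_every_evaluation(self):
        space = HyperparamSpace(budget=8)
        calls = []
        def objective(p):
            calls.append(p)
            return (p["momentum"] - 0.8) ** 2
        _, trace = bayes_optimize(space, objective, seed=1)
        assert len(trace) == len(calls) == 8

    def test_quadratic_objective_beats_random_search(self):
        """Budget-20 GP search finds the 1-D quadratic minimum within 10 % of
        the range and does at least as well as a random search median."""
        target = 0.8
        objective = lambda p: (p["momentum"] - target) ** 2
        space = HyperparamSpace(budget=20)
        best, trace = bayes_optimize(space, objective, seed=2)
        span = space.momentum[1] - space.momentum[0]
        assert abs(best["momentum"] - target) <= 0.1 * span
        randoms = []
        for s in range(5):
            rb, _ = bayes_optimize(space, objective, seed=100 + s,
                                   random_search=True)
            randoms.append((rb["momentum"] - target) ** 2)
        assert (best["momentum"] - target) ** 2 <= np.median(randoms)

    def test_failures_skipped_and_all_failures_rejected(self):
        space = HyperparamSpace(budget=6)
        def flaky(p):
            return np.nan if p["momentum"] < 0.9 else p["momentum"]
        best, trace = bayes_optimize(space, flaky, seed=3)
        assert trace["objective"].isna().sum() >= 1
        with pytest.raises(ClassificationError, match="failed"):
            bayes_optimize(HyperparamSpace(budget=3), lambda p: np.nan, seed=4)

    def test_decode_respects_bounds(self):
        space = HyperparamSpace()
        for u in (np.zeros(6), np.ones(6), np.full(6, 0.5)):
            p = space.decode(u)
            assert space.section_depth[0] <= p["section_depth"] <= space.section_depth[1]
            assert space.learning_rate[0] <= p["learning_rate"] <= space.learning_rate[1]
            assert p["filter_size"] in space.filter_sizes
            assert space.n_filters[0] <= p["n_filters"] <= space.n_filters[1]


class TestLeakageControls:
    def test_scaler_and_msc_fit_on_train_rows_only(self, high_separation_config):
        ds, _ = generate_dataset(high_separation_config)
        run = run_classification(ds, grouping="subject", n_repeats=1,
                                 bayes_budget=0, seed=9)
        stats = run.preprocess_stats[0]
        split = run.splits[0]
        train_rows = split.rows("train")
        # recompute the chain on the training rows alone
        from serofir.preprocess import PreprocessModel, PreprocessParams
        pre = PreprocessModel(PreprocessParams(scale_mode="standardize")).fit(
            ds.select_rows(train_rows))
        np.testing.assert_array_equal(stats["msc_reference"], pre.msc_.reference_)
        np.testing.assert_array_equal(stats["scaler_means"], pre.scaler_.means_)
        # and they must differ from full-data statistics
        pre_full = PreprocessModel(PreprocessParams(scale_mode="standardize")).fit(ds)
        assert not np.allclose(stats["msc_reference"], pre_full.msc_.reference_)

    def test_label_permutation_control(self):
        """Training on permuted labels collapses accuracy to chance.

        One spectrum per subject keeps the pooled test rows independent, so
        the 3-sd band around 1/3 is the right null envelope."""
        from serofir.simulate import SimConfig, default_bands
        cfg = SimConfig(grid_step=3.0, n_subjects_per_class=30,
                        n_replicates_per_subject=1,
                        bands=tuple(default_bands("high")), seed=41)
        ds, _ = generate_dataset(cfg)
        rng = np.random.default_rng(17)
        permuted = ds.metadata.copy()
        permuted["group"] = rng.permutation(permuted["group"].to_numpy())
        shuffled = SpectralDataset(ds.wavenumbers, ds.intensities, permuted)
        run = run_classification(shuffled, grouping="spectrum", n_repeats=3,
                                 bayes_budget=0, seed=4)
        pooled = pd.concat(run.predictions)
        truth = ds.metadata.set_index("spectrum_id")["group"]
        acc = (pooled["predicted"].to_numpy()
               == truth.loc[pooled["spectrum_id"]].to_numpy()).mean()
        sd = np.sqrt((1 / 3) * (2 / 3) / len(pooled))
        assert abs(acc - 1 / 3) < 3 * sd
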
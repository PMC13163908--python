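import numpy as np
import pytest

from specnn.evaluate import (
    confusion_matrix,
    evaluate_predictions,
    make_classical_model,
    metrics_from_cm,
    specs_differ_only_in_eca,
)
from specnn.net import build_cnn1d, build_ecnn1d, build_resnet1d, build_vgg1d


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        cm = confusion_matrix(y, y, 3)
        np.testing.assert_array_equal(cm, np.diag([2, 2, 2]))

    def test_direct_count_example(self):
        cm = confusion_matrix([0, 0, 1], [0, 1, 1], 2)
        np.testing.assert_array_equal(cm, [[1, 1], [0, 1]])

    def test_entries_sum_to_n(self, rng):
        for _ in range(5):
            n = int(rng.integers(1, 50))
            yt = rng.integers(0, 4, size=n)
            yp = rng.integers(0, 4, size=n)
            assert confusion_matrix(yt, yp, 4).sum() == n

    def test_label_out_of_range(self):
        with pytest.raises(ValueError, match="outside"):
            confusion_matrix([0, 3], [0, 1], 3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            confusion_matrix([0, 1], [0], 2)


class TestMetrics:
    def test_diagonal_all_ones(self):
        rep = metrics_from_cm(np.diag([4, 5, 6]))
        assert rep.accuracy == 1.0
        np.testing.assert_allclose(rep.precision, 1.0)
        np.testing.assert_allclose(rep.recall, 1.0)
        np.testing.assert_allclose(rep.f1, 1.0)
        assert rep.macro_f1 == 1.0

    def test_hand_computed_example(self):
        cm = np.array([[8, 2, 0], [1, 9, 0], [0, 0, 10]])
        rep = metrics_from_cm(cm)
        assert rep.accuracy == pytest.approx(27 / 30)
        np.testing.assert_allclose(rep.precision, [8 / 9, 9 / 11, 1.0])
        np.testing.assert_allclose(rep.recall, [0.8, 0.9, 1.0])
        expected_f1 = [2 * p * r / (p + r) for p, r in
                       zip([8 / 9, 9 / 11, 1.0], [0.8, 0.9, 1.0])]
        np.testing.assert_allclose(rep.f1, expected_f1)
        assert rep.macro_precision == pytest.approx(np.mean([8 / 9, 9 / 11, 1.0]))
        assert rep.macro_recall == pytest.approx(np.mean([0.8, 0.9, 1.0]))
        assert rep.macro_f1 == pytest.approx(np.mean(expected_f1))

    def test_degenerate_class_scores_zero_with_warning(self):
        # class 2 never predicted and absent from the truth
        cm = np.array([[3, 0, 0], [0, 3, 0], [0, 0, 0]])
        with pytest.warns(UserWarning):
            rep = metrics_from_cm(cm)
        assert rep.precision[2] == 0.0
        assert rep.recall[2] == 0.0
        assert rep.f1[2] == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics_from_cm(np.zeros((3, 3), dtype=int))

    def test_macro_recall_equals_balanced_accuracy(self, rng):
        # balanced truth: macro recall == mean of per-class accuracies
        yt = np.repeat([0, 1, 2], 20)
        yp = rng.integers(0, 3, size=60)
        rep = evaluate_predictions(yt, yp, 3)
        per_class = [np.mean(yp[yt == k] == k) for k in range(3)]
        assert rep.macro_recall == pytest.approx(np.mean(per_class))

    def test_matches_per_sample_brute_force(self, rng):
        for trial in range(10):
            n = int(rng.integers(10, 60))
            yt = rng.integers(0, 3, size=n)
            yp = rng.integers(0, 3, size=n)
            rep = evaluate_predictions(yt, yp, 3)
            # brute force: accuracy by sample loop, P/R by definition counts
            acc = sum(int(a == b) for a, b in zip(yt, yp)) / n
            assert rep.accuracy == pytest.approx(acc)
            for k in range(3):
                tp = sum(1 for a, b in zip(yt, yp) if a == k and b == k)
                fp = sum(1 for a, b in zip(yt, yp) if a != k and b == k)
                fn = sum(1 for a, b in zip(yt, yp) if a == k and b != k)
                p = tp / (tp + fp) if tp + fp else 0.0
                r = tp / (tp + fn) if tp + fn else 0.0
                assert rep.precision[k] == pytest.approx(p)
                assert rep.recall[k] == pytest.approx(r)

    def test_metrics_within_unit_interval(self, rng):
        yt = rng.integers(0, 3, size=30)
        yp = rng.integers(0, 3, size=30)
        rep = evaluate_predictions(yt, yp, 3)
        for v in (rep.accuracy, rep.macro_precision, rep.macro_recall, rep.macro_f1):
            assert 0.0 <= v <= 1.0


class TestClassicalModels:
    @pytest.mark.parametrize("name", ["lda", "rf", "knn", "svm"])
    def test_fit_predict(self, name, rng):
        X = np.vstack([rng.normal(0, 1, (20, 5)), rng.normal(3, 1, (20, 5))])
        y = np.repeat([0, 1], 20)
        clf = make_classical_model(name, seed=0)
        clf.fit(X, y)
        assert (clf.predict(X) == y).mean() > 0.9

    def test_unknown_name(self):
        with pytest.raises(ValueError, match="unknown classical"):
            make_classical_model("xgboost")


class TestAblationStructure:
    def test_ecnn_cnn_pair(self):
        assert specs_differ_only_in_eca(build_ecnn1d(123, 3), build_cnn1d(123, 3))

    def test_vgg_pair(self):
        assert specs_differ_only_in_eca(build_vgg1d(123, 3, eca=True),
                                        build_vgg1d(123, 3, eca=False))

    def test_resnet_pair(self):
        assert specs_differ_only_in_eca(build_resnet1d(123, 3, eca=True),
                                        build_resnet1d(123, 3, eca=False))

    def test_mismatched_pair_rejected(self):
        assert not specs_differ_only_in_eca(build_ecnn1d(123, 3), build_vgg1d(123, 3))
        assert not specs_differ_only_in_eca(build_ecnn1d(123, 3), build_ecnn1d(64, 3))


@pytest.fixture(scope="module")
def grid():
    from specnn.evaluate import benchmark_grid
    from specnn.synth import SimSpec, generate
    from specnn.train import TrainConfig

    datasets = {
        "easy": generate(SimSpec(preset="visnir", n_per_class=12, delta=0.3,
                                 noise_sd=0.01, seed=1)),
        "tiny": generate(SimSpec(preset="visnir", n_per_class=10, delta=0.3,
                                 noise_sd=0.01, seed=2)),
    }
    cfg = TrainConfig(max_epochs=2, patience=2, seeds=(0, 1))
    models = {"lda": "lda", "knn": "knn"}
    return benchmark_grid(models, datasets, cfg)


class TestBenchmarkGrid:

    def test_cell_count(self, grid):
        assert len(grid) == 4
        assert set(grid["model"]) == {"lda", "knn"}
        assert set(grid["dataset"]) == {"easy", "tiny"}

    def test_no_errors_and_metrics_present(self, grid):
        assert grid["error"].isna().all()
        assert grid["accuracy_mean"].between(0, 1).all()
        assert (grid["accuracy_std"] >= 0).all()

    def test_cell_failure_does_not_abort(self):
        from specnn.evaluate import benchmark_grid
        from specnn.synth import SimSpec, generate
        from specnn.train import TrainConfig

        ds = generate(SimSpec(preset="visnir", n_per_class=10, seed=3))
        cfg = TrainConfig(max_epochs=1, patience=1, seeds=(0,))
        # a builder that raises
        def broken(n_bands, n_classes):
            raise RuntimeError("boom")

        grid = benchmark_grid({"broken": broken, "lda": "lda"}, {"d": ds}, cfg)
        row = grid[grid["model"] == "broken"].iloc[0]
        assert "boom" in row["error"]
        ok = grid[grid["model"] == "lda"].iloc[0]
        assert ok["error"] is None or (isinstance(ok["error"], float) and np.isnan(ok["error"]))

    def test_reproducible_given_seeds(self):
        from specnn.evaluate import benchmark_grid
        from specnn.synth import SimSpec, generate
        from specnn.train import TrainConfig

        ds = generate(SimSpec(preset="visnir", n_per_class=10, delta=0.3, seed=4))
        cfg = TrainConfig(max_epochs=1, patience=1, seeds=(0, 1))
        g1 = benchmark_grid({"lda": "lda"}, {"d": ds}, cfg)
        g2 = benchmark_grid({"lda": "lda"}, {"d": ds}, cfg)
        assert g1["accuracy_mean"].iloc[0] == g2["accuracy_mean"].iloc[0]


class TestReducedFeatureModeling:
    """Reduced-feature path: 20-D scores feed any classifier end-to-end."""

    def test_pca20_grid_runs_for_classical_and_deep(self):
        from specnn.evaluate import benchmark_grid
        from specnn.net import build_cnn1d
        from specnn.synth import SimSpec, generate
        from specnn.train import TrainConfig

        ds = generate(SimSpec(preset="visnir", n_per_class=15, delta=0.3, seed=6))
        cfg = TrainConfig(max_epochs=2, patience=2, seeds=(0,))
        grid = benchmark_grid({"lda": "lda", "cnn1d": build_cnn1d}, {"d": ds},
                              cfg, features="pca", n_components=20)
        assert grid["error"].isna().all()
        assert grid["accuracy_mean"].between(0, 1).all()

    def test_umap20_grid_runs(self):
        pytest.importorskip("umap")
        from specnn.evaluate import benchmark_grid
        from specnn.synth import SimSpec, generate
        from specnn.train import TrainConfig

        ds = generate(SimSpec(preset="visnir", n_per_class=15, delta=0.3, seed=7))
        cfg = TrainConfig(max_epochs=1, patience=1, seeds=(0,))
        grid = benchmark_grid({"knn": "knn"}, {"d": ds}, cfg,
                              features="umap", n_components=5)
        assert grid["error"].isna().all()


class TestClassicalGridOnEasyPreset:
    def test_all_classical_models_accurate_on_separable_data(self):
        # scaled-down analogue of the full-spectrum benchmark: on a
        # well-separated fixture every classical model should be near-perfect
        from specnn.evaluate import benchmark_grid
        from specnn.synth import SimSpec, generate
        from specnn.train import TrainConfig

        ds = generate(SimSpec(preset="visnir", n_per_class=60, delta=0.3, seed=9))
        cfg = TrainConfig(max_epochs=1, patience=1, seeds=(0, 1, 2))
        grid = benchmark_grid({m: m for m in ("lda", "rf", "knn", "svm")},
                              {"visnir": ds}, cfg,
                              preprocess=["sg", "snv"])
        assert grid["error"].isna().all()
        assert (grid["accuracy_mean"] >= 0.95).all()
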
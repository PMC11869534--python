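"""The balanced-subsample repeated classification harness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from facegest import (
    HarnessConfig,
    aggregate,
    balanced_subsample,
    compare_algorithms,
    run_harness,
    run_once,
)
from facegest.classify import RunResult, _run_seeds

#: A reduced SVM grid keeps unit tests quick; the default grid is the full one.
SMALL_SVM = dict(svm_gamma=(0.01, 0.05), svm_cost=(0.01, 1.0), svm_coef0=(1.0,))


def gaussian_table(n_per_class, separation, seed=0, classes=("vo", "un"), n_features=6):
    """Two (or more) Gaussian blobs with controllable class separation."""
    rng = np.random.default_rng(seed)
    rows = []
    for c_idx, cls in enumerate(classes):
        X = rng.normal(c_idx * separation, 1.0, size=(n_per_class, n_features))
        for i, x in enumerate(X):
            rows.append({**{f"f{j}": v for j, v in enumerate(x)},
                         "clip_id": f"{cls}{i}", "voicing": cls, "context": cls})
    return pd.DataFrame(rows)


class TestBalancedSubsample:
    def test_exact_counts_per_class(self):
        table = gaussian_table(5000, 0.0)
        config = HarnessConfig(task="voicing", n_per_class=3000, n_runs=1)
        sub = balanced_subsample(table, config, run_seed=7)
        assert len(sub) == 6000
        assert sub["voicing"].value_counts().to_dict() == {"vo": 3000, "un": 3000}

    def test_insufficient_class_is_an_error_naming_it(self):
        table = gaussian_table(150, 0.0)
        config = HarnessConfig(task="voicing", n_per_class=200, n_runs=1)
        with pytest.raises(ValueError, match="'vo'"):
            balanced_subsample(table, config, run_seed=1)

    def test_same_seed_reproduces_selection(self):
        table = gaussian_table(500, 0.0)
        config = HarnessConfig(task="voicing", n_per_class=300, n_runs=1)
        a = balanced_subsample(table, config, run_seed=3)
        b = balanced_subsample(table, config, run_seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestRunOnce:
    def test_separated_classes_classified_perfectly(self):
        table = gaussian_table(120, 8.0, seed=1)
        config = HarnessConfig(
            task="voicing", n_per_class=100, n_runs=1, **SMALL_SVM,
            rf_n_trees=100,
        )
        sub = balanced_subsample(table, config, run_seed=2)
        result = run_once(sub, config, run_seed=2)
        for algo in ("mlp", "svm", "rfc"):
            assert result.metrics[(algo, "test")]["accuracy"] > 0.98

    def test_identical_seed_gives_identical_result(self):
        table = gaussian_table(150, 1.0, seed=2)
        config = HarnessConfig(
            task="voicing", n_per_class=100, n_runs=1, **SMALL_SVM, rf_n_trees=50
        )
        sub = balanced_subsample(table, config, run_seed=5)
        a = run_once(sub, config, run_seed=5)
        b = run_once(sub, config, run_seed=5)
        assert a.metrics == b.metrics
        for algo in a.confusion:
            np.testing.assert_array_equal(a.confusion[algo], b.confusion[algo])

    def test_confusion_rows_sum_to_per_class_test_counts(self):
        table = gaussian_table(150, 1.0, seed=3)
        config = HarnessConfig(
            task="voicing", n_per_class=100, n_runs=1, algorithms=("rfc",),
            rf_n_trees=50,
        )
        sub = balanced_subsample(table, config, run_seed=4)
        result = run_once(sub, config, run_seed=4)
        # stratified 30% of 100 per class
        np.testing.assert_array_equal(
            result.confusion["rfc"].sum(axis=1), [30, 30]
        )

    def test_single_class_training_rejected(self):
        table = gaussian_table(50, 0.0, classes=("vo",))
        config = HarnessConfig(task="voicing", n_per_class=40, n_runs=1)
        with pytest.raises(ValueError, match="single class"):
            run_once(table, config, run_seed=1)


class TestRunHarness:
    def test_shuffled_labels_hover_at_chance(self):
        # label-independent features: mean test CCR within 3 SE of 50%
        table = gaussian_table(400, 0.0, seed=4)
        config = HarnessConfig(
            task="voicing", n_per_class=200, n_runs=20, seed=11,
            algorithms=("rfc",), rf_n_trees=100,
        )
        results = run_harness(table, config)
        accs = np.array([r.metrics[("rfc", "test")]["accuracy"] for r in results])
        se = accs.std(ddof=1) / np.sqrt(len(accs))
        assert abs(accs.mean() - 0.5) < 3 * se

    def test_run_count_and_distinct_subsamples(self):
        table = gaussian_table(300, 0.5, seed=5)
        config = HarnessConfig(
            task="voicing", n_per_class=100, n_runs=4, seed=1,
            algorithms=("rfc",), rf_n_trees=20,
        )
        results = run_harness(table, config)
        assert [r.run_index for r in results] == [0, 1, 2, 3]
        accs = {r.metrics[("rfc", "test")]["accuracy"] for r in results}
        assert len(accs) > 1  # fresh subsample/split per run

    def test_seed_derivation_is_stable(self):
        assert _run_seeds(42, 5) == _run_seeds(42, 5)
        assert all(0 <= s < 2**31 for s in _run_seeds(123, 10))


def synthetic_results(accs_by_algo, n_classes=2):
    """RunResults carrying prescribed per-run test accuracies."""
    algos = list(accs_by_algo)
    n_runs = len(next(iter(accs_by_algo.values())))
    out = []
    for r in range(n_runs):
        metrics = {}
        confusion = {}
        for algo in algos:
            acc = accs_by_algo[algo][r]
            metrics[(algo, "test")] = {
                "accuracy": acc, "precision": acc, "recall": acc, "f1": acc
            }
            metrics[(algo, "train")] = dict(metrics[(algo, "test")])
            confusion[algo] = np.full((n_classes, n_classes), 10)
        out.append(RunResult(r, tuple("ab"[:n_classes]), metrics, confusion))
    return out


class TestAggregate:
    def test_mean_and_sd_of_two_runs(self):
        results = synthetic_results({"rfc": [0.8, 0.9]})
        summary = aggregate(results)["summary"]
        assert summary.loc["accuracy", ("rfc", "test", "mean")] == pytest.approx(0.85)
        assert summary.loc["accuracy", ("rfc", "test", "sd")] == pytest.approx(
            np.std([0.8, 0.9], ddof=1)
        )

    def test_identical_runs_have_zero_sd(self):
        results = synthetic_results({"rfc": [0.7, 0.7, 0.7]})
        summary = aggregate(results)["summary"]
        assert summary.loc["accuracy", ("rfc", "test", "sd")] == pytest.approx(0.0, abs=1e-12)

    def test_confusion_percentage_rows_sum_to_100(self, small_dataset):
        from facegest.features import prune_correlated
        from facegest.pipeline import build_feature_table

        table, _ = build_feature_table(
            small_dataset.predictions, small_dataset.clip_labels
        )
        reduced, _ = prune_correlated(table)
        config = HarnessConfig(
            task="context", n_per_class=8, n_runs=3, seed=2,
            algorithms=("rfc",), rf_n_trees=20,
        )
        results = run_harness(reduced, config)
        confusion = aggregate(results)["confusion"]["rfc"]
        np.testing.assert_allclose(confusion.sum(axis=1), 100.0, atol=1e-9)


class TestCompareAlgorithms:
    def test_identical_series_give_t_zero(self):
        rng = np.random.default_rng(6)
        accs = 0.8 + 0.01 * rng.normal(size=20)
        jitter = 1e-6 * rng.normal(size=20)  # breaks exact zero variance
        results = synthetic_results({"mlp": accs, "svm": accs + jitter})
        comp = compare_algorithms(results).comparisons[0]
        assert comp.t_statistic == pytest.approx(0.0, abs=1.0)
        assert comp.df == 19

    def test_constant_offset_is_flagged_degenerate(self):
        accs = np.linspace(0.7, 0.9, 10)
        results = synthetic_results({"mlp": accs, "svm": accs + 0.02})
        comp = compare_algorithms(results).comparisons[0]
        assert comp.degenerate
        assert np.isnan(comp.t_statistic)
        assert comp.mean_difference == pytest.approx(-0.02)

    def test_t_statistic_matches_closed_form(self):
        rng = np.random.default_rng(7)
        diff = rng.normal(0.025, 0.01, size=100)
        base = 0.5 + 0.001 * rng.normal(size=100)
        results = synthetic_results({"mlp": base + diff, "svm": base})
        comp = compare_algorithms(results).comparisons[0]
        expected = diff.mean() * np.sqrt(100) / diff.std(ddof=1)
        assert comp.t_statistic == pytest.approx(expected, abs=1e-9)
        assert comp.df == 99
        assert comp.p_value < 0.01
        # distribution-check stage ran
        assert 0 < comp.shapiro_p <= 1

    def test_pairs_cover_all_three_families(self):
        rng = np.random.default_rng(8)
        results = synthetic_results(
            {a: 0.5 + 0.01 * rng.normal(size=10) for a in ("mlp", "svm", "rfc")}
        )
        pairs = {c.pair for c in compare_algorithms(results).comparisons}
        assert pairs == {("mlp", "svm"), ("mlp", "rfc"), ("svm", "rfc")}
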
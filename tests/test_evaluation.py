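import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emrgraph.errors import MetricError
from emrgraph.evaluation import auprc, auroc, bootstrap_ci, compare_report, run_baselines
from oracles import auroc_bruteforce, average_precision_bruteforce


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_worked_example(self):
        # 3 concordant of the 4 positive-negative pairs
        assert auroc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert auroc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            auroc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 40))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0], labels[-1] = 0, 1
            scores = rng.choice([0.1, 0.2, 0.5, 0.7, 0.9], size=n)  # force ties
            assert auroc(labels, scores) == pytest.approx(auroc_bruteforce(labels, scores))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(1, 100))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=30)
        if labels.min() == labels.max():
            labels[0], labels[-1] = 0, 1
        scores = rng.normal(size=30)
        assert auroc(labels, np.exp(3 * scores)) == pytest.approx(auroc(labels, scores))


class TestAuprc:
    def test_perfect_ranking(self):
        assert auprc([1, 0], [0.9, 0.1]) == 1.0

    def test_random_scores_converge_to_prevalence(self):
        rng = np.random.default_rng(1)
        n, p = 100_000, 0.2
        labels = (rng.random(n) < p).astype(int)
        scores = rng.random(n)
        assert auprc(labels, scores) == pytest.approx(p, abs=0.01)

    def test_reversed_perfect_ranking_matches_enumeration(self):
        labels = np.array([0, 0, 0, 1, 1])
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1])  # worst ranking
        assert auprc(labels, scores) == pytest.approx(
            average_precision_bruteforce(labels, scores)
        )

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(3, 30))
            labels = rng.integers(0, 2, size=n)
            labels[0] = 1
            scores = rng.normal(size=n)
            assert auprc(labels, scores) == pytest.approx(
                average_precision_bruteforce(labels, scores)
            )

    def test_no_positives_rejected(self):
        with pytest.raises(MetricError):
            auprc([0, 0], [0.1, 0.2])


class TestBootstrap:
    def test_perfect_classifier_degenerate_interval(self):
        labels = np.array([0] * 20 + [1] * 20)
        scores = labels.astype(float)
        assert bootstrap_ci(auroc, labels, scores, n_boot=50, seed=0) == (1.0, 1.0)

    def test_same_seed_same_interval(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, size=100)
        labels[:2] = [0, 1]
        scores = rng.random(100)
        a = bootstrap_ci(auroc, labels, scores, n_boot=100, seed=9)
        b = bootstrap_ci(auroc, labels, scores, n_boot=100, seed=9)
        assert a == b

    def test_stratification_keeps_both_classes(self):
        # one positive only: unstratified resampling would often lose it
        labels = np.array([1] + [0] * 30)
        scores = np.linspace(0, 1, 31)
        lo, hi = bootstrap_ci(auroc, labels, scores, n_boot=50, seed=1)
        assert 0.0 <= lo <= hi <= 1.0


class TestBaselines:
    def test_linearly_separable_lr_auroc(self):
        rng = np.random.default_rng(4)
        n = 400
        X = rng.normal(size=(n, 5))
        y = (X[:, 0] > 0).astype(int)
        idx = np.arange(n)
        scores = run_baselines(X, y, idx[: n // 2], idx[n // 2 :], seed=0, rf_trees=50)
        assert auroc(y[idx[n // 2 :]], scores["LR"]) >= 0.99

    def test_identical_seeds_identical_scores(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 4))
        y = rng.integers(0, 2, size=200)
        y[:2] = [0, 1]
        idx = np.arange(200)
        a = run_baselines(X, y, idx[:100], idx[100:], seed=3, rf_trees=20)
        b = run_baselines(X, y, idx[:100], idx[100:], seed=3, rf_trees=20)
        for name in a:
            assert np.array_equal(a[name], b[name])

    def test_single_class_training_split_rejected(self):
        X = np.zeros((10, 2))
        y = np.zeros(10, dtype=int)
        with pytest.raises(MetricError):
            run_baselines(X, y, np.arange(5), np.arange(5, 10))


class TestReport:
    def test_single_model_table_and_recomputation(self, tmp_path):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 2, size=200)
        labels[:2] = [0, 1]
        scores = np.clip(labels * 0.4 + rng.random(200) * 0.6, 0, 1)
        report = compare_report({"only": (labels, scores)}, tmp_path, n_boot=50, seed=0)
        table = report.table()
        assert len(table) == 1
        # table entries are pure recomputations from the stored score vector
        assert table.loc[0, "AUROC"] == pytest.approx(auroc(labels, scores), abs=5e-4)
        assert (tmp_path / "roc_curves.png").exists()
        assert (tmp_path / "outcome_distribution.png").exists()
        assert (tmp_path / "table.md").read_text().startswith("| Model |")

    def test_roc_curves_span_unit_square(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        report = compare_report(
            {"a": (labels, rng.random(50)), "b": (labels, rng.random(50))}, n_boot=20, seed=0
        )
        for res in report.results:
            fpr, tpr = res.roc_points
            assert (fpr[0], tpr[0]) == (0.0, 0.0)
            assert (fpr[-1], tpr[-1]) == (1.0, 1.0)

    def test_empty_results_rejected(self):
        with pytest.raises(MetricError):
            compare_report({})
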
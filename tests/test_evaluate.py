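import itertools
import math

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import cohen_kappa_score, f1_score

import edgebiomark as eb
from edgebiomark.evaluate import CVConfig
from edgebiomark.synthetic import CohortSpec, SignalPlan


def pair_counting_auc(scores, labels):
    """Oracle: fraction of correctly ordered (pos, neg) pairs, ties half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_ranking(self):
        assert eb.auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert eb.auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_is_nan(self):
        assert math.isnan(eb.auc([0.1, 0.9], [1, 1]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        # coarse grid forces plenty of ties
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], n)
        assert eb.auc(scores, labels) == pytest.approx(pair_counting_auc(scores, labels))


class TestF1Kappa:
    def test_perfect_predictions(self):
        assert eb.f1_and_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == (1.0, 1.0)

    def test_all_negative_predictions(self):
        f1, kappa = eb.f1_and_kappa([0, 0, 0, 0], [1, 0, 1, 0])
        assert f1 == 0.0 and kappa == 0.0

    def test_hand_confusion_counts(self):
        # TP=3 FP=1 FN=2 TN=4
        pred = [1] * 3 + [1] + [0] * 2 + [0] * 4
        true = [1] * 3 + [0] + [1] * 2 + [0] * 4
        f1, kappa = eb.f1_and_kappa(pred, true)
        precision, recall = 3 / 4, 3 / 5
        assert f1 == pytest.approx(2 * precision * recall / (precision + recall))
        p_o = 7 / 10
        p_e = (4 * 5 + 6 * 5) / 100
        assert kappa == pytest.approx((p_o - p_e) / (1 - p_e))

    def test_exhaustive_2x2_against_sklearn(self):
        for n in range(2, 11):
            for tp, fp, fn in itertools.product(range(n + 1), repeat=3):
                tn = n - tp - fp - fn
                if tn < 0:
                    continue
                pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
                true = [1] * tp + [0] * fp + [1] * fn + [0] * tn
                f1, kappa = eb.f1_and_kappa(pred, true)
                assert f1 == pytest.approx(
                    f1_score(true, pred, pos_label=1, zero_division=0)
                )
                p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
                if p_e == 1.0:
                    assert math.isnan(kappa)
                else:
                    assert kappa == pytest.approx(cohen_kappa_score(true, pred))


class TestOptimalThreshold:
    def test_separable_reaches_corner(self):
        res = eb.optimal_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.distance == 0.0
        assert 0.2 < res.threshold <= 0.8
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_distance_formula_holds(self):
        res = eb.optimal_threshold([0.9, 0.1, 0.6, 0.55, 0.4, 0.2], [1, 0, 1, 0, 1, 0])
        assert res.distance == pytest.approx(
            math.sqrt((1 - res.sensitivity) ** 2 + (1 - res.specificity) ** 2)
        )

    def test_tie_broken_toward_higher_threshold(self):
        # cuts 0.9 and 0.6 both give distance 0.5; keep 0.9
        res = eb.optimal_threshold([0.9, 0.8, 0.6, 0.4], [1, 0, 1, 0])
        assert res.threshold == 0.9
        assert res.distance == pytest.approx(0.5)

    def test_degenerate_all_equal(self):
        res = eb.optimal_threshold([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
        assert res.distance == pytest.approx(1.0)
        assert res.sensitivity == 1.0 and res.specificity == 0.0

    def test_single_class_validation_is_error(self):
        with pytest.raises(ValueError, match="both classes"):
            eb.optimal_threshold([0.2, 0.4], [1, 1])

    def test_threshold_ignores_test_data(self):
        """No leakage: the chosen cut is a function of validation data only."""
        rng = np.random.default_rng(0)
        val_scores = rng.uniform(size=30)
        val_labels = rng.integers(0, 2, 30)
        val_labels[0], val_labels[1] = 0, 1
        before = eb.optimal_threshold(val_scores, val_labels)
        _poisoned_test = rng.normal(size=(10, 5)) * 1e6  # never passed in
        after = eb.optimal_threshold(val_scores, val_labels)
        assert before == after


class TestPairedTTest:
    def test_identical_vectors_nan(self):
        assert math.isnan(eb.paired_ttest([0.7, 0.8, 0.9], [0.7, 0.8, 0.9]))

    def test_constant_shift_tiny_p(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=100)
        shifted = base + 0.1 + 1e-4 * rng.normal(size=100)
        assert eb.paired_ttest(shifted, base) < 1e-10

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(2)
        pvals = [
            eb.paired_ttest(rng.normal(size=100), rng.normal(size=100))
            for _ in range(200)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            eb.paired_ttest([1.0, 2.0], [1.0])


def strong_signal_problem(seed=0):
    plan = SignalPlan(
        n_modules=2, module_size=10, n_signal_edges=5, per_gene_shift=1.5,
        batch_sd=0.0, seed=seed,
    )
    gene_ids = [f"G{i:02d}" for i in range(60)]
    ds = eb.generate_cohorts(gene_ids, [CohortSpec("c", 30, 60)], plan)
    from edgebiomark.synthetic import signal_edges

    net = eb.generate_background_network(
        gene_ids, 60, seed=seed + 1, include_pairs=signal_edges(gene_ids, plan)
    )
    return ds, eb.edge_feature_matrix(ds, eb.restrict_network(net, ds))


class TestRunCV:
    def test_strong_signal_high_auc(self):
        ds, fm = strong_signal_problem()
        cfg = CVConfig(n_folds=5, n_repetitions=3, model="RF", seed=3)
        metrics = eb.run_cv(fm, ds.labels, cfg)
        assert metrics["AUC"].mean > 0.9
        assert 0.0 <= metrics["F1"].mean <= 1.0

    def test_permuted_labels_chance_auc(self):
        ds, fm = strong_signal_problem()
        rng = np.random.default_rng(5)
        y = rng.permutation(ds.labels)
        cfg = CVConfig(n_folds=5, n_repetitions=10, model="RF", seed=4)
        auc = eb.run_cv(fm, y, cfg)["AUC"].mean
        assert 0.35 < auc < 0.65

    def test_same_seed_identical(self):
        ds, fm = strong_signal_problem()
        cfg = CVConfig(n_folds=3, n_repetitions=2, model="RF", rf_estimators=25, seed=11)
        a = eb.run_cv(fm, ds.labels, cfg)
        b = eb.run_cv(fm, ds.labels, cfg)
        for m in ("AUC", "F1", "Kappa"):
            assert np.array_equal(a[m].values, b[m].values)

    def test_optimal_threshold_mode_runs(self):
        ds, fm = strong_signal_problem()
        cfg = CVConfig(
            n_folds=4, n_repetitions=2, model="RF", rf_estimators=50,
            threshold_mode="optimal", seed=6,
        )
        metrics = eb.run_cv(fm, ds.labels, cfg)
        assert metrics["AUC"].mean > 0.8
        assert metrics["Kappa"].mean > 0.0

    @pytest.mark.parametrize("model", ["SVM", "LR"])
    def test_linear_models_smoke(self, model):
        ds, fm = strong_signal_problem()
        cfg = CVConfig(n_folds=3, n_repetitions=1, model=model, seed=7)
        metrics = eb.run_cv(fm, ds.labels, cfg)
        assert metrics["AUC"].mean > 0.7


class TestSummarizeComparison:
    def test_win_ss(self):
        rng = np.random.default_rng(0)
        gene = eb.MetricVector("AUC", rng.normal(0.7, 0.01, 50))
        edge = eb.MetricVector("AUC", gene.values + 0.05)
        summary = eb.summarize_comparison(edge, gene)
        assert summary.outcome == "Win-SS" and summary.p_value < 0.05

    def test_lose_nss(self):
        rng = np.random.default_rng(1)
        gene = eb.MetricVector("AUC", rng.normal(0.7, 0.05, 10))
        edge = eb.MetricVector("AUC", gene.values - 0.001 + 0.05 * rng.normal(size=10))
        summary = eb.summarize_comparison(edge, gene)
        assert summary.outcome.startswith(("Lose", "Win"))
        if summary.mean_difference < 0 and summary.p_value >= 0.05:
            assert summary.outcome == "Lose-NSS"

    def test_equal_vectors(self):
        v = eb.MetricVector("AUC", np.full(10, 0.8))
        assert eb.summarize_comparison(v, v).outcome == "Equal/NaN"
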
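import math

import numpy as np
import pytest

from clpmi.benchmarks import (
    CROSS_SPECIES_CV,
    CROSS_SPECIES_TEST,
    DATASET_COUNTS,
    HUMAN_CV,
    NEW_TEST,
    PROPOSED_ROWS,
    best_competitor,
    pooled_counts,
)
from clpmi.metrics import (
    ConfusionCounts,
    UndefinedMetricError,
    aupr,
    auroc,
    confusion,
    evaluate,
    g_mean,
    metrics_from_counts,
    relative_improvement,
)


def auroc_oracle(scores, labels):
    """Trapezoidal integration of the ROC curve over every threshold."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    P, N = (labels == 1).sum(), (labels == 0).sum()
    tpr = [(scores[labels == 1] >= t).sum() / P for t in thresholds] + [1.0]
    fpr = [(scores[labels == 0] >= t).sum() / N for t in thresholds] + [1.0]
    return np.trapezoid(tpr, fpr)


def aupr_oracle(scores, labels):
    """Exhaustive threshold sweep, precision held constant between recalls."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    P = labels.sum()
    area, prev_recall = 0.0, 0.0
    tp = 0
    scores_sorted = scores[order]
    for i in range(len(labels)):
        tp += labels[i]
        # threshold boundaries fall between distinct score values
        if i + 1 < len(labels) and scores_sorted[i + 1] == scores_sorted[i]:
            continue
        recall = tp / P
        precision = tp / (i + 1)
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


class TestConfusion:
    def test_simple_counts(self):
        c = confusion([0.9, 0.2], [1, 0])
        assert (c.TP, c.TN, c.FP, c.FN) == (1, 1, 0, 0)

    def test_all_negative(self):
        c = confusion([0.0] * 5, [0] * 5)
        assert c.TN == 5 and c.total == 5

    def test_matches_counting_loop_on_random_case(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        c = confusion(scores, labels)
        tp = sum(1 for s, y in zip(scores, labels) if s >= 0.5 and y == 1)
        tn = sum(1 for s, y in zip(scores, labels) if s < 0.5 and y == 0)
        fp = sum(1 for s, y in zip(scores, labels) if s >= 0.5 and y == 0)
        fn = sum(1 for s, y in zip(scores, labels) if s < 0.5 and y == 1)
        assert (c.TP, c.TN, c.FP, c.FN) == (tp, tn, fp, fn)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion([], [])


class TestThresholdMetrics:
    def test_perfect_classifier(self):
        rep = metrics_from_counts(ConfusionCounts(TP=50, TN=50, FP=0, FN=0))
        assert (rep.SE, rep.SP, rep.PPV, rep.F_score, rep.g_mean) == (1, 1, 1, 1, 1)

    @pytest.mark.parametrize(
        "se,sp,expected",
        [(0.977, 0.910, 0.943), (0.970, 0.907, 0.938)],
    )
    def test_g_mean_reproduces_reported_values(self, se, sp, expected):
        assert round(g_mean(se, sp), 3) == expected

    def test_ppv_flagged_when_no_positive_calls(self):
        rep = metrics_from_counts(ConfusionCounts(TP=0, TN=10, FP=0, FN=2))
        assert rep.PPV == 0.0 and not rep.ppv_defined

    def test_g_mean_squared_identity(self, rng):
        for _ in range(20):
            counts = ConfusionCounts(*rng.integers(1, 100, 4))
            rep = metrics_from_counts(counts)
            assert rep.g_mean**2 == pytest.approx(rep.SE * rep.SP, abs=1e-12)

    def test_f_score_recomputable_from_counts(self, rng):
        c = ConfusionCounts(*rng.integers(1, 100, 4))
        rep = metrics_from_counts(c)
        assert rep.F_score == pytest.approx(2 * c.TP / (2 * c.TP + c.FP + c.FN))


class TestRankingMetrics:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert aupr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auroc([0.5, 0.6], [1, 1])
        with pytest.raises(UndefinedMetricError):
            aupr([0.5, 0.6], [0, 0])

    def test_random_scores_near_half_auroc_and_prevalence_aupr(self):
        rng = np.random.default_rng(99)
        n = 10_000
        scores = rng.random(n)
        labels = rng.random(n) < 0.2
        assert auroc(scores, labels) == pytest.approx(0.5, abs=0.02)
        assert aupr(scores, labels) == pytest.approx(0.2, abs=0.02)

    def test_toy_set_matches_exhaustive_sweep(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.65, 0.05]
        labels = [0, 0, 1, 1, 1, 0]
        assert auroc(scores, labels) == pytest.approx(auroc_oracle(scores, labels))
        assert aupr(scores, labels) == pytest.approx(aupr_oracle(scores, labels))

    def test_matches_oracles_on_random_draws(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            scores = rng.random(n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auroc(scores, labels) == pytest.approx(
                auroc_oracle(scores, labels), abs=1e-12
            )
            assert aupr(scores, labels) == pytest.approx(
                aupr_oracle(scores, labels), abs=1e-12
            )

    def test_auroc_invariant_under_monotone_transform(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        base = auroc(scores, labels)
        for f in (lambda s: 2 * s + 3, np.exp, lambda s: s**3):
            assert auroc(f(scores), labels) == pytest.approx(base, abs=1e-12)

    def test_aupr_at_least_prevalence_when_some_positive_ranks_top(self):
        scores = np.array([0.99, 0.4, 0.3, 0.2, 0.1])
        labels = np.array([1, 0, 1, 0, 0])
        assert aupr(scores, labels) >= labels.mean()


class TestRelativeImprovement:
    @pytest.mark.parametrize(
        "ours,other,expected",
        [(0.995, 0.903, 10.19), (0.990, 0.911, 8.67), (0.5, 0.5, 0.0)],
    )
    def test_examples(self, ours, other, expected):
        assert relative_improvement(ours, other) == expected

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            relative_improvement(0.5, 0.0)


class TestBenchmarkArithmetic:
    """Consistency of the published comparison tables with the metric code."""

    def test_pooled_example_totals(self):
        assert pooled_counts() == (3230, 23934)

    def test_imbalance_ratio_rounds_to_published_value(self):
        pos, neg = pooled_counts()
        assert round(neg / pos, 1) == 7.4

    def test_gmean_internally_consistent_for_all_proposed_rows(self):
        for name, row in PROPOSED_ROWS.items():
            assert round(g_mean(row["SE"], row["SP"]), 3) == pytest.approx(
                row["g_mean"], abs=5e-4
            ), name

    @pytest.mark.parametrize(
        "table,metric,expected",
        [
            (CROSS_SPECIES_CV, "SE", 10.19),
            (CROSS_SPECIES_CV, "g_mean", 3.40),
            (CROSS_SPECIES_CV, "F_score", 10.47),
            (CROSS_SPECIES_CV, "PPV", 8.67),
            (HUMAN_CV, "F_score", 16.45),
            (HUMAN_CV, "SE", 12.64),
            (HUMAN_CV, "PPV", 11.71),
            (HUMAN_CV, "g_mean", 3.89),
        ],
    )
    def test_cv_improvements_over_best_competitor(self, table, metric, expected):
        ours = table["Proposed"][metric]
        assert relative_improvement(ours, best_competitor(table, metric)) == expected

    def test_cross_species_test_se_improvement_over_dcnn(self):
        ours = CROSS_SPECIES_TEST["Proposed"]["SE"]
        dcnn = CROSS_SPECIES_TEST["DCNN fixed-sized"]["SE"]
        assert relative_improvement(ours, dcnn) == 8.08

    @pytest.mark.parametrize(
        "metric,baseline,expected",
        [
            ("SE", "miRBoost", 5.32),
            ("PPV", "DCNN variable-sized", 27.34),
            ("F_score", "DCNN variable-sized", 20.07),
        ],
    )
    def test_new_dataset_improvements(self, metric, baseline, expected):
        ours = NEW_TEST["Proposed"][metric]
        assert relative_improvement(ours, NEW_TEST[baseline][metric]) == expected

    def test_dataset_counts_match_published_table(self):
        assert DATASET_COUNTS["cross-species"] == (1677, 8266)
        assert DATASET_COUNTS["human"] == (863, 7422)
        assert DATASET_COUNTS["new"] == (690, 8246)


def test_evaluate_combines_threshold_and_ranking(rng):
    scores = rng.random(60)
    labels = (scores + rng.normal(0, 0.3, 60) > 0.5).astype(int)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    rep = evaluate(scores, labels)
    assert rep.AUROC is not None and rep.AUPR is not None
    assert math.isclose(rep.g_mean, math.sqrt(rep.SE * rep.SP), abs_tol=1e-12)
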
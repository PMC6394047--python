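"""Confusion metrics, Hanley-McNeil AUC, ROC consistency and group
summaries."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from reosig import (
    ClassLabels,
    ExpressionMatrix,
    Signature,
    confusion_metrics,
    evaluate_results,
    format_percent,
    group_pair_summaries,
    hanley_mcneil_auc,
    roc_points,
    trapezoidal_auc,
)
from reosig.classify import VoteResult

from conftest import mann_whitney_oracle


def _results(labels_by_sample):
    return [
        VoteResult(sid, 2 if lab == "GC" else 0, 2,
                   1.0 if lab == "GC" else 0.0, lab)
        for sid, lab in labels_by_sample.items()
    ]


def _make(n_gc, tp, n_non, tn):
    truth = {}
    predicted = {}
    for i in range(n_gc):
        sid = f"gc{i}"
        truth[sid] = "GC"
        predicted[sid] = "GC" if i < tp else "non-GC"
    for i in range(n_non):
        sid = f"nn{i}"
        truth[sid] = "NORMAL"
        predicted[sid] = "non-GC" if i < tn else "GC"
    return _results(predicted), ClassLabels(pd.Series(truth))


class TestConfusionMetrics:
    def test_published_style_percent_rounding(self):
        results, truth = _make(158, 153, 79, 76)
        report = confusion_metrics(results, truth)
        assert format_percent(report.sensitivity) == "96.84%"
        assert format_percent(report.specificity) == "96.20%"

    def test_all_correct(self):
        results, truth = _make(10, 10, 8, 8)
        r = confusion_metrics(results, truth)
        assert r.sensitivity == r.specificity == r.accuracy == 1.0

    def test_accuracy_decomposition_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_gc = int(rng.integers(2, 40))
            n_non = int(rng.integers(2, 40))
            tp = int(rng.integers(0, n_gc + 1))
            tn = int(rng.integers(0, n_non + 1))
            r = confusion_metrics(*_make(n_gc, tp, n_non, tn))
            assert r.accuracy == pytest.approx(
                (r.sensitivity * n_gc + r.specificity * n_non) / (n_gc + n_non)
            )

    def test_gc_adjacent_scored_on_the_gc_side_by_default(self):
        truth = ClassLabels(
            pd.Series({"a": "GC_ADJ", "b": "GC", "c": "NORMAL", "d": "GASTRITIS"})
        )
        results = _results({"a": "GC", "b": "GC", "c": "non-GC", "d": "non-GC"})
        r = confusion_metrics(results, truth)
        assert r.n_gc == 2 and r.sensitivity == 1.0
        r2 = confusion_metrics(results, truth, gc_adj_as_gc=False)
        assert r2.n_gc == 1 and r2.n_non == 3 and r2.specificity == pytest.approx(2 / 3)

    def test_abstentions_reported_separately(self):
        results, truth = _make(4, 4, 4, 4)
        results.append(VoteResult("x", 0, 2, float("nan"), None, abstained=True))
        truth = ClassLabels(pd.concat([truth.labels, pd.Series({"x": "GC"})]))
        r = confusion_metrics(results, truth)
        assert r.n_abstained == 1 and r.n_gc == 4


class TestHanleyMcNeilAuc:
    def test_exhaustive_four_comparison_example(self):
        # GC (0.9, 0.3) vs non-GC (0.5, 0.1): win, win, loss, win
        auc, se, ci = hanley_mcneil_auc(
            [0.9, 0.3, 0.5, 0.1], [True, True, False, False]
        )
        assert auc == pytest.approx(0.75)

    def test_perfect_separation_has_zero_se(self):
        auc, se, ci = hanley_mcneil_auc([1, 1, 0, 0], [True, True, False, False])
        assert auc == 1.0 and se == 0.0 and ci == (1.0, 1.0)

    def test_identical_scores_give_half(self):
        auc, se, ci = hanley_mcneil_auc([0.5] * 6, [True] * 3 + [False] * 3)
        assert auc == 0.5
        assert ci[0] >= 0.0 and ci[1] <= 1.0

    def test_matches_pairwise_oracle_and_scipy(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(6, 25))
            scores = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=n)
            truth = rng.random(n) < 0.5
            if truth.all() or not truth.any():
                continue
            auc, _, _ = hanley_mcneil_auc(scores, truth)
            assert abs(auc - mann_whitney_oracle(scores, truth)) < 1e-12
            u = scipy.stats.mannwhitneyu(
                scores[truth], scores[~truth], alternative="two-sided"
            ).statistic
            assert auc == pytest.approx(u / (truth.sum() * (~truth).sum()))

    def test_se_formula_terms(self):
        # hand-computed Hanley-McNeil SE for A=0.75, n+=2, n-=2
        auc, se, _ = hanley_mcneil_auc(
            [0.9, 0.3, 0.5, 0.1], [True, True, False, False]
        )
        a = 0.75
        q1 = a / (2 - a)
        q2 = 2 * a * a / (1 + a)
        expected = np.sqrt(
            (a * (1 - a) + (q1 - a * a) + (q2 - a * a)) / 4
        )
        assert se == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            hanley_mcneil_auc([1.0, 0.5], [True, True])


class TestRoc:
    def test_perfect_separation_passes_through_corner(self):
        pts = roc_points([1, 1, 0, 0], [True, True, False, False])
        assert ((pts.fpr == 0) & (pts.tpr == 1)).any()

    def test_identical_scores_area_half(self):
        pts = roc_points([0.3] * 6, [True] * 3 + [False] * 3)
        assert trapezoidal_auc(pts) == pytest.approx(0.5)

    def test_trapezoid_equals_mann_whitney_on_random_scores(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(8, 30))
            scores = rng.choice([0.0, 0.5, 1.0], size=n)
            truth = rng.random(n) < 0.5
            if truth.all() or not truth.any():
                continue
            area = trapezoidal_auc(roc_points(scores, truth))
            assert abs(area - mann_whitney_oracle(scores, truth)) < 1e-12

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(9)
        scores = rng.random(40)
        truth = rng.random(40) < 0.4
        pts = roc_points(scores, truth)
        assert (np.diff(pts.fpr) >= 0).all() and (np.diff(pts.tpr) >= 0).all()


class TestEvaluateResults:
    def test_full_report_combines_metrics_and_auc(self):
        results, truth = _make(20, 19, 10, 10)
        report = evaluate_results(results, truth)
        assert report.auc is not None and report.ci95[1] <= 1.0
        assert report.accuracy == pytest.approx(29 / 30)
        assert "AUC" in report.summary()


class TestGroupPairSummaries:
    def test_direct_arithmetic(self):
        df = pd.DataFrame(
            {
                "g1": [10.0, 5.0], "g2": [20.0, 8.0],
                "n1": [3.0, 3.0], "n2": [4.0, 4.0],
            },
            index=["CYR61", "MMP28"],
        )
        truth = ClassLabels(
            pd.Series({"g1": "GC", "g2": "GC", "n1": "NORMAL", "n2": "NORMAL"})
        )
        sig = Signature(pairs=[("CYR61", "MMP28")])
        out = group_pair_summaries(ExpressionMatrix(df), truth, sig)
        gc = next(s for s in out if s.group == "GC")
        assert gc.median_fold_change == pytest.approx(2.25)  # median of (2, 2.5)
        assert gc.median_difference == pytest.approx(8.5)  # median of (5, 12)
        non = next(s for s in out if s.group == "non-GC")
        assert non.median_fold_change == pytest.approx(1.0)
        assert non.median_difference == pytest.approx(0.0)

    def test_single_sample_group_and_zero_denominator(self):
        df = pd.DataFrame(
            {"g1": [6.0, 3.0], "n1": [0.0, 0.0], "n2": [2.0, 1.0]},
            index=["A", "B"],
        )
        truth = ClassLabels(pd.Series({"g1": "GC", "n1": "NORMAL", "n2": "NORMAL"}))
        sig = Signature(pairs=[("A", "B")])
        out = group_pair_summaries(ExpressionMatrix(df), truth, sig)
        gc = next(s for s in out if s.group == "GC")
        assert gc.median_fold_change == 2.0 and gc.median_difference == 3.0
        non = next(s for s in out if s.group == "non-GC")
        assert non.n_skipped_fc == 1  # n1 has B == 0
        assert non.median_fold_change == pytest.approx(2.0)
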
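"""Confusion counts, ROC curves and corpus summaries."""

import random

import numpy as np
import pytest

from cbmfia.core import ValidationError
from cbmfia.evaluate import (
    binding_prediction_rates,
    confusion_at_threshold,
    roc_curve,
    summarize_alignment_stats,
    summarize_template_usage,
)
from cbmfia.fia import PairwiseAlignment
from cbmfia.fixtures import generate_template_set
from cbmfia.model_select import ModelCandidate


def _sites(n_pos, n_neg, rng, lo=0, hi=200):
    scores = {}
    positives, negatives = set(), set()
    for i in range(n_pos):
        scores[("p", i)] = rng.randint(lo, hi)
        positives.add(("p", i))
    for i in range(n_neg):
        scores[("n", i)] = rng.randint(lo, hi)
        negatives.add(("n", i))
    return scores, positives, negatives


class TestConfusion:
    def test_rate_arithmetic(self):
        scores = {("p", i): (150 if i < 72 else 50) for i in range(97)}
        scores.update({("n", i): 10 for i in range(558)})
        positives = {("p", i) for i in range(97)}
        negatives = {("n", i) for i in range(558)}
        c = confusion_at_threshold(scores, positives, negatives, 97)
        assert (c.tp, c.fn) == (72, 25)
        assert c.tpr == pytest.approx(72 / 97)
        assert c.fpr == 0.0

    def test_threshold_zero_predicts_everything(self):
        rng = random.Random(1)
        scores, pos, neg = _sites(10, 20, rng, lo=1)
        c = confusion_at_threshold(scores, pos, neg, 0)
        assert c.tpr == 1.0 and c.fpr == 1.0

    def test_threshold_above_max_predicts_nothing(self):
        rng = random.Random(2)
        scores, pos, neg = _sites(10, 20, rng)
        c = confusion_at_threshold(scores, pos, neg, max(scores.values()) + 1)
        assert c.tp == 0 and c.fp == 0

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValidationError):
            confusion_at_threshold({("a", 1): 5}, {("a", 1)}, {("a", 1)}, 0)

    def test_conservation_across_thresholds(self):
        rng = random.Random(3)
        scores, pos, neg = _sites(30, 50, rng)
        for threshold in range(0, 220, 13):
            c = confusion_at_threshold(scores, pos, neg, threshold)
            assert c.tp + c.fn == 30
            assert c.fp + c.tn == 50


class TestRoc:
    def test_perfect_separation_passes_corner(self):
        scores = {("p", i): 100 for i in range(5)}
        scores.update({("n", i): 0 for i in range(5)})
        curve = roc_curve(scores, set(list(scores)[:5]), set(list(scores)[5:]))
        points = {(c.fpr, c.tpr) for _, c in curve.points}
        assert (0.0, 1.0) in points
        assert curve.auc() == pytest.approx(1.0)

    def test_constant_scores_give_two_endpoint_curve(self):
        scores = {("x", i): 7 for i in range(10)}
        curve = roc_curve(scores, {("x", i) for i in range(5)},
                          {("x", i) for i in range(5, 10)})
        assert [(c.fpr, c.tpr) for _, c in curve.points] == [(1.0, 1.0), (0.0, 0.0)]
        assert curve.auc() == pytest.approx(0.5)

    def test_endpoints_and_monotonicity(self):
        rng = random.Random(4)
        scores, pos, neg = _sites(40, 60, rng)
        curve = roc_curve(scores, pos, neg)
        rates = [(c.fpr, c.tpr) for _, c in curve.points]
        assert rates[0] == (1.0, 1.0)
        assert rates[-1] == (0.0, 0.0)
        # threshold ascending => rates non-increasing
        for (f1, t1), (f2, t2) in zip(rates, rates[1:]):
            assert f2 <= f1 and t2 <= t1

    def test_matches_naive_per_threshold_recount(self):
        rng = random.Random(5)
        scores, pos, neg = _sites(300, 700, rng)
        curve = roc_curve(scores, pos, neg)
        for threshold, counts in curve.points:
            tp = sum(scores[s] >= threshold for s in pos)
            fp = sum(scores[s] >= threshold for s in neg)
            assert (counts.tp, counts.fp) == (tp, fp)

    def test_auc_agrees_with_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = random.Random(6)
        scores, pos, neg = _sites(80, 120, rng, lo=0, hi=30)
        curve = roc_curve(scores, pos, neg)
        y = [1] * len(pos) + [0] * len(neg)
        x = [scores[s] for s in pos] + [scores[s] for s in neg]
        assert curve.auc() == pytest.approx(
            sklearn_metrics.roc_auc_score(y, x), abs=1e-12
        )

    def test_empty_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_curve({("a", 1): 3}, {("a", 1)}, set())


class TestBindingRates:
    def test_synthetic_templates_yield_consistent_rates(self):
        templates = generate_template_set(6, length=80, n_binding=2, seed=5)
        result = binding_prediction_rates(templates, threshold=97)
        # every planted positive scores >= 132, so TPR is 100% by design
        assert result["tp_rate_pct"] == pytest.approx(100.0)
        assert 0.0 <= result["fp_rate_pct"] <= 100.0
        assert result["n_positives"] == 12
        assert result["auc"] >= 0.5

    def test_raising_threshold_cannot_raise_rates(self):
        templates = generate_template_set(6, length=80, n_binding=2, seed=5)
        low = binding_prediction_rates(templates, threshold=97)
        high = binding_prediction_rates(templates, threshold=150)
        assert high["tp_rate_pct"] <= low["tp_rate_pct"]
        assert high["fp_rate_pct"] <= low["fp_rate_pct"]


def _stub_alignment(ident, ncols):
    return PairwiseAlignment(
        target_id="t", template_id="p", t_row="A" * ncols, p_row="A" * ncols,
        score=0.0, ident=ident, sim=ident, gap_openings=0,
    )


class TestSummaries:
    def test_self_alignments_average_100(self):
        stats = summarize_alignment_stats([_stub_alignment(10, 10)] * 4)
        assert stats["mean_identity_pct"] == 100.0
        assert stats["n_alignments"] == 4

    def test_mean_of_two_levels(self):
        stats = summarize_alignment_stats(
            [_stub_alignment(2, 10), _stub_alignment(4, 10)]
        )
        assert stats["mean_identity_pct"] == pytest.approx(30.0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            summarize_alignment_stats([])

    def _candidate(self, origin):
        alns = (
            (_stub_alignment(1, 4),)
            if origin == "single"
            else (_stub_alignment(1, 4),
                  PairwiseAlignment(
                      target_id="t", template_id="q", t_row="AAAA",
                      p_row="AAAA", score=0.0, ident=1, sim=1, gap_openings=0))
        )
        return ModelCandidate(alignments=alns)

    def test_usage_percentages(self):
        top5 = [self._candidate("double")] * 3 + [self._candidate("single")] * 2
        usage = summarize_template_usage([top5])
        assert usage["pct_double"] == pytest.approx(60.0)
        assert usage["pct_single"] == pytest.approx(40.0)

    def test_all_double(self):
        usage = summarize_template_usage([[self._candidate("double")] * 5] * 3)
        assert usage["pct_double"] == 100.0

    def test_oversized_list_rejected(self):
        with pytest.raises(ValidationError):
            summarize_template_usage([[self._candidate("single")] * 6])

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            summarize_template_usage([])
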
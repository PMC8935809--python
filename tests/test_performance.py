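import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import accuracy_score, matthews_corrcoef

from nitrenium.fixtures import synthetic_scores
from nitrenium.performance import (ConfusionCounts, compute_metrics,
                                   confusion_counts, cutoff_sweep,
                                   default_grid, format_row, round_half_up)


def _counts(tp, fp, tn, fn, inc=0, ood=0):
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, n_inconclusive=inc,
                           n_out_of_domain=ood)


class TestConfusionCounts:
    def test_basic_tally(self):
        preds = ["mutagenic"] * 5 + ["nonmutagenic"] * 5
        labels = ["mutagen"] * 5 + ["nonmutagen"] * 5
        c = confusion_counts(preds, labels)
        assert (c.tp, c.fp, c.tn, c.fn) == (5, 0, 5, 0)

    def test_all_inconclusive(self):
        c = confusion_counts(["inconclusive"] * 4,
                             ["mutagen", "mutagen", "nonmutagen", "nonmutagen"])
        assert c.covered == 0
        assert c.n_inconclusive == 4
        assert compute_metrics(c).coverage == 0.0
        assert compute_metrics(c).accuracy is None

    def test_exclusion_from_denominator(self):
        preds = (["mutagenic"] * 4 + ["nonmutagenic"] * 4
                 + ["inconclusive"] * 2)
        labels = ["mutagen"] * 4 + ["nonmutagen"] * 4 + ["mutagen"] * 2
        c = confusion_counts(preds, labels)
        m = compute_metrics(c)
        assert c.covered == 8
        assert m.accuracy == pytest.approx(100.0)
        assert m.coverage == pytest.approx(80.0)

    def test_out_of_domain_counted_separately(self):
        c = confusion_counts(["out_of_domain", "mutagenic"],
                             ["mutagen", "mutagen"])
        assert c.n_out_of_domain == 1 and c.tp == 1
        assert c.total == 2

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_counts(["mutagenic"], [])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(["mutagenic"], ["positive"])


class TestMetricFormulas:
    def test_reconstructed_benchmark_row(self):
        """Confusion table reconstructed from the original 85-compound
        validation (51 mutagens / 34 nonmutagens): all seven statistics."""
        m = compute_metrics(_counts(tp=38, fp=13, tn=21, fn=13))
        assert round_half_up(m.accuracy) == 69.4
        assert round_half_up(m.sensitivity) == 74.5
        assert round_half_up(m.specificity) == 61.8
        assert round_half_up(m.ppv) == 74.5
        assert round_half_up(m.npv) == 61.8
        assert round_half_up(m.mcc) == 0.4
        assert m.mcc == pytest.approx(629 / 1734, abs=1e-12)
        assert m.coverage == pytest.approx(100.0)

    def test_perfect_classifier(self):
        m = compute_metrics(_counts(tp=10, fp=0, tn=10, fn=0))
        for v in (m.accuracy, m.sensitivity, m.specificity, m.ppv, m.npv,
                  m.coverage):
            assert v == pytest.approx(100.0)
        assert m.mcc == pytest.approx(1.0)

    def test_degenerate_denominators_absent_not_zero(self):
        # all-positive predictor on balanced labels: npv has no denominator
        m = compute_metrics(_counts(tp=5, fp=5, tn=0, fn=0))
        assert m.specificity == 0.0
        assert m.npv is None
        assert m.mcc is None
        assert format_row(m)["npv"] == "N/A"

    def test_oracle_equivalence_random_tables(self, rng):
        """Metrics agree with brute-force recounts (and scikit-learn) on
        1000 random prediction/label sets."""
        for _ in range(1000):
            n = rng.integers(1, 40)
            labels = rng.choice(["mutagen", "nonmutagen"], n).tolist()
            preds = rng.choice(
                ["mutagenic", "nonmutagenic", "inconclusive"], n).tolist()
            c = confusion_counts(preds, labels)
            m = compute_metrics(c)
            pairs = [(p, l) for p, l in zip(preds, labels)
                     if p != "inconclusive"]
            assert c.covered == len(pairs)
            if not pairs:
                assert m.accuracy is None
                continue
            y_true = [l == "mutagen" for _, l in pairs]
            y_pred = [p == "mutagenic" for p, _ in pairs]
            assert m.accuracy == pytest.approx(
                100.0 * accuracy_score(y_true, y_pred))
            if m.mcc is not None and len(set(y_true)) == 2 \
                    and len(set(y_pred)) == 2:
                assert m.mcc == pytest.approx(
                    matthews_corrcoef(y_true, y_pred), abs=1e-12)

    def test_accuracy_is_prevalence_weighted_average(self, rng):
        """accuracy = prevalence*sensitivity + (1-prevalence)*specificity."""
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(1, 30, 4)
            m = compute_metrics(_counts(tp=tp, fp=fp, tn=tn, fn=fn))
            prev = (tp + fn) / (tp + fp + tn + fn)
            assert m.accuracy == pytest.approx(
                prev * m.sensitivity + (1 - prev) * m.specificity)


class TestMetricProperties:
    @given(tp=st.integers(0, 50), fp=st.integers(0, 50),
           tn=st.integers(0, 50), fn=st.integers(0, 50))
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_bounds_and_accuracy_between_sens_and_spec(self, tp, fp, tn, fn):
        m = compute_metrics(_counts(tp=tp, fp=fp, tn=tn, fn=fn))
        for v in (m.accuracy, m.sensitivity, m.specificity, m.ppv, m.npv,
                  m.coverage):
            assert v is None or 0.0 <= v <= 100.0
        if m.mcc is not None:
            assert -1.0 <= m.mcc <= 1.0 + 1e-12
        if None not in (m.accuracy, m.sensitivity, m.specificity):
            lo = min(m.sensitivity, m.specificity) - 1e-9
            hi = max(m.sensitivity, m.specificity) + 1e-9
            assert lo <= m.accuracy <= hi

    @given(st.lists(st.floats(-30, 30, allow_nan=False), min_size=1,
                    max_size=20),
           st.floats(-10, 10, allow_nan=False))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_classification_monotone_in_cutoff(self, values, cutoff):
        """Raising the cutoff can only move predictions toward mutagenic."""
        from nitrenium.scoring import classify
        for v in values:
            a = classify(v, cutoff)
            b = classify(v, cutoff + 1.0)
            assert not (a == "mutagenic" and b == "nonmutagenic")


class TestCutoffSweep:
    def test_default_grid(self):
        grid = default_grid()
        assert len(grid) == 9
        assert grid[0] == -10.0 and grid[-1] == 10.0
        assert grid[1] - grid[0] == 2.5

    def test_recovers_separating_cutoff(self):
        """Synthetic Gaussian scores with the analytic optimum at the class
        midpoint: the best grid cutoff lands within one step of 0."""
        scores, labels = synthetic_scores(500, 500, -8.0, 8.0, 5.0, seed=13)
        rows, best = cutoff_sweep(scores.tolist(), labels)
        assert abs(best.cutoff) <= 2.5

    def test_perfectly_separated(self):
        values = [-3.0] * 5 + [3.0] * 5
        labels = ["mutagen"] * 5 + ["nonmutagen"] * 5
        rows, best = cutoff_sweep(values, labels)
        for row in rows:
            if row.cutoff in (-2.5, 0.0, 2.5):
                assert row.accuracy == pytest.approx(100.0)
        assert best.accuracy == pytest.approx(100.0)
        assert best.cutoff == 0.0  # tie broken toward smaller |cutoff|

    def test_single_point_grid(self):
        rows, best = cutoff_sweep([-1.0, 1.0], ["mutagen", "nonmutagen"],
                                  [0.0])
        assert len(rows) == 1 and best is rows[0]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            cutoff_sweep([1.0], ["mutagen"], [])

    def test_permutation_invariance(self, rng):
        scores, labels = synthetic_scores(30, 30, seed=5)
        perm = rng.permutation(60)
        r1, _ = cutoff_sweep(scores.tolist(), labels)
        r2, _ = cutoff_sweep(scores[perm].tolist(),
                             [labels[i] for i in perm])
        for a, b in zip(r1, r2):
            assert a.accuracy == b.accuracy and a.mcc == b.mcc

    def test_absent_scores_count_as_inconclusive(self):
        values = [None, -5.0, 5.0]
        labels = ["mutagen", "mutagen", "nonmutagen"]
        rows, _ = cutoff_sweep(values, labels, [0.0])
        assert rows[0].coverage == pytest.approx(100.0 * 2 / 3)


class TestRounding:
    def test_half_up(self):
        assert round_half_up(0.05, 1) == 0.1
        assert round_half_up(69.44, 1) == 69.4
        assert round_half_up(-0.25, 1) == -0.2  # toward +inf on ties
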
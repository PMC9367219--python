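"""Confusion matrix, point metrics, summary reconstruction, and bootstrap."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cadval.evaluation import (
    ConfusionMatrix,
    LabeledPair,
    bootstrap_f1,
    confusion,
    expand_cm_to_pairs,
    f1_score,
    metrics,
    reconstruct_from_summary,
)

cm_counts = st.integers(min_value=0, max_value=50)


def pairs_of(*truth_pred: tuple[int, int]) -> list[LabeledPair]:
    return [
        LabeledPair(study_uid=f"u{i}", truth=t, prediction=p)
        for i, (t, p) in enumerate(truth_pred)
    ]


class TestConfusion:
    def test_one_of_each(self):
        cm = confusion(pairs_of((1, 1), (0, 1), (1, 0), (0, 0)))
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 1, 1)

    def test_all_true_positive(self):
        cm = confusion(pairs_of(*[(1, 1)] * 7))
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (7, 0, 0, 0)

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            confusion([])

    def test_permutation_invariant(self):
        pairs = pairs_of((1, 1), (0, 1), (1, 0), (0, 0), (1, 1))
        assert confusion(pairs) == confusion(list(reversed(pairs)))

    @given(tp=cm_counts, fp=cm_counts, fn=cm_counts, tn=cm_counts)
    @settings(max_examples=100, deadline=None)
    def test_expand_round_trip(self, tp, fp, fn, tn):
        cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
        pairs = expand_cm_to_pairs(cm)
        assert len(pairs) == cm.total
        if cm.total:
            assert confusion(pairs) == cm


class TestF1:
    def test_reconstructed_deployment_matrix(self):
        assert f1_score(ConfusionMatrix(tp=1205, fp=729, fn=551, tn=3800)) == (
            pytest.approx(0.653, abs=5e-4)
        )

    def test_perfect(self):
        assert f1_score(ConfusionMatrix(tp=9, fp=0, fn=0, tn=0)) == 1.0

    def test_no_true_positives(self):
        assert f1_score(ConfusionMatrix(tp=0, fp=3, fn=5, tn=0)) == 0.0

    def test_undefined_flagged_not_zero(self):
        assert math.isnan(f1_score(ConfusionMatrix(tp=0, fp=0, fn=0, tn=4)))

    @given(tp=cm_counts, fp=cm_counts, fn=cm_counts, tn=cm_counts)
    @settings(max_examples=200, deadline=None)
    def test_harmonic_mean_identity(self, tp, fp, fn, tn):
        cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
        if tp + fp == 0 or tp + fn == 0:
            return  # precision or recall undefined
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        if precision + recall == 0:
            return
        harmonic = 2 * precision * recall / (precision + recall)
        assert f1_score(cm) == pytest.approx(harmonic, abs=1e-12)


class TestMetrics:
    def test_reconstructed_deployment_matrix(self):
        ms = metrics(ConfusionMatrix(tp=1205, fp=729, fn=551, tn=3800))
        assert ms.accuracy == pytest.approx(0.796, abs=5e-4)
        assert ms.sensitivity == pytest.approx(0.686, abs=5e-4)
        assert ms.specificity == pytest.approx(0.839, abs=5e-4)

    def test_perfect_two_pairs(self):
        ms = metrics(ConfusionMatrix(tp=1, fp=0, fn=0, tn=1))
        assert (ms.accuracy, ms.sensitivity, ms.specificity, ms.precision, ms.f1) == (
            1.0,
            1.0,
            1.0,
            1.0,
            1.0,
        )

    def test_degenerate_denominators_flagged(self):
        ms = metrics(ConfusionMatrix(tp=0, fp=0, fn=5, tn=5))
        assert ms.sensitivity == 0.0
        assert ms.precision is None


class TestReconstructFromSummary:
    def test_deployment_marginals(self):
        cm = reconstruct_from_summary(1756, 4529, 0.686, 0.839)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1205, 729, 551, 3800)

    def test_perfect_rates(self):
        cm = reconstruct_from_summary(10, 10, 1.0, 1.0)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (10, 0, 0, 10)

    def test_empty_positive_class(self):
        cm = reconstruct_from_summary(0, 5, 0.3, 1.0)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (0, 0, 0, 5)

    def test_rounding_half_away_from_zero(self):
        cm = reconstruct_from_summary(10, 0, 0.25, 1.0)  # 2.5 -> 3
        assert cm.tp == 3

    def test_rejects_invalid_rates(self):
        with pytest.raises(ValueError):
            reconstruct_from_summary(10, 10, 1.5, 0.5)


class TestBootstrap:
    def test_all_true_positives_degenerate_free(self):
        result = bootstrap_f1(pairs_of(*[(1, 1)] * 20), n_boot=200, seed=0)
        assert result.mean_f1 == 1.0
        assert (result.ci_low, result.ci_high) == (1.0, 1.0)
        assert result.n_degenerate == 0

    def test_deterministic_for_fixed_seed(self):
        pairs = expand_cm_to_pairs(ConfusionMatrix(tp=30, fp=10, fn=15, tn=45))
        a = bootstrap_f1(pairs, n_boot=500, seed=42)
        b = bootstrap_f1(pairs, n_boot=500, seed=42)
        assert (a.mean_f1, a.ci_low, a.ci_high) == (b.mean_f1, b.ci_low, b.ci_high)
        c = bootstrap_f1(pairs, n_boot=500, seed=43)
        assert (a.mean_f1, a.ci_low, a.ci_high) != (c.mean_f1, c.ci_low, c.ci_high)

    def test_mean_converges_to_point_estimate(self):
        cm = ConfusionMatrix(tp=120, fp=70, fn=55, tn=380)
        pairs = expand_cm_to_pairs(cm)
        point = f1_score(cm)
        large = bootstrap_f1(pairs, n_boot=50_000, seed=0)
        assert large.mean_f1 == pytest.approx(point, abs=0.003)
        other_seed = bootstrap_f1(pairs, n_boot=50_000, seed=1)
        assert large.mean_f1 == pytest.approx(other_seed.mean_f1, abs=0.003)

    def test_ci_width_scales_as_inverse_sqrt_n(self):
        full = expand_cm_to_pairs(ConfusionMatrix(tp=1205, fp=729, fn=551, tn=3800))
        half = expand_cm_to_pairs(ConfusionMatrix(tp=602, fp=364, fn=276, tn=1900))
        width_full = np.diff(
            [bootstrap_f1(full, n_boot=4000, seed=0).ci_low,
             bootstrap_f1(full, n_boot=4000, seed=0).ci_high]
        )[0]
        result_half = bootstrap_f1(half, n_boot=4000, seed=0)
        width_half = result_half.ci_high - result_half.ci_low
        assert width_half / width_full == pytest.approx(math.sqrt(2), rel=0.15)

    def test_degenerate_replicates_counted(self):
        # one TP among many TNs: some replicates draw no positives at all
        pairs = pairs_of((1, 1), *[(0, 0)] * 40)
        result = bootstrap_f1(pairs, n_boot=2000, seed=7)
        assert result.n_degenerate > 0
        assert result.n_degenerate < 2000
        assert 0 <= result.mean_f1 <= 1

    def test_all_degenerate_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            bootstrap_f1(pairs_of((0, 0), (0, 0)), n_boot=50, seed=0)

    def test_rejects_empty_and_bad_nboot(self):
        with pytest.raises(ValueError):
            bootstrap_f1([], n_boot=10, seed=0)
        with pytest.raises(ValueError):
            bootstrap_f1(pairs_of((1, 1)), n_boot=0, seed=0)


def test_labeled_pair_validates_binary_fields():
    with pytest.raises(ValueError):
        LabeledPair(study_uid="u", truth=2, prediction=0)
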
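"""Task mapping, LOO SVM, metric arithmetic, contingencies, heatmaps."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octmargin.evaluate import (
    FLUORESCENCE_GUIDANCE_COUNTS,
    POSTOP_MRI_COUNTS,
    TASKS,
    ContingencyCounts,
    TaskSpec,
    agreement_heatmap,
    assign_task_labels,
    balanced_accuracy_from_rates,
    compute_metrics,
    contingency_from_outcomes,
    loo_svm_evaluate,
    make_task_one,
    round_half_away,
)
from octmargin.params import TissueLabel
from octmargin.visual import VisualClass


class TestTaskMapping:
    def test_task_one_includes_all_six_labels(self):
        labels = [l for l in TissueLabel] * 2
        mask, y = assign_task_labels(labels, "I")
        assert mask.all()
        positives = {l for l, flag in zip(labels, y) if flag}
        assert positives == {
            TissueLabel.WM0_30, TissueLabel.WM30_60,
            TissueLabel.WM60plus, TissueLabel.WME,
        }

    def test_task_three_excludes_intermediate_labels(self):
        labels = list(TissueLabel)
        mask, y = assign_task_labels(labels, "III")
        included = {l for l, m in zip(labels, mask) if m}
        assert included == {TissueLabel.WM0, TissueLabel.WM60plus}
        assert list(y) == [0, 1]

    def test_single_class_input_rejected(self):
        with pytest.raises(ValueError, match="one class"):
            assign_task_labels([TissueLabel.WM0] * 5, "II")

    def test_task_one_edema_assignment_is_configurable(self):
        assert TissueLabel.WME in make_task_one(edema_positive=True).positives
        assert TissueLabel.WME not in make_task_one(edema_positive=False).positives

    def test_task_spec_validation(self):
        with pytest.raises(ValueError, match="subset"):
            TaskSpec("X", frozenset({TissueLabel.WM0}),
                     frozenset({TissueLabel.WME}))
        with pytest.raises(ValueError, match="negative"):
            TaskSpec("X", frozenset({TissueLabel.WM0}),
                     frozenset({TissueLabel.WM0}))


def clustered_features(rng, n_patients=6, per_patient=20, gap=8.0):
    """Two well-separated feature clusters, half of each patient's rows per class."""
    rows, labels, pids = [], [], []
    for p in range(n_patients):
        for k in range(per_patient):
            y = k % 2
            rows.append(rng.normal([0, 0, 0] if y == 0 else [gap, gap, gap], 1.0))
            labels.append(y)
            pids.append(f"P{p}")
    return np.asarray(rows), np.asarray(labels), np.asarray(pids)


class TestLooSvm:
    def test_separable_clusters_score_high(self):
        X, y, pids = clustered_features(np.random.default_rng(0))
        report = loo_svm_evaluate(X, y, pids, cost=0.1)
        assert report.balanced_accuracy_pct >= 95.0
        assert len(report.per_fold) == 6

    def test_shuffled_labels_score_at_chance(self):
        rng = np.random.default_rng(1)
        X, y, pids = clustered_features(rng)
        report = loo_svm_evaluate(X, rng.permutation(y), pids)
        assert 35.0 <= report.balanced_accuracy_pct <= 65.0

    def test_single_class_folds_are_skipped_with_warning(self):
        # patients A and B carry only negatives; C carries both classes, so
        # leaving C out collapses the training data to one class
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (30, 3))
        y = np.array([0] * 20 + [0] * 5 + [1] * 5)
        X[y == 1] += 8.0
        pids = np.array(["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        with pytest.warns(UserWarning, match="single-class"):
            report = loo_svm_evaluate(X, y, pids)
        assert report.skipped_folds == ["C"]
        assert len(report.per_fold) == 2

    def test_report_records_protocol(self):
        X, y, pids = clustered_features(np.random.default_rng(3))
        report = loo_svm_evaluate(X, y, pids, cost=0.1, standardize=True)
        assert report.cost == 0.1
        assert report.standardized is True

    def test_deterministic_under_rerun(self):
        X, y, pids = clustered_features(np.random.default_rng(4))
        a = loo_svm_evaluate(X, y, pids)
        b = loo_svm_evaluate(X, y, pids)
        pd.testing.assert_frame_equal(a.per_fold, b.per_fold)


class TestMetrics:
    @pytest.mark.parametrize("sens,spec,expected", [
        (75, 89, 82),   # visual classifier, observer 1
        (91, 83, 87),   # visual classifier, observer 2
        (81, 89, 85),   # optical-property SVM, task II
        (87, 79, 83),   # direct network, task III
        (90, 84, 87),   # autoencoder + classifier, task III
    ])
    def test_balanced_accuracy_from_printed_rate_pairs(self, sens, spec, expected):
        assert round_half_away(balanced_accuracy_from_rates(sens, spec)) == expected

    def test_perfect_classifier(self):
        m = compute_metrics(ContingencyCounts(tp=10, fp=0, tn=10, fn=0))
        assert m.rounded() == {
            "sensitivity_pct": 100, "specificity_pct": 100,
            "balanced_accuracy_pct": 100, "accuracy_pct": 100,
        }

    def test_exact_rational_arithmetic_before_rounding(self):
        m = compute_metrics(ContingencyCounts(tp=1, fp=0, tn=1, fn=2))
        assert m.exact["sensitivity"] == Fraction(100, 3)
        assert m.exact["balanced_accuracy"] == (Fraction(100, 3) + 100) / 2

    def test_undefined_denominators_flagged(self):
        m = compute_metrics(ContingencyCounts(tp=0, fp=0, tn=5, fn=0))
        assert m.sensitivity_pct is None
        assert m.balanced_accuracy_pct is None
        assert m.specificity_pct == 100.0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        tn=st.integers(0, 50), fn=st.integers(0, 50),
    )
    def test_metric_invariants(self, tp, fp, tn, fn):
        """Percentages live in [0, 100]; balanced accuracy is the mean rate."""
        if tp + fp + tn + fn == 0:
            return
        m = compute_metrics(ContingencyCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        for v in (m.sensitivity_pct, m.specificity_pct,
                  m.balanced_accuracy_pct, m.accuracy_pct):
            assert v is None or 0.0 <= v <= 100.0
        if m.sensitivity_pct is not None and m.specificity_pct is not None:
            assert m.balanced_accuracy_pct == pytest.approx(
                (m.sensitivity_pct + m.specificity_pct) / 2
            )

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(41.5) == 42
        assert round_half_away(66.5) == 67
        assert round_half_away(-2.5) == -3
        assert round_half_away(74.49) == 74


class TestContingencies:
    def test_fluorescence_guidance_counts(self):
        """Surgeon's fluorescence-based call: 42% sensitivity, 67% accuracy."""
        m = compute_metrics(FLUORESCENCE_GUIDANCE_COUNTS)
        assert m.rounded()["sensitivity_pct"] == 42
        assert m.rounded()["accuracy_pct"] == 67

    def test_postop_mri_counts(self):
        """Early post-operative MRI reaches 75% sensitivity for residual tumor."""
        m = compute_metrics(POSTOP_MRI_COUNTS)
        assert m.rounded()["sensitivity_pct"] == 75

    def test_outcome_maps_build_correct_counts(self):
        predicted = {"P1": "residual", "P2": "clear", "P3": "clear", "P4": "residual"}
        truth = {"P1": "residual", "P2": "residual", "P3": "clear", "P4": "clear"}
        c = contingency_from_outcomes(predicted, truth)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 1)

    def test_all_correct_gives_100_accuracy(self):
        outcomes = {"P1": "residual", "P2": "clear"}
        c = contingency_from_outcomes(outcomes, dict(outcomes))
        assert compute_metrics(c).accuracy_pct == 100.0

    def test_mismatched_patient_sets_rejected(self):
        with pytest.raises(ValueError, match="patient sets"):
            contingency_from_outcomes({"P1": "clear"}, {"P2": "clear"})


class TestHeatmap:
    def test_single_pair_single_cell(self):
        table = agreement_heatmap([VisualClass.TUMOROUS], [TissueLabel.WM60plus])
        assert table.to_numpy().sum() == 1
        assert table.loc["tumorous", "WM>60"] == 1

    def test_concordant_cohort_concentrates_on_diagonal(self):
        from scipy.stats import spearmanr

        pairs = [
            (VisualClass.WHITE_MATTER, TissueLabel.WM0),
            (VisualClass.RATHER_NOT_TUMOROUS, TissueLabel.WME),
            (VisualClass.RATHER_TUMOROUS_GRAY_MATTER, TissueLabel.GM0),
            (VisualClass.RATHER_TUMOROUS, TissueLabel.WM0_30),
            (VisualClass.RATHER_TUMOROUS, TissueLabel.WM30_60),
            (VisualClass.TUMOROUS, TissueLabel.WM60plus),
        ] * 10
        visual, histo = zip(*pairs)
        table = agreement_heatmap(list(visual), list(histo))
        rows, cols = np.nonzero(table.to_numpy())
        rho = spearmanr(rows, cols).statistic
        assert rho > 0.5

    def test_empty_input_gives_all_zero_matrix(self):
        table = agreement_heatmap([], [])
        assert table.shape == (5, 6)
        assert table.to_numpy().sum() == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            agreement_heatmap([VisualClass.TUMOROUS], [])

    def test_render_writes_image(self, tmp_path):
        from octmargin.evaluate import render_agreement_heatmap

        table = agreement_heatmap(
            [VisualClass.TUMOROUS, VisualClass.WHITE_MATTER],
            [TissueLabel.WM60plus, TissueLabel.WM0],
        )
        out = tmp_path / "heatmap.png"
        render_agreement_heatmap(table, out)
        assert out.stat().st_size > 0
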
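"""Lesion metrics, confusion-matrix statistics, correlation and ROC tests."""
import numpy as np
import pytest
from scipy import stats

import fusionffr as ff
from fusionffr.contours import ValidationError
from fusionffr.metrics import (ConfusionMatrix, _round_half_up,
                               clopper_pearson)


class TestAreaStenosis:
    def test_simple_ratio(self):
        assert ff.area_stenosis(8.0, 2.0) == 75.0

    def test_no_stenosis(self):
        assert ff.area_stenosis(5.0, 5.0) == 0.0

    def test_reference_from_proximal_distal_mean(self):
        # reference = mean(7.2, 6.5) as for proximal/distal segment areas
        ref = (7.2 + 6.5) / 2
        assert ff.area_stenosis(ref, 2.3) == pytest.approx(66.42, abs=0.01)

    def test_mla_larger_than_reference_rejected(self):
        with pytest.raises(ValidationError):
            ff.area_stenosis(4.0, 5.0)


class TestClassify:
    @pytest.mark.parametrize("ffr,expected", [
        (0.80, True),   # cut-off itself is functionally significant
        (0.801, False),
        (0.74, True),
        (1.0, False),
    ])
    def test_cutoff_inclusive(self, ffr, expected):
        assert ff.classify_significant(ffr) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            ff.classify_significant(1.2)


class TestConfusionFromRates:
    def test_reconstructs_fusion_counts(self):
        cm = ff.confusion_from_rates(148, 65, 0.846, 0.843)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (55, 10, 70, 13)

    def test_reconstructs_ct_counts_and_predicted_positives(self):
        cm = ff.confusion_from_rates(148, 65, 0.877, 0.614)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (57, 8, 51, 32)
        assert cm.tp + cm.fp == 89  # matches the reported CT-FFR <= 0.8 count

    def test_perfect_rates(self):
        cm = ff.confusion_from_rates(100, 40, 1.0, 1.0)
        assert cm.fp == 0 and cm.fn == 0


class TestDiagnosticPerformance:
    def test_fusion_column(self):
        s = ff.diagnostic_performance(ConfusionMatrix(55, 13, 10, 70))
        assert s.accuracy.rounded() == 84.5
        assert s.sensitivity.rounded() == 84.6
        assert s.specificity.rounded() == 84.3
        assert s.ppv.rounded() == 80.9
        assert s.npv.rounded() == 87.5

    def test_oct_column(self):
        s = ff.diagnostic_performance(ConfusionMatrix(51, 22, 14, 61))
        assert s.accuracy.rounded() == 75.7
        assert s.ppv.rounded() == 69.9
        assert s.npv.rounded() == 81.3

    def test_undefined_metric_flagged_not_nan(self):
        s = ff.diagnostic_performance(ConfusionMatrix(0, 0, 0, 10))
        assert s.accuracy.value_pct == 100.0
        assert s.sensitivity is None
        assert s.ppv is None

    def test_point_estimate_inside_ci(self):
        s = ff.diagnostic_performance(ConfusionMatrix(55, 13, 10, 70))
        for p in (s.accuracy, s.sensitivity, s.specificity, s.ppv, s.npv):
            assert p.ci_low_pct <= p.value_pct <= p.ci_high_pct

    def test_agrees_with_brute_force_counting(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = rng.integers(10, 80)
            truth = rng.random(n) < rng.uniform(0.2, 0.8)
            pred = truth ^ (rng.random(n) < 0.3)
            if truth.all() or not truth.any():
                continue
            cm = ConfusionMatrix.from_labels(truth, pred)
            assert cm.total == n
            assert cm.tp == int(np.sum(truth & pred))
            acc = ff.diagnostic_performance(cm).accuracy.value_pct
            assert acc == pytest.approx(100 * np.mean(truth == pred))

    def test_accuracy_prevalence_identity(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            cm = ConfusionMatrix(*(int(k) for k in rng.integers(1, 50, 4)))
            s = ff.diagnostic_performance(cm)
            prev = (cm.tp + cm.fn) / cm.total
            lhs = s.accuracy.value_pct
            rhs = (s.sensitivity.value_pct * prev
                   + s.specificity.value_pct * (1 - prev))
            assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_clopper_pearson_is_exact_beta(self):
        lo, hi = clopper_pearson(55, 65)
        assert lo == pytest.approx(stats.beta.ppf(0.025, 55, 11))
        assert hi == pytest.approx(stats.beta.ppf(0.975, 56, 10))
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_display_rounding_half_up(self):
        assert _round_half_up(84.45, 1) == 84.5
        assert _round_half_up(84.44, 1) == 84.4


class TestPearsonAndSteiger:
    def test_perfect_linear(self):
        x = np.arange(5.0)
        assert ff.pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert ff.pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert ff.pearson_r([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == \
            pytest.approx(0.8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            ff.pearson_r([1, 1, 1], [1, 2, 3])

    def test_steiger_equal_correlations_give_zero(self):
        z, p = ff.steiger_z(0.7, 0.7, 0.5, 100)
        assert z == 0.0
        assert p == 1.0

    def test_steiger_clinical_scale_significant(self):
        z, p = ff.steiger_z(0.836, 0.682, 0.75, 148)
        assert z > 0
        assert p < 0.05

    def test_steiger_sign_antisymmetry(self):
        z1, _ = ff.steiger_z(0.8, 0.6, 0.5, 80)
        z2, _ = ff.steiger_z(0.6, 0.8, 0.5, 80)
        assert z1 == pytest.approx(-z2)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValidationError):
            ff.steiger_z(1.0, 0.5, 0.5, 50)

    def test_null_p_values_uniform(self):
        # under H0 (equal population correlations) Steiger p-values are
        # uniform on [0, 1]
        rng = np.random.default_rng(3)
        n, reps = 60, 2000
        cov = np.array([[1.0, 0.5, 0.5],
                        [0.5, 1.0, 0.3],
                        [0.5, 0.3, 1.0]])
        chol = np.linalg.cholesky(cov)
        pvals = []
        for _ in range(reps):
            x = rng.standard_normal((n, 3)) @ chol.T
            r = np.corrcoef(x, rowvar=False)
            pvals.append(ff.steiger_z(r[0, 1], r[0, 2], r[1, 2], n)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestRoc:
    def test_perfect_separation(self):
        assert ff.roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert ff.roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_small_example(self):
        assert ff.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            ff.roc_auc([1, 2, 3], [1, 1, 1])

    def test_matches_exhaustive_pairwise_oracle(self):
        # including heavy tie patterns, on every cohort size <= 12
        rng = np.random.default_rng(5)
        for _ in range(400):
            n = rng.integers(2, 13)
            labels = rng.integers(0, 2, n)
            if labels.all() or not labels.any():
                continue
            scores = rng.integers(0, 4, n).astype(float)  # many ties
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            oracle = np.mean([(1.0 if p > q else 0.5 if p == q else 0.0)
                              for p in pos for q in neg])
            assert ff.roc_auc(scores, labels) == pytest.approx(oracle)


class TestDeLong:
    def test_identical_scores_degenerate(self):
        s = np.array([0.1, 0.2, 0.7, 0.9])
        y = [0, 0, 1, 1]
        with pytest.raises(ValidationError):
            ff.delong_test(s, s, y)

    def test_auc_matches_roc_auc(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        a = rng.random(60) + y
        b = rng.random(60) * 2 + y
        auc_a, auc_b, z, p = ff.delong_test(a, b, y)
        assert auc_a == pytest.approx(ff.roc_auc(a, y))
        assert auc_b == pytest.approx(ff.roc_auc(b, y))
        assert 0 <= p <= 1

    def test_detects_noisier_predictor(self):
        # true signal + small noise vs + large noise: significant in most
        # replicates of a 500-subject cohort
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(100):
            truth = rng.standard_normal(500)
            y = truth > 0.5
            a = truth + 0.3 * rng.standard_normal(500)
            b = truth + 2.0 * rng.standard_normal(500)
            *_, p = ff.delong_test(a, b, y)
            hits += p < 0.05
        assert hits >= 90


class TestBlandAltman:
    def test_identical_series(self):
        m, sd, loa = ff.bland_altman([1, 2, 3], [1, 2, 3])
        assert m == 0.0 and sd == 0.0

    def test_constant_offset(self):
        x = np.linspace(0.6, 1.0, 20)
        m, sd, loa = ff.bland_altman(x, x + 0.02)
        assert m == pytest.approx(0.02)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_agreement_scale(self):
        rng = np.random.default_rng(23)
        x = rng.uniform(0.6, 1.0, 10_000)
        y = x + rng.normal(0.0, 0.06, 10_000)
        m, sd, (lo, hi) = ff.bland_altman(x, y)
        assert abs(m) < 0.002
        assert sd == pytest.approx(0.06, abs=0.002)
        assert lo == pytest.approx(m - 1.96 * sd)
        assert hi == pytest.approx(m + 1.96 * sd)
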
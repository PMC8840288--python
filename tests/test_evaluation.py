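import numpy as np
import pytest
from scipy import stats

from stressreport.evaluation import (
    chi2_concordance,
    f1_binary,
    flag_consistency,
    ground_truth_table,
    rpd,
    total_rpd,
)
from stressreport.intervals import IntervalPair
from stressreport.registry import StressReportError
from stressreport.report import ReportRow, StressReport


def _pair(feature, lo, hi):
    return IntervalPair(
        feature=feature,
        available=True,
        reference_interval=(lo, hi),
        stress_interval=(lo, hi),
        direction="increases_with_stress",
        t_pvalue=0.01,
        n_stress=30,
        n_nostress=30,
    )


class TestRpd:
    def test_direct_evaluation(self):
        # midpoints 10 and 8 -> 100*|10-8|/(2*8) = 12.5%
        assert rpd(_pair("f", 5.0, 15.0), _pair("f", 4.0, 12.0)) == pytest.approx(12.5)

    def test_identical_intervals_zero(self):
        assert rpd(_pair("f", 5.0, 15.0), _pair("f", 5.0, 15.0)) == 0.0

    def test_scales_linearly_in_midpoint_gap(self):
        r1 = rpd(_pair("f", 9.0, 11.0), _pair("f", 7.0, 9.0))
        r2 = rpd(_pair("f", 10.0, 14.0), _pair("f", 7.0, 9.0))
        assert r2 == pytest.approx(2.0 * r1)

    def test_unavailable_interval_undefined(self):
        assert rpd(_pair("f", 5.0, 15.0), IntervalPair("f", available=False)) is None

    def test_zero_midpoint_undefined(self):
        assert rpd(_pair("f", 5.0, 15.0), _pair("f", -1.0, 1.0)) is None

    def test_feature_mismatch_rejected(self):
        with pytest.raises(StressReportError):
            rpd(_pair("a", 0.0, 1.0), _pair("b", 0.0, 1.0))


class TestTotalRpd:
    def test_mean_aggregation(self):
        assert total_rpd([10.0, 20.0, 30.0]) == 20.0
        assert total_rpd([12.5]) == 12.5

    def test_sum_variant(self):
        assert total_rpd([10.0, 20.0], mode="sum") == 30.0

    def test_undefined_entries_dropped(self):
        assert total_rpd([10.0, None, 30.0]) == 20.0

    def test_all_undefined_rejected(self):
        with pytest.raises(StressReportError):
            total_rpd([None, None])


class TestReportingArithmetic:
    """The published per-fold summaries reproduced through the package's
    aggregation paths."""

    def test_mean_of_per_fold_f1(self):
        fold_f1 = [0.93, 0.63, 0.91, 0.64]
        assert np.mean(fold_f1) == pytest.approx(0.78, abs=0.005)

    def test_mean_of_per_fold_total_rpds(self):
        # printed per-fold totals; the published average rounds to 16.8
        assert total_rpd([20.5, 15.4, 15.4, 16.2]) == pytest.approx(16.8, abs=0.1)

    def test_mean_of_per_fold_consistencies(self):
        assert np.mean([81.0, 79.0, 80.0, 80.0]) == pytest.approx(80.0)


def _flag_report(flag_pairs):
    rows = [
        ReportRow(f"f{i}", 0.0, "", (0.0, 1.0), 1.0, star, circle)
        for i, (star, circle) in enumerate(flag_pairs)
    ]
    return StressReport(user_stress_level=0, system_confidence_level=0.0, rows=rows)


class TestFlagConsistency:
    def test_full_agreement(self):
        rep = _flag_report([("red", "red"), ("green", "green")])
        overall, _ = flag_consistency([rep])
        assert overall == 100.0

    def test_half_agreement_by_construction(self):
        rep = _flag_report(
            [("red", "red"), ("red", "green"), ("green", "green"), ("green", "red")]
        )
        overall, per_feature = flag_consistency([rep])
        assert overall == 50.0
        assert per_feature["f0"] == 100.0 and per_feature["f1"] == 0.0

    def test_permutation_invariance(self):
        pairs = [("red", "green"), ("green", "green"), ("red", "red")]
        a, _ = flag_consistency([_flag_report(pairs)])
        b, _ = flag_consistency([_flag_report(pairs[::-1])])
        assert a == b

    def test_no_flagged_rows_rejected(self):
        rep = StressReport(
            user_stress_level=0,
            system_confidence_level=0.0,
            rows=[ReportRow("f", 0.0, "", None, 0.0, None, "green")],
        )
        with pytest.raises(StressReportError):
            flag_consistency([rep])


class TestChi2Concordance:
    @staticmethod
    def _from_table(table):
        signs = [1.0] * (table[0][0] + table[0][1]) + [-1.0] * (table[1][0] + table[1][1])
        inside = (
            [False] * table[0][0] + [True] * table[0][1]
            + [False] * table[1][0] + [True] * table[1][1]
        )
        return chi2_concordance(np.array(signs), np.array(inside))

    def test_perfect_association(self):
        stat, p = self._from_table([[30, 0], [0, 30]])
        assert stat == pytest.approx(60.0)
        assert p < 1e-10

    def test_exact_independence(self):
        stat, p = self._from_table([[15, 15], [15, 15]])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_matches_hand_pearson_formula_on_small_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 51, size=4)
            stat, _ = self._from_table([[a, b], [c, d]])
            n = a + b + c + d
            expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert stat == pytest.approx(expected, rel=1e-12)

    def test_degenerate_margin_undefined(self):
        stat, p = self._from_table([[10, 5], [0, 0]])
        assert stat is None and p is None

    def test_zero_impacts_excluded(self):
        signs = np.array([0.0, 0.0, 1.0, 1.0, -1.0, -1.0])
        inside = np.array([True, False, False, False, True, True])
        stat, p = chi2_concordance(signs, inside)
        ref = stats.chi2_contingency(np.array([[2, 0], [0, 2]]), correction=False)
        assert stat == pytest.approx(ref.statistic)


class TestF1Binary:
    def test_half_precision_half_recall(self):
        assert f1_binary([1, 1, 0, 0], [1, 0, 1, 0]) == 0.5

    def test_perfect_prediction(self):
        assert f1_binary([1, 0, 1], [1, 0, 1]) == 1.0

    def test_all_negative_prediction(self):
        assert f1_binary([1, 1, 0], [0, 0, 0]) == 0.0

    def test_no_positive_labels_rejected(self):
        with pytest.raises(StressReportError):
            f1_binary([0, 0], [0, 1])

    def test_matches_confusion_matrix_by_hand(self):
        y_true = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 0, 0, 1, 0, 0, 0, 0, 0])
        # tp=2 fp=1 fn=2 -> P=2/3, R=1/2, F1=2PR/(P+R)=4/7
        assert f1_binary(y_true, y_pred) == pytest.approx(4.0 / 7.0)


class TestGroundTruth:
    def test_ranged_entries(self):
        table = {e.feature: e for e in ground_truth_table()}
        ranged = [e for e in table.values() if e.no_stress_range is not None]
        assert len(ranged) == 5
        hr = table["mu_HR"]
        assert hr.no_stress_range == (78.45, 12.38)
        assert hr.stress_range == (95.54, 13.69)
        assert hr.p_value == 0.005

    def test_direction_only_entries(self):
        table = {e.feature: e for e in ground_truth_table()}
        for f in ("mu_EMG", "RMS_EMG", "RMS50P_EMG"):
            assert table[f].direction == "increases_with_stress"
            assert table[f].no_stress_range is None
        assert table["mu_RespRate"].direction == "increases_with_stress"

    def test_p_values_within_unit_interval(self):
        for e in ground_truth_table():
            if e.p_value is not None:
                assert 0.0 < e.p_value < 1.0
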
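"""ROC thresholds, Wilson intervals, OddsPath and evidence strength."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from crisprselect.calibration import (
    ControlVariant,
    calibrate,
    calibration_score,
    compute_oddspath,
    roc_curve,
    strength_from_oddspath,
    wilson_interval,
)
from crisprselect.ingest import DAY12_CONDITIONS
from crisprselect.ratios import ConditionStats, RatioSeries


def series(means: dict) -> RatioSeries:
    return RatioSeries(
        "v1",
        "variant",
        {cond: ConditionStats((m,), m, 0.0, 3) for cond, m in means.items()},
    )


class TestCalibrationScore:
    def test_minimum_across_arms(self):
        means = dict(zip(DAY12_CONDITIONS, [90, 85, 88, 20]))
        assert calibration_score(series(means)) == 20

    def test_all_equal(self):
        assert calibration_score(series({c: 100 for c in DAY12_CONDITIONS})) == 100

    def test_single_condition(self):
        assert calibration_score(series({"day12_mmc": 37.0})) == 37.0

    def test_no_conditions_rejected(self):
        with pytest.raises(ValueError):
            calibration_score(series({}))


def make_controls(path_scores, benign_scores):
    return [
        *(ControlVariant(f"p{i}", "pathogenic", s) for i, s in enumerate(path_scores)),
        *(ControlVariant(f"b{i}", "benign", s) for i, s in enumerate(benign_scores)),
    ]


class TestRoc:
    def test_perfect_separation_auc_1(self):
        controls = make_controls([5, 10, 15], [70, 80, 90])
        assert roc_curve(controls).auc == 1.0

    def test_identical_scores_auc_half(self):
        controls = make_controls([50, 50], [50, 50])
        assert roc_curve(controls).auc == 0.5

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([ControlVariant("p", "pathogenic", 5.0)])

    @given(
        path=st.lists(st.integers(0, 100), min_size=1, max_size=8),
        benign=st.lists(st.integers(0, 100), min_size=1, max_size=8),
    )
    def test_auc_equals_mann_whitney(self, path, benign):
        """Trapezoid ROC AUC equals the pairwise concordance statistic."""
        controls = make_controls(path, benign)
        auc = roc_curve(controls).auc
        # Lower score = pathogenic; a pathogenic-benign pair is concordant
        # when the pathogenic score is lower, half-weighted on ties.
        u = sum(
            1.0 if p < b else 0.5 if p == b else 0.0 for p in path for b in benign
        ) / (len(path) * len(benign))
        assert auc == pytest.approx(u, abs=1e-12)


class TestWilson:
    def test_reproduces_printed_lower_bounds(self):
        lo14, hi14 = wilson_interval(14, 14)
        lo9, hi9 = wilson_interval(9, 9)
        assert round(lo14 * 100, 1) == 78.5
        assert round(lo9 * 100, 1) == 70.1
        assert hi14 == hi9 == 1.0

    def test_zero_successes_mirrors_full_successes(self):
        lo, hi = wilson_interval(0, 9)
        assert lo == 0.0
        assert round(hi, 3) == 0.299

    @given(n=st.integers(1, 500), conf=st.sampled_from([0.90, 0.95, 0.99]))
    def test_k_equals_n_closed_form(self, n, conf):
        from scipy.stats import norm

        z = norm.ppf(1 - (1 - conf) / 2)
        lower, upper = wilson_interval(n, n, conf)
        assert abs(lower - n / (n + z * z)) < 1e-12
        assert upper == pytest.approx(1.0)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            wilson_interval(0, 0)


class TestOddsPath:
    def test_published_control_set(self):
        op_path, op_benign, p1, p2a, p2n = compute_oddspath(14, 0, 0, 9)
        assert op_path == 9.0
        assert round(op_benign, 3) == 0.071
        assert p1 == pytest.approx(14 / 23)
        assert p2a == pytest.approx(14 / 15)
        assert p2n == pytest.approx(1 / 10)

    def test_full_strength_control_set(self):
        op_path, _, _, _, _ = compute_oddspath(19, 0, 0, 19)
        assert op_path == 19.0

    def test_small_balanced_set(self):
        op_path, _, _, _, _ = compute_oddspath(4, 0, 0, 4)
        assert op_path == 4.0

    @given(n=st.integers(1, 60))
    def test_balanced_perfect_identity(self, n):
        """n+n perfect controls give odds n (pathogenic) and 1/n (benign)."""
        op_path, op_benign, _, _, _ = compute_oddspath(n, 0, 0, n)
        assert op_path == pytest.approx(n, rel=1e-12)
        assert op_benign == pytest.approx(1 / n, rel=1e-12)

    @given(
        pa=st.integers(1, 40),
        pn=st.integers(0, 10),
        ba=st.integers(0, 10),
        bn=st.integers(1, 40),
    )
    def test_adding_correct_pathogenic_never_decreases_odds(self, pa, pn, ba, bn):
        before, *_ = compute_oddspath(pa, pn, ba, bn)
        after, *_ = compute_oddspath(pa + 1, pn, ba, bn)
        assert after >= before - 1e-12

    def test_empty_readout_class_rejected(self):
        with pytest.raises(ValueError, match="abnormal"):
            compute_oddspath(0, 14, 0, 9)
        with pytest.raises(ValueError, match="normal"):
            compute_oddspath(14, 0, 9, 0)


class TestStrengthMapping:
    @pytest.mark.parametrize(
        "value,direction,expected",
        [
            (9.0, "pathogenic", "moderate"),
            (0.071, "benign", "moderate"),
            (19.0, "pathogenic", "strong"),
            (400.0, "pathogenic", "very_strong"),
            (2.2, "pathogenic", "supporting"),
            (1.5, "pathogenic", "indeterminate"),
            (0.002, "benign", "very_strong"),
            (0.4, "benign", "supporting"),
            (0.9, "benign", "indeterminate"),
        ],
    )
    def test_cutpoints(self, value, direction, expected):
        assert strength_from_oddspath(value, direction) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            strength_from_oddspath(0.0, "pathogenic")


class TestCalibrate:
    def test_perfect_control_set_end_to_end(self):
        controls = make_controls([5 + i for i in range(14)], [70 + i for i in range(9)])
        calib = calibrate(controls)
        assert calib.sensitivity == 1.0
        assert calib.specificity == 1.0
        assert calib.auc == 1.0
        assert calib.oddspath_pathogenic == 9.0
        assert round(calib.oddspath_benign, 3) == 0.071
        assert calib.ps3_strength == "moderate"
        assert calib.bs3_strength == "moderate"
        assert round(calib.sens_ci[0] * 100, 1) == 78.5
        assert round(calib.spec_ci[0] * 100, 1) == 70.1

    def test_threshold_ordering_validated(self):
        controls = make_controls([5], [70])
        with pytest.raises(ValueError):
            calibrate(controls, threshold_deleterious=60, threshold_neutral=50)
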
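import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cxrtubes.evaluation import (
    UndefinedAUCError,
    auc_one_vs_rest,
    bootstrap_ci,
    evaluate_scores,
    format_count_percent,
    group_average_auc,
    is_significant,
    landmark_mae_mm,
    paired_difference_test,
    parse_duration_s,
    percent,
    percent_reduction,
    stratified_report,
)
from cxrtubes.geometry import ImageMeta, Point
from cxrtubes.rules import LABELS


def allpairs_auc(labels, scores):
    """Brute-force oracle: count concordant pairs, ties half."""
    pos = [s for y, s in zip(labels, scores) if y]
    neg = [s for y, s in zip(labels, scores) if not y]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_worked_example(self):
        # 3 of 4 pos-neg pairs concordant
        assert auc_one_vs_rest(
            [0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]
        ) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auc_one_vs_rest([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedAUCError):
            auc_one_vs_rest([1, 1, 1], [0.1, 0.2, 0.3])
        with pytest.raises(UndefinedAUCError):
            auc_one_vs_rest([0, 0], [0.1, 0.2])

    def test_ties_count_half(self):
        assert auc_one_vs_rest([0, 1], [0.5, 0.5]) == pytest.approx(0.5)

    def test_matches_allpairs_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            n = int(rng.integers(2, 51))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = np.round(rng.random(n), 2)  # coarse grid to force ties
            assert auc_one_vs_rest(y, s) == pytest.approx(
                allpairs_auc(y, s)
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, size=100)
        y[:2] = [0, 1]
        s = rng.random(100)
        a0 = auc_one_vs_rest(y, s)
        for f in (lambda x: 3 * x + 1, np.exp, lambda x: x**3):
            assert auc_one_vs_rest(y, f(s)) == pytest.approx(a0)


class TestBootstrapCI:
    def test_constant_metric_zero_width(self):
        point, lo, hi = bootstrap_ci(lambda idx: 0.7, 50, n_boot=100, seed=1)
        assert point == lo == hi == 0.7

    def test_same_seed_identical(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=80)
        y[:2] = [0, 1]
        s = rng.random(80)
        metric = lambda idx: auc_one_vs_rest(y[idx], s[idx])
        a = bootstrap_ci(metric, 80, n_boot=200, seed=9)
        b = bootstrap_ci(metric, 80, n_boot=200, seed=9)
        assert a == b

    def test_undefined_on_full_data_propagates(self):
        y = np.ones(20, dtype=int)
        s = np.linspace(0, 1, 20)
        with pytest.raises(UndefinedAUCError):
            bootstrap_ci(lambda idx: auc_one_vs_rest(y[idx], s[idx]), 20,
                         n_boot=10, seed=0)

    def test_stratified_resampling_preserves_classes(self):
        y = np.array([1] * 2 + [0] * 48)
        s = np.random.default_rng(2).random(50) + y
        point, lo, hi = bootstrap_ci(
            lambda idx: auc_one_vs_rest(y[idx], s[idx]), 50,
            n_boot=200, seed=3, strata=y,
        )
        assert lo <= point <= hi


class TestGroupAverage:
    def test_three_label_group(self):
        # an external-test ETT table: per-label 0.994/0.968/0.998
        avg = group_average_auc(
            {"ETT_Normal": 0.994, "ETT_Borderline": 0.968,
             "ETT_Abnormal": 0.998}
        )
        assert round(avg, 3) == 0.987

    def test_four_label_group(self):
        avg = group_average_auc(
            {"a": 0.990, "b": 0.955, "c": 0.976, "d": 0.991}
        )
        assert round(avg, 3) == 0.978

    def test_single_label_group(self):
        assert group_average_auc({"x": 0.77}) == 0.77

    def test_undefined_labels_skipped(self):
        assert group_average_auc({"x": 0.8, "y": None}) == 0.8
        with pytest.raises(UndefinedAUCError):
            group_average_auc({"x": None})


class TestEvaluateScores:
    @staticmethod
    def _frames(n=60, seed=0):
        rng = np.random.default_rng(seed)
        y = pd.DataFrame({lb: rng.integers(0, 2, n).astype(bool)
                          for lb in LABELS})
        s = pd.DataFrame({lb: rng.random(n) for lb in LABELS})
        return y, s

    def test_report_shape_and_bounds(self):
        y, s = self._frames()
        rep = evaluate_scores(y, s, n_boot=50, seed=0)
        assert set(rep["per_label"]) == set(LABELS)
        assert set(rep["groups"]) == {"ETT", "NGT", "CVC"}
        for cell in rep["per_label"].values():
            assert cell["lo"] <= cell["auc"] <= cell["hi"]

    def test_undefined_cells_are_explicit(self):
        y, s = self._frames()
        y["NGT_Abnormal"] = False  # no positive cases at all
        rep = evaluate_scores(y, s, n_boot=20, seed=0)
        assert rep["per_label"]["NGT_Abnormal"] == "undefined"
        assert rep["groups"]["NGT"] != "undefined"  # other labels remain

    def test_stratified_report_null_effect(self):
        y, s = self._frames(n=400, seed=5)
        flag = np.random.default_rng(6).random(400) < 0.5
        rep = stratified_report(y, s, flag, n_boot=50, seed=0)
        a = rep["with"]["groups"]["ETT"]
        b = rep["without"]["groups"]["ETT"]
        # flag independent of scores: strata agree within bootstrap CIs
        assert a["lo"] <= b["auc"] and b["lo"] <= a["auc"]

    def test_one_empty_stratum(self):
        y, s = self._frames()
        rep = stratified_report(y, s, np.ones(len(y), bool), n_boot=20,
                                seed=0)
        assert rep["without"]["n"] == 0


class TestLandmarkMae:
    def test_identical_annotations(self, unit_meta):
        pts = {f"i{k}": Point(10 + k, 20) for k in range(5)}
        metas = {k: unit_meta for k in pts}
        assert landmark_mae_mm(pts, pts, metas) == (0.0, 0.0)

    def test_two_image_example(self, unit_meta):
        truth = {"a": Point(0, 0), "b": Point(0, 0)}
        pred = {"a": Point(3, 0), "b": Point(5, 0)}  # distances 3 and 5 mm
        metas = {"a": unit_meta, "b": unit_meta}
        mean, sd = landmark_mae_mm(pred, truth, metas)
        assert mean == pytest.approx(4.0)
        assert sd == pytest.approx(1.0)  # divide-by-n convention
        _, sd1 = landmark_mae_mm(pred, truth, metas, ddof=1)
        assert sd1 == pytest.approx(math.sqrt(2.0))

    def test_unpaired_images_excluded(self, unit_meta):
        truth = {"a": Point(0, 0), "b": Point(0, 0)}
        pred = {"a": Point(3, 0), "c": Point(9, 9)}
        mean, _ = landmark_mae_mm(pred, truth, {"a": unit_meta})
        assert mean == pytest.approx(3.0)

    def test_empty_pairing_is_error(self, unit_meta):
        with pytest.raises(ValueError):
            landmark_mae_mm({"a": Point(0, 0)}, {"b": Point(0, 0)}, {})

    def test_rayleigh_mean_recovery(self, rng):
        """Isotropic Gaussian displacement: mean distance = sd*sqrt(pi/2)."""
        from cxrtubes.synthetic import corrupt_landmarks
        from cxrtubes.geometry import LandmarkSet

        meta = ImageMeta(width=4000, height=4000, spacing_row=1.0)
        sd = 3.0
        truth, pred, metas = {}, {}, {}
        lm = LandmarkSet(carina=Point(2000, 2000))
        for k in range(800):
            noisy = corrupt_landmarks(lm, sd, rng, meta)
            truth[str(k)] = lm.carina
            pred[str(k)] = noisy.carina
            metas[str(k)] = meta
        mean, _ = landmark_mae_mm(pred, truth, metas)
        assert mean == pytest.approx(sd * math.sqrt(math.pi / 2), rel=0.08)


class TestPairedDifference:
    def test_identical_vectors(self):
        d, ci, p = paired_difference_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0 and p == 1.0 and ci == (0.0, 0.0)

    def test_constant_shift_with_jitter(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(5, 25, size=300)
        b = a - 2.0 + rng.normal(0, 0.5, size=300)
        d, (lo, hi), p = paired_difference_test(a, b)
        assert d == pytest.approx(-2.0, abs=0.15)
        assert lo < -2.0 < hi or (hi < -1.5)  # CI near the true shift
        assert p < 0.01

    def test_antisymmetry(self):
        rng = np.random.default_rng(9)
        a = rng.random(50)
        b = a + rng.normal(0.3, 0.1, size=50)
        d1, _, p1 = paired_difference_test(a, b)
        d2, _, p2 = paired_difference_test(b, a)
        assert d1 == pytest.approx(-d2)
        assert p1 == pytest.approx(p2)

    def test_too_short(self):
        with pytest.raises(ValueError):
            paired_difference_test([1.0], [2.0])


def test_significance_requires_both_conditions():
    assert is_significant(0.01, (0.70, 0.75), (0.83, 0.94))
    assert not is_significant(0.2, (0.70, 0.75), (0.83, 0.94))  # p too big
    assert not is_significant(0.01, (0.70, 0.85), (0.83, 0.94))  # overlap


class TestReportArithmetic:
    def test_parse_duration(self):
        assert parse_duration_s("1:27:41") == 5261
        assert parse_duration_s("02:25:02") == 8702
        with pytest.raises(ValueError):
            parse_duration_s("90:99")

    def test_percent_reduction(self):
        assert round(percent_reduction("1:27:41", "0:20:03"), 2) == 77.13
        assert percent_reduction("1:00:00", "0:45:00") == pytest.approx(25.0)
        assert percent_reduction("0:10:00", "0:10:00") == 0.0

    def test_cohort_percent(self):
        assert percent(140, 178) == 78.7
        assert format_count_percent(140, 178) == "140 (78.7)"
        assert percent(151, 303) == 49.8
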
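"""Margin-recognition statistic, binomial inference, info content, trends."""

import numpy as np
import pytest
from scipy import stats as sstats

from msimargin import (InfoContentRecord, LabelMap, ROI, ROISet, assess_margin,
                       info_content, peritumor_match_pct,
                       recognition_binomial_test, trend_tests,
                       tumor_reference_label)
from msimargin.datacube import NO_TISSUE


def mask(h, w, coords):
    m = np.zeros((h, w), dtype=bool)
    for y, x in coords:
        m[y, x] = True
    return m


@pytest.fixture
def simple_map_and_rois():
    """6x6 map: left half label 0 (tumor side), right half label 1."""
    labels = np.zeros((6, 6), dtype=np.int32)
    labels[:, 3:] = 1
    lm = LabelMap(6, 6, labels, 2)
    rois = ROISet([
        ROI("T1", "tumor", mask(6, 6, [(0, 0), (1, 0)])),
        ROI("T2", "tumor", mask(6, 6, [(4, 1), (5, 1)])),
        ROI("PT1", "peritumor", mask(6, 6, [(0, 4), (1, 4), (2, 4), (3, 4), (4, 4)])),
        ROI("PT2", "peritumor", mask(6, 6, [(0, 5), (1, 5), (2, 5), (3, 5), (4, 5)])),
    ])
    return lm, rois


class TestTumorReferenceLabel:
    def test_majority(self):
        labels = np.array([[0, 0, 0, 1]], dtype=np.int32)
        lm = LabelMap(4, 1, labels, 2)
        rois = ROISet([
            ROI("T1", "tumor", mask(1, 4, [(0, 0), (0, 1)])),
            ROI("T2", "tumor", mask(1, 4, [(0, 2), (0, 3)])),
            ROI("PT1", "peritumor", mask(1, 4, [(0, 3)])),
            ROI("PT2", "peritumor", mask(1, 4, [(0, 0)])),
        ])
        assert tumor_reference_label(lm, rois) == 0

    def test_tie_goes_to_smaller_label(self):
        labels = np.array([[0, 0, 1, 1]], dtype=np.int32)
        lm = LabelMap(4, 1, labels, 2)
        rois = ROISet([
            ROI("T1", "tumor", mask(1, 4, [(0, 0), (0, 1)])),
            ROI("T2", "tumor", mask(1, 4, [(0, 2), (0, 3)])),
            ROI("PT1", "peritumor", mask(1, 4, [(0, 0)])),
            ROI("PT2", "peritumor", mask(1, 4, [(0, 1)])),
        ])
        assert tumor_reference_label(lm, rois) == 0

    def test_roi_entirely_off_tissue_errors(self):
        labels = np.array([[0, NO_TISSUE]], dtype=np.int32)
        lm = LabelMap(2, 1, labels, 1)
        rois = ROISet([
            ROI("T1", "tumor", mask(1, 2, [(0, 1)])),
            ROI("T2", "tumor", mask(1, 2, [(0, 1)])),
            ROI("PT1", "peritumor", mask(1, 2, [(0, 0)])),
            ROI("PT2", "peritumor", mask(1, 2, [(0, 0)])),
        ])
        with pytest.raises(ValueError, match="tumor ROIs"):
            tumor_reference_label(lm, rois)


class TestMatchPct:
    def test_one_in_twenty_recognized(self):
        # 10 peritumor pixels per ROI, exactly 1 carries the tumor label
        labels = np.ones((4, 6), dtype=np.int32)
        labels[:, :2] = 0
        labels[0, 2] = 0  # one intruding tumor-labeled pixel
        lm = LabelMap(6, 4, labels, 2)
        peri = [(y, x) for y in range(4) for x in (2, 3)]
        rois = ROISet([
            ROI("T1", "tumor", mask(4, 6, [(0, 0), (1, 0)])),
            ROI("T2", "tumor", mask(4, 6, [(2, 1), (3, 1)])),
            ROI("PT1", "peritumor", mask(4, 6, peri)),
            ROI("PT2", "peritumor", mask(4, 6, [(y, x) for y in range(4)
                                                for x in (4, 5)])),
        ])
        pct = peritumor_match_pct(lm, rois, 0)
        assert pct == pytest.approx(100 * 1 / 16)
        a = assess_margin(lm, rois)
        assert a.recognized

    def test_strictly_less_than_threshold(self):
        # exactly 10% matching is NOT recognized (strict inequality)
        labels = np.ones((1, 20), dtype=np.int32)
        labels[0, :9] = 0
        labels[0, 10] = 0  # 1 of 10 peritumor pixels matches tumor label 0
        lm = LabelMap(20, 1, labels, 2)
        rois = ROISet([
            ROI("T1", "tumor", mask(1, 20, [(0, i) for i in range(5)])),
            ROI("T2", "tumor", mask(1, 20, [(0, i) for i in range(5, 9)])),
            ROI("PT1", "peritumor", mask(1, 20, [(0, i) for i in range(10, 15)])),
            ROI("PT2", "peritumor", mask(1, 20, [(0, i) for i in range(15, 20)])),
        ])
        assert peritumor_match_pct(lm, rois, 0) == pytest.approx(10.0)
        assert not assess_margin(lm, rois).recognized

    def test_degenerate_single_cluster_not_recognized(self):
        labels = np.zeros((4, 4), dtype=np.int32)
        lm = LabelMap(4, 4, labels, 1)
        rois = ROISet([
            ROI("T1", "tumor", mask(4, 4, [(0, 0)])),
            ROI("T2", "tumor", mask(4, 4, [(1, 0)])),
            ROI("PT1", "peritumor", mask(4, 4, [(2, 3)])),
            ROI("PT2", "peritumor", mask(4, 4, [(3, 3)])),
        ])
        a = assess_margin(lm, rois)
        assert a.match_pct == pytest.approx(100.0)
        assert not a.recognized

    def test_threshold_monotonicity(self, simple_map_and_rois):
        lm, rois = simple_map_and_rois
        verdicts = [assess_margin(lm, rois, threshold=t).recognized
                    for t in (0.0, 5.0, 10.0, 50.0, 101.0)]
        # once recognized at some threshold, recognized at all larger ones
        assert verdicts == sorted(verdicts)

    def test_per_roi_percentages(self, simple_map_and_rois):
        lm, rois = simple_map_and_rois
        per = peritumor_match_pct(lm, rois, 0, pooled=False)
        assert len(per) == 2

    def test_roiset_json_round_trip(self, simple_map_and_rois, tmp_path):
        _, rois = simple_map_and_rois
        p = tmp_path / "rois.json"
        rois.to_json(p)
        back = ROISet.from_json(p)
        for a, b in zip(rois.rois, back.rois):
            assert a.role == b.role
            np.testing.assert_array_equal(a.mask, b.mask)

    def test_roles_must_be_two_plus_two(self, simple_map_and_rois):
        _, rois = simple_map_and_rois
        bad = [ROI(r.name, "tumor", r.mask) for r in rois.rois]
        with pytest.raises(ValueError, match="two tumor"):
            ROISet(bad)


class TestBinomial:
    def test_closed_form_for_all_small_n(self):
        from math import comb

        for n in range(1, 13):
            for s in range(n + 1):
                expected = sum(comb(n, i) for i in range(s, n + 1)) / 2 ** n
                assert recognition_binomial_test(s, n).p_value == pytest.approx(
                    expected, abs=0)

    def test_agrees_with_scipy(self):
        for n, s in [(10, 9), (10, 5), (12, 7), (7, 7)]:
            ours = recognition_binomial_test(s, n).p_value
            ref = sstats.binomtest(s, n, 0.5, alternative="greater").pvalue
            assert ours == pytest.approx(ref, rel=1e-12)

    def test_examples(self):
        assert recognition_binomial_test(9, 10).p_value == pytest.approx(11 / 1024)
        assert recognition_binomial_test(10, 10).p_value == pytest.approx(1 / 1024)
        assert recognition_binomial_test(5, 10).p_value == pytest.approx(638 / 1024)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            recognition_binomial_test(5, 4)


class TestInfoContent:
    def test_constant_below_checkerboard(self):
        const = LabelMap(50, 50, np.zeros((50, 50), dtype=np.int32), 1)
        board = LabelMap(50, 50, (np.indices((50, 50)).sum(0) % 2).astype(np.int32), 2)
        assert info_content(const).bytes < info_content(board).bytes

    def test_identical_maps_identical_bytes(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 4, (30, 30)).astype(np.int32)
        labels[0, :4] = [0, 1, 2, 3]
        lm = LabelMap(30, 30, labels, 4)
        assert info_content(lm).bytes == info_content(lm).bytes


def make_records(mode, sizes_by_window, case="c1", k=2):
    windows = ["200-400", "400-600", "600-800", "800-1000"]
    return [InfoContentRecord(case_id=case, mode=mode, k=k, window=w,
                              bytes=int(round(kb * 1024)))
            for w, kb in zip(windows, sizes_by_window)]


class TestTrendTests:
    def test_exact_collinear_slope(self):
        res = trend_tests(make_records("positive", [100, 80, 60, 40]))
        t = res.per_mode["positive"]
        assert t.slope == pytest.approx(-20.0)
        assert t.p_decreasing < 1e-12
        assert not np.isnan(t.p_decreasing)

    def test_flat_sizes_give_zero_slope_p_one(self):
        res = trend_tests(make_records("positive", [64, 64, 64, 64]))
        t = res.per_mode["positive"]
        assert t.slope == pytest.approx(0.0)
        assert t.p_decreasing == pytest.approx(1.0)

    def test_single_window_errors(self):
        recs = [InfoContentRecord("c", "positive", 2, "800-1000", 1000)] * 3
        with pytest.raises(ValueError, match="two mass windows"):
            trend_tests(recs)

    def test_slope_difference_between_modes(self):
        rng = np.random.default_rng(0)
        recs = []
        for c in range(10):
            down = [100 - 20 * i + rng.normal(0, 2) for i in range(4)]
            flat = [60 + rng.normal(0, 2) for _ in range(4)]
            recs += make_records("positive", down, case=f"c{c}")
            recs += make_records("negative", flat, case=f"c{c}")
        res = trend_tests(recs)
        assert res.per_mode["positive"].p_decreasing < 0.005
        assert res.per_mode["negative"].p_decreasing > 0.05
        assert res.slope_difference is not None
        assert res.slope_difference.p_value < 0.005

    def test_monte_carlo_power_for_slope_difference(self):
        """Two modes, slopes -20 vs 0, noise sd 2, 10 cases: the interaction
        t-test detects the difference at p < 0.005 in >= 90/100 replicates."""
        rng = np.random.default_rng(2024)
        hits = 0
        for _ in range(100):
            recs = []
            for c in range(10):
                down = [100 - 20 * i + rng.normal(0, 2) for i in range(4)]
                flat = [100 + rng.normal(0, 2) for _ in range(4)]
                recs += make_records("positive", down, case=f"c{c}")
                recs += make_records("negative", flat, case=f"c{c}")
            if trend_tests(recs).slope_difference.p_value < 0.005:
                hits += 1
        assert hits >= 90

    def test_midpoint_regressor_supported(self):
        res = trend_tests(make_records("negative", [100, 80, 60, 40]),
                          regressor="midpoint")
        assert res.per_mode["negative"].slope == pytest.approx(-0.1)
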
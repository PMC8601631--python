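"""Precision/recall/F1 arithmetic, per-cell pixel accounting, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qwaseg import (
    MatchConfig,
    PerturbationPlan,
    cell_pixel_metrics,
    fn_size_histogram,
    high_accuracy_fraction,
    instance_confusion,
    match_instances,
    perturb_labelmap,
    prf_from_counts,
)
from qwaseg.metrics import ImageMetrics, aggregate_summary

from conftest import scene_for


def underestimated_pair():
    """A 1715-px lumen whose prediction covers only a 482-px subset."""
    gt = np.zeros((45, 60), dtype=np.int32)
    gt[3:38, 4:53] = 1            # 35 x 49 = 1715 px
    pred = np.zeros_like(gt)
    pred[3:17, 4:38] = 1          # 14 x 34 = 476 px ...
    pred[17, 4:10] = 1            # ... + 6 px = 482, strictly inside the lumen
    return gt, pred


def overestimated_pair():
    """An 85-px lumen swallowed by a 600-px prediction."""
    gt = np.zeros((40, 40), dtype=np.int32)
    gt[12:29, 15:20] = 1          # 17 x 5 = 85 px
    pred = np.zeros_like(gt)
    pred[5:35, 10:30] = 1         # 30 x 20 = 600 px containing the lumen
    return gt, pred


class TestPRF:
    def test_underestimated_lumen_counts(self):
        prf = prf_from_counts(tp=482, fp=0, fn=1233)
        assert prf.precision == 1.0
        assert round(prf.recall, 2) == 0.28
        assert round(prf.f1, 2) == 0.44

    def test_overestimated_lumen_counts(self):
        prf = prf_from_counts(tp=85, fp=515, fn=0)
        assert round(prf.precision, 2) == 0.14
        assert prf.recall == 1.0
        assert round(prf.f1, 2) == 0.25

    def test_degenerate_counts_fall_back_to_zero(self):
        prf = prf_from_counts(0, 0, 0)
        assert (prf.precision, prf.recall, prf.f1) == (0.0, 0.0, 0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            prf_from_counts(-1, 0, 0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6), st.integers(0, 10**6), st.integers(0, 10**6))
    def test_f1_is_harmonic_mean_and_bounded(self, tp, fp, fn):
        prf = prf_from_counts(tp, fp, fn)
        assert 0.0 <= prf.precision <= 1.0
        assert 0.0 <= prf.recall <= 1.0
        if prf.precision + prf.recall > 0:
            expect = 2 * prf.precision * prf.recall / (prf.precision + prf.recall)
            assert prf.f1 == pytest.approx(expect)
            # the harmonic mean lies between its arguments
            assert min(prf.precision, prf.recall) - 1e-12 <= prf.f1
            assert prf.f1 <= max(prf.precision, prf.recall) + 1e-12
        assert (prf.f1 == 1.0) == (prf.precision == 1.0 and prf.recall == 1.0)


class TestCellPixelMetrics:
    def test_underestimated_lumen_geometry(self):
        gt, pred = underestimated_pair()
        cell = cell_pixel_metrics(gt, pred, (1, 1))
        assert (cell.gt_area, cell.pred_area) == (1715, 482)
        assert (cell.prf.tp, cell.prf.fp, cell.prf.fn) == (482, 0, 1233)
        assert cell.prf.precision == 1.0
        assert round(cell.prf.recall, 2) == 0.28

    def test_overestimated_lumen_geometry(self):
        gt, pred = overestimated_pair()
        cell = cell_pixel_metrics(gt, pred, (1, 1))
        assert (cell.gt_area, cell.pred_area) == (85, 600)
        assert (cell.prf.tp, cell.prf.fp, cell.prf.fn) == (85, 515, 0)
        assert cell.prf.recall == 1.0
        assert round(cell.prf.f1, 2) == 0.25

    def test_identical_cell_is_perfect(self):
        gt, _ = underestimated_pair()
        cell = cell_pixel_metrics(gt, gt, (1, 1))
        assert cell.prf.precision == cell.prf.recall == cell.prf.f1 == 1.0

    def test_conservation_identities(self):
        for gt, pred in (underestimated_pair(), overestimated_pair()):
            cell = cell_pixel_metrics(gt, pred, (1, 1))
            assert cell.prf.tp + cell.prf.fn == cell.gt_area
            assert cell.prf.tp + cell.prf.fp == cell.pred_area

    def test_non_overlapping_pair_rejected(self):
        gt, _ = underestimated_pair()
        pred = np.zeros_like(gt)
        pred[40:44, 55:59] = 1
        with pytest.raises(ValueError, match="matched"):
            cell_pixel_metrics(gt, pred, (1, 1))


class TestInstanceConfusion:
    def test_identity_is_perfect(self):
        scene = scene_for(0, "conifer")
        prf = instance_confusion(match_instances(scene.labels, scene.labels))
        assert prf.precision == prf.recall == prf.f1 == 1.0

    def test_counts_follow_the_perturbation_plan(self):
        scene = scene_for(2, "diffuse")
        plan = PerturbationPlan(n_delete=3, n_spurious=2, seed=2)
        pred, expected = perturb_labelmap(scene.labels, plan)
        prf = instance_confusion(match_instances(scene.labels, pred))
        assert prf.tp == expected["matched"]
        assert prf.fn == 3 and prf.fp == 2
        assert prf.recall == pytest.approx(prf.tp / (prf.tp + 3))


class TestAggregation:
    def test_single_image_macro_equals_micro(self):
        one = prf_from_counts(9, 1, 1)
        macro = aggregate_summary([one], "macro")
        micro = aggregate_summary([one], "micro")
        assert macro == pytest.approx(micro)

    def test_macro_micro_differ_on_unbalanced_images(self):
        a = prf_from_counts(9, 1, 1)
        b = prf_from_counts(1, 4, 9)
        macro = aggregate_summary([a, b], "macro")
        micro = aggregate_summary([a, b], "micro")
        # pooled counts: tp 10, fp 5, fn 10
        assert micro["precision"] == pytest.approx(10 / 15)
        assert micro["recall"] == pytest.approx(0.5)
        assert macro["precision"] == pytest.approx((0.9 + 0.2) / 2)
        assert macro["precision"] != pytest.approx(micro["precision"])

    def test_per_cell_mode_averages_cell_statistics(self):
        gt, pred = underestimated_pair()
        cell = cell_pixel_metrics(gt, pred, (1, 1))
        perfect = cell_pixel_metrics(gt, gt, (1, 1))
        img = ImageMetrics(instance=prf_from_counts(2, 0, 0),
                           cells=(cell, perfect))
        out = aggregate_summary([img], "per_cell")
        assert out["precision"] == pytest.approx((1.0 + 1.0) / 2)
        assert out["recall"] == pytest.approx((cell.prf.recall + 1.0) / 2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_summary([], "macro")


class TestHighAccuracyFraction:
    def test_all_perfect_cells(self):
        gt, _ = underestimated_pair()
        cells = [cell_pixel_metrics(gt, gt, (1, 1))] * 4
        assert high_accuracy_fraction(cells) == 1.0

    def test_badly_segmented_cells_score_zero(self):
        cells = [cell_pixel_metrics(*underestimated_pair(), (1, 1)),
                 cell_pixel_metrics(*overestimated_pair(), (1, 1))]
        assert high_accuracy_fraction(cells) == 0.0

    def test_fraction_matches_direct_count(self):
        scene = scene_for(3, "conifer")
        plan = PerturbationPlan(n_erode=5, erode_px=2, seed=3)
        pred, _ = perturb_labelmap(scene.labels, plan)
        result = match_instances(scene.labels, pred)
        cells = [cell_pixel_metrics(scene.labels, pred, (m.gt_id, m.pred_id))
                 for m in result.matched]
        frac = high_accuracy_fraction(cells, threshold=0.9)
        assert frac == sum(c.prf.f1 >= 0.9 for c in cells) / len(cells)
        assert frac < 1.0  # the heavily eroded cells fall below the bar


class TestFnSizeHistogram:
    def test_no_fn_gives_all_zero_counts(self):
        scene = scene_for(0, "conifer")
        result = match_instances(scene.labels, scene.labels)
        hist = fn_size_histogram(scene.labels, result)
        assert hist.total_fn == 0
        assert all(c == 0 for c in hist.fn_counts)

    def test_counts_equal_area_lookup_oracle(self):
        scene = scene_for(5, "semidiffuse")
        pred, expected = perturb_labelmap(
            scene.labels, PerturbationPlan(n_delete=4, seed=5))
        result = match_instances(scene.labels, pred)
        hist = fn_size_histogram(scene.labels, result, n_bins=6)
        assert hist.total_fn == expected["fn_missed"]
        areas = np.bincount(scene.labels.labels.ravel())
        fn_areas = [areas[i] for i, _ in result.fn]
        edges = np.asarray(hist.bin_edges)
        oracle, _ = np.histogram(fn_areas, bins=edges)
        assert list(hist.fn_counts) == list(oracle)
        assert sum(hist.fn_counts) == hist.total_fn
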
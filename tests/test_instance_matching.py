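"""Instance matching: IoU assignment, border exclusion, split/merge detection."""

import numpy as np
import pytest

from qwaseg import (
    MatchConfig,
    PerturbationPlan,
    find_incomplete,
    intersection_table,
    match_instances,
    perturb_labelmap,
    swap_roles,
)
from qwaseg.instance_matching import (
    FN_MERGED,
    FN_MISSED,
    FN_SPLIT_VICTIM,
    FP_MERGED_PREDICTION,
    FP_SPLIT_FRAGMENT,
)

from conftest import jittered_prediction, random_rect_labelmap, scene_for


def grid_of_cells(n=5, cell=6, gap=4, margin=5):
    """n interior square cells in a row, far from every border."""
    size = margin * 2 + n * cell + (n - 1) * gap
    arr = np.zeros((cell + 2 * margin, size), dtype=np.int32)
    for i in range(n):
        c0 = margin + i * (cell + gap)
        arr[margin:margin + cell, c0:c0 + cell] = i + 1
    return arr


class TestIntersectionTable:
    def test_disjoint_maps_give_empty_table(self):
        gt = grid_of_cells(2)
        pred = np.zeros_like(gt)
        assert intersection_table(gt, pred) == {}

    def test_identity_gives_diagonal_with_full_areas(self):
        gt = grid_of_cells(3)
        table = intersection_table(gt, gt)
        areas = np.bincount(gt.ravel())
        assert table == {(i, i): int(areas[i]) for i in (1, 2, 3)}

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            intersection_table(np.zeros((4, 4), int), np.zeros((5, 5), int))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        gt = random_rect_labelmap(rng, shape=(40, 40))
        pred = jittered_prediction(rng, gt)
        table = intersection_table(gt, pred)
        oracle = {}
        for r in range(40):
            for c in range(40):
                g, p = int(gt.labels[r, c]), int(pred.labels[r, c])
                if g > 0 and p > 0:
                    oracle[(g, p)] = oracle.get((g, p), 0) + 1
        assert table == oracle


class TestFindIncomplete:
    def test_interior_cells_not_flagged(self):
        assert find_incomplete(grid_of_cells(3)) == []

    def test_border_clipped_cell_flagged(self):
        arr = grid_of_cells(2)
        arr[0:4, 0:4] = 3  # a cell on the top-left frame
        assert find_incomplete(arr) == [3]

    @pytest.mark.parametrize("seed", range(3))
    def test_equals_frame_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lm = random_rect_labelmap(rng, shape=(30, 30), margin=0)
        frame = set()
        labels = lm.labels
        for r in range(30):
            for c in range(30):
                if (r in (0, 29) or c in (0, 29)) and labels[r, c] > 0:
                    frame.add(int(labels[r, c]))
        assert set(find_incomplete(lm)) == frame


class TestMatchInstances:
    def test_identity_match(self):
        gt = grid_of_cells(5)
        result = match_instances(gt, gt)
        assert len(result.matched) == 5
        assert result.fn == [] and result.fp == []
        assert all(m.iou == 1.0 for m in result.matched)

    def test_empty_prediction_gives_all_missed(self):
        gt = grid_of_cells(4)
        result = match_instances(gt, np.zeros_like(gt))
        assert result.matched == []
        assert sorted(result.fn) == [(i, FN_MISSED) for i in (1, 2, 3, 4)]

    def test_border_cells_excluded_both_sides(self):
        gt = grid_of_cells(3)
        gt[0:4, 0:6] = 4  # incomplete cell on the frame
        result = match_instances(gt, gt)
        assert result.excluded_gt == [4] and result.excluded_pred == [4]
        assert len(result.matched) == 3

    def test_split_cell_detected_as_disconnected_positive(self):
        # one 1000-px cell predicted as two disjoint 450-px halves
        gt = np.zeros((30, 60), dtype=np.int32)
        gt[5:25, 5:55] = 1                       # 20 x 50 = 1000 px
        pred = np.zeros_like(gt)
        pred[5:23, 5:30] = 1                     # 18 x 25 = 450 px
        pred[5:23, 31:56] = 2                    # 450 px, gap column at 30
        result = match_instances(gt, pred)
        assert result.matched == []
        assert result.fn == [(1, FN_SPLIT_VICTIM)]
        assert sorted(result.fp) == [(1, FP_SPLIT_FRAGMENT), (2, FP_SPLIT_FRAGMENT)]

    def test_merged_cells_detected_as_merged_negative(self):
        # two adjacent 400-px cells predicted as one 810-px union
        gt = np.zeros((30, 50), dtype=np.int32)
        gt[5:25, 5:25] = 1                       # 20 x 20 = 400 px
        gt[5:25, 26:46] = 2                      # 20 x 20 = 400 px
        pred = np.zeros_like(gt)
        pred[5:25, 5:46] = 1                     # the union plus the gap
        result = match_instances(gt, pred)
        assert result.matched == []
        assert sorted(result.fn) == [(1, FN_MERGED), (2, FN_MERGED)]
        assert result.fp == [(1, FP_MERGED_PREDICTION)]

    def test_partition_invariant_on_random_scenes(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            gt = random_rect_labelmap(rng, shape=(60, 60))
            pred = jittered_prediction(rng, gt)
            result = match_instances(gt, pred)
            live_gt = gt.n_instances - len(result.excluded_gt)
            live_pred = pred.n_instances - len(result.excluded_pred)
            assert len(result.matched) + len(result.fn) == live_gt
            assert len(result.matched) + len(result.fp) == live_pred
            gt_seen = [m.gt_id for m in result.matched] + [i for i, _ in result.fn]
            pred_seen = [m.pred_id for m in result.matched] + [i for i, _ in result.fp]
            assert len(gt_seen) == len(set(gt_seen))
            assert len(pred_seen) == len(set(pred_seen))

    def test_raising_threshold_never_adds_matches(self):
        rng = np.random.default_rng(7)
        gt = random_rect_labelmap(rng, shape=(60, 60))
        pred = jittered_prediction(rng, gt)
        sizes = []
        for tau in (0.3, 0.5, 0.7, 0.9):
            result = match_instances(gt, pred, MatchConfig(iou_threshold=tau))
            sizes.append(len(result.matched))
        assert sizes == sorted(sizes, reverse=True)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            MatchConfig(iou_threshold=0.0)


class TestSwapRoles:
    def test_identity_is_self_dual(self):
        gt = grid_of_cells(3)
        result = match_instances(gt, gt)
        swapped = swap_roles(result)
        assert [(m.gt_id, m.pred_id) for m in swapped.matched] == \
            [(m.pred_id, m.gt_id) for m in result.matched]
        assert swapped.fn == [] and swapped.fp == []

    def test_split_becomes_merge_under_swap(self):
        gt = np.zeros((30, 60), dtype=np.int32)
        gt[5:25, 5:55] = 1
        pred = np.zeros_like(gt)
        pred[5:23, 5:30] = 1
        pred[5:23, 31:56] = 2
        swapped = swap_roles(match_instances(gt, pred))
        assert sorted(swapped.fn) == [(1, FN_MERGED), (2, FN_MERGED)]
        assert swapped.fp == [(1, FP_MERGED_PREDICTION)]

    @pytest.mark.parametrize("seed", range(6))
    def test_swap_equals_direct_reversed_evaluation(self, seed):
        scene = scene_for(seed)
        pred, _ = perturb_labelmap(scene.labels, PerturbationPlan(
            n_delete=1, n_spurious=2, n_split=1, n_merge=1, seed=seed))
        forward = match_instances(scene.labels, pred)
        reverse = match_instances(pred, scene.labels)
        swapped = swap_roles(forward)
        assert sorted((m.gt_id, m.pred_id) for m in reverse.matched) == \
            sorted((m.gt_id, m.pred_id) for m in swapped.matched)
        assert sorted(reverse.fn) == sorted(swapped.fn)
        assert sorted(reverse.fp) == sorted(swapped.fp)
        assert reverse.excluded_gt == swapped.excluded_gt
        assert reverse.excluded_pred == swapped.excluded_pred
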
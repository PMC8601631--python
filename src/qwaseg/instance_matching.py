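"""Match predicted cells to ground-truth cells and categorise every instance.

The evaluation follows a confusion-matrix approach at the *instance* level:
a prediction matched one-to-one to a ground-truth cell is a true positive
(TP), an unmatched prediction a false positive (FP), and an unmatched
ground-truth cell a false negative (FN).  Two special situations are detected
and sub-categorised rather than lumped into plain FP/FN:

* **disconnected positive** — a single true cell detected as two or more
  fragments: the fragments count as FP (``disconnected_positive``) and the
  cell as FN (``disconnected_victim``);
* **merged negative** — two or more true cells detected as a single object:
  the true cells count as FN (``merged_negative``) and the covering
  prediction as FP (``merged_prediction``).

Cells clipped by the image border ("incomplete") are excluded from all counts,
as are predictions that touch the border or whose pixel mass lies mostly
inside an excluded cell — border clipping must never manufacture errors.

Matching similarity is intersection-over-union (IoU).  With the default
threshold τ = 0.5 at most one prediction can exceed τ against a given
ground-truth cell, so the greedy assignment below is provably optimal and
order-independent; for τ < 0.5 determinism is kept by sorting candidates by
descending IoU with id tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .imaging_core import LabelsLike, as_labels, _frame_ids

__all__ = [
    "FN_MISSED",
    "FN_MERGED",
    "FN_SPLIT_VICTIM",
    "FP_SPURIOUS",
    "FP_SPLIT_FRAGMENT",
    "FP_MERGED_PREDICTION",
    "MatchConfig",
    "MatchedPair",
    "MatchResult",
    "find_incomplete",
    "intersection_table",
    "match_instances",
    "swap_roles",
]

# FN sub-categories (ground-truth side)
FN_MISSED = "missed"
FN_MERGED = "merged_negative"
FN_SPLIT_VICTIM = "disconnected_victim"
# FP sub-categories (prediction side)
FP_SPURIOUS = "spurious"
FP_SPLIT_FRAGMENT = "disconnected_positive"
FP_MERGED_PREDICTION = "merged_prediction"

_FN_TO_FP = {FN_MISSED: FP_SPURIOUS, FN_MERGED: FP_SPLIT_FRAGMENT,
             FN_SPLIT_VICTIM: FP_MERGED_PREDICTION}
_FP_TO_FN = {v: k for k, v in _FN_TO_FP.items()}


@dataclass(frozen=True)
class MatchConfig:
    """Knobs of the matching rule.

    iou_threshold : minimal IoU for a one-to-one match (τ); 0.5 guarantees
        unique matches and is the community convention for instance matching.
    containment_fraction : majority-containment fraction (κ) used by the
        split/merge detectors and the border-exclusion spill rule.
    border_exclusion : exclude cells cut by the image border from all counts.
    """

    iou_threshold: float = 0.5
    containment_fraction: float = 0.5
    border_exclusion: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.iou_threshold <= 1.0:
            raise ValueError("iou_threshold must lie in (0, 1]")
        if not 0.0 < self.containment_fraction <= 1.0:
            raise ValueError("containment_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class MatchedPair:
    gt_id: int
    pred_id: int
    iou: float
    intersection_px: int


@dataclass
class MatchResult:
    """Categorised outcome of comparing a prediction to the ground truth.

    Every non-excluded ground-truth id appears exactly once across
    ``matched`` ∪ ``fn``; every non-excluded prediction id exactly once across
    ``matched`` ∪ ``fp``; matched pairs are one-to-one.
    """

    matched: List[MatchedPair] = field(default_factory=list)
    fn: List[Tuple[int, str]] = field(default_factory=list)
    fp: List[Tuple[int, str]] = field(default_factory=list)
    excluded_gt: List[int] = field(default_factory=list)
    excluded_pred: List[int] = field(default_factory=list)

    def fn_ids(self, reason: str | None = None) -> List[int]:
        return [i for i, r in self.fn if reason is None or r == reason]

    def fp_ids(self, reason: str | None = None) -> List[int]:
        return [i for i, r in self.fp if reason is None or r == reason]

    def category_counts(self) -> Dict[str, int]:
        """Counts per category, the vocabulary of the perturbation oracle."""
        out = {
            "matched": len(self.matched),
            "fn_missed": 0, "fn_merged_negative": 0, "fn_disconnected_victim": 0,
            "fp_spurious": 0, "fp_disconnected_positive": 0, "fp_merged_prediction": 0,
        }
        for _, r in self.fn:
            out["fn_" + r] += 1
        for _, r in self.fp:
            out["fp_" + r] += 1
        return out


def intersection_table(gt: LabelsLike, pred: LabelsLike) -> Dict[Tuple[int, int], int]:
    """Sparse table of intersection pixel counts for every overlapping
    (gt_id, pred_id) pair.  An entry exists iff the intersection is nonzero."""
    g = as_labels(gt)
    p = as_labels(pred)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: gt {g.shape} vs pred {p.shape}")
    both = (g > 0) & (p > 0)
    if not both.any():
        return {}
    gi = g[both].astype(np.int64)
    pi = p[both].astype(np.int64)
    # pack pairs into single keys for a vectorised group-by
    keys = gi * (int(p.max()) + 1) + pi
    uniq, counts = np.unique(keys, return_counts=True)
    base = int(p.max()) + 1
    return {(int(k // base), int(k % base)): int(c) for k, c in zip(uniq, counts)}


def find_incomplete(labelmap: LabelsLike) -> List[int]:
    """Ids of instances with at least one pixel on the outermost row/column
    frame — the border-cut "incomplete" cells excluded from evaluation."""
    return [int(i) for i in _frame_ids(as_labels(labelmap))]


def _iou(inter: int, area_a: int, area_b: int) -> float:
    union = area_a + area_b - inter
    return inter / union if union > 0 else 0.0


def match_instances(gt: LabelsLike, pred: LabelsLike,
                    cfg: MatchConfig | None = None) -> MatchResult:
    """Assign every instance of ``gt`` and ``pred`` to exactly one category.

    Steps: border exclusion, greedy one-to-one IoU matching, split detection,
    merge detection, residual missed/spurious assignment (see module docs).
    """
    cfg = cfg or MatchConfig()
    g = as_labels(gt)
    p = as_labels(pred)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: gt {g.shape} vs pred {p.shape}")
    tau = cfg.iou_threshold
    kappa = cfg.containment_fraction

    gt_areas = np.bincount(g.ravel())
    pred_areas = np.bincount(p.ravel())
    gt_ids = [int(i) for i in range(1, len(gt_areas)) if gt_areas[i] > 0]
    pred_ids = [int(i) for i in range(1, len(pred_areas)) if pred_areas[i] > 0]
    table = intersection_table(g, p)

    result = MatchResult()

    # --- step 1: border exclusion -------------------------------------------
    if cfg.border_exclusion:
        excluded_gt = set(find_incomplete(g))
        excluded_pred = set(find_incomplete(p))
        if excluded_gt:
            # predictions spilling mostly into an excluded gt cell go too
            for (gi, pi), inter in table.items():
                if gi in excluded_gt and pi not in excluded_pred:
                    if inter / pred_areas[pi] > kappa:
                        excluded_pred.add(pi)
        result.excluded_gt = sorted(excluded_gt)
        result.excluded_pred = sorted(excluded_pred)
    else:
        excluded_gt, excluded_pred = set(), set()

    live_gt = [i for i in gt_ids if i not in excluded_gt]
    live_pred = [i for i in pred_ids if i not in excluded_pred]
    live_gt_set, live_pred_set = set(live_gt), set(live_pred)

    # --- step 2: greedy one-to-one IoU matching -----------------------------
    candidates = []
    for (gi, pi), inter in table.items():
        if gi in live_gt_set and pi in live_pred_set:
            iou = _iou(inter, int(gt_areas[gi]), int(pred_areas[pi]))
            if iou >= tau:
                candidates.append((iou, gi, pi, inter))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_gt: set = set()
    used_pred: set = set()
    for iou, gi, pi, inter in candidates:
        if gi in used_gt or pi in used_pred:
            continue
        result.matched.append(MatchedPair(gi, pi, iou, inter))
        used_gt.add(gi)
        used_pred.add(pi)

    un_gt = [i for i in live_gt if i not in used_gt]
    un_pred = [i for i in live_pred if i not in used_pred]
    un_pred_set = set(un_pred)

    # index intersections by gt and by pred among the unmatched
    by_gt: Dict[int, List[Tuple[int, int]]] = {}
    by_pred: Dict[int, List[Tuple[int, int]]] = {}
    for (gi, pi), inter in table.items():
        if gi in live_gt_set and gi not in used_gt and pi in un_pred_set:
            by_gt.setdefault(gi, []).append((pi, inter))
            by_pred.setdefault(pi, []).append((gi, inter))

    # --- step 3: split detection (disconnected positive) --------------------
    split_preds: set = set()
    split_gts: set = set()
    for gi in un_gt:
        frags = [(pi, inter) for pi, inter in by_gt.get(gi, [])
                 if pi not in split_preds and inter / pred_areas[pi] > kappa]
        if len(frags) < 2:
            continue
        inter_sum = sum(i for _, i in frags)
        area_sum = sum(int(pred_areas[pi]) for pi, _ in frags)
        # fragments are disjoint, so |union(S) ∪ G| = areaG + Σarea − Σinter
        union_iou = inter_sum / (int(gt_areas[gi]) + area_sum - inter_sum)
        if union_iou >= tau:
            split_gts.add(gi)
            split_preds.update(pi for pi, _ in frags)
            result.fn.append((gi, FN_SPLIT_VICTIM))
            for pi, _ in sorted(frags):
                result.fp.append((pi, FP_SPLIT_FRAGMENT))

    # --- step 4: merge detection (merged negative) ---------------------------
    merged_gts: set = set()
    merged_preds: set = set()
    for pi in un_pred:
        if pi in split_preds:
            continue
        parts = [(gi, inter) for gi, inter in by_pred.get(pi, [])
                 if gi not in split_gts and gi not in merged_gts
                 and inter / gt_areas[gi] > kappa]
        if len(parts) < 2:
            continue
        inter_sum = sum(i for _, i in parts)
        area_sum = sum(int(gt_areas[gi]) for gi, _ in parts)
        union_iou = inter_sum / (int(pred_areas[pi]) + area_sum - inter_sum)
        if union_iou >= tau:
            merged_preds.add(pi)
            merged_gts.update(gi for gi, _ in parts)
            result.fp.append((pi, FP_MERGED_PREDICTION))
            for gi, _ in sorted(parts):
                result.fn.append((gi, FN_MERGED))

    # --- step 5: residuals ---------------------------------------------------
    for gi in un_gt:
        if gi not in split_gts and gi not in merged_gts:
            result.fn.append((gi, FN_MISSED))
    for pi in un_pred:
        if pi not in split_preds and pi not in merged_preds:
            result.fp.append((pi, FP_SPURIOUS))

    result.fn.sort()
    result.fp.sort()
    return result


def swap_roles(result: MatchResult) -> MatchResult:
    """The result of evaluating with the roles of gt and prediction reversed:
    matched pairs transposed, fp and fn exchanged with their dual categories."""
    return MatchResult(
        matched=[MatchedPair(m.pred_id, m.gt_id, m.iou, m.intersection_px)
                 for m in result.matched],
        fn=sorted((pid, _FP_TO_FN[r]) for pid, r in result.fp),
        fp=sorted((gid, _FN_TO_FP[r]) for gid, r in result.fn),
        excluded_gt=list(result.excluded_pred),
        excluded_pred=list(result.excluded_gt),
    )
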
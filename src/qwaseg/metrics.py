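"""Precision / recall / F1 at the instance and pixel level.

The same three statistics serve two questions:

* *cell instance detection* — how many target cells were found at all
  (TP/FP/FN are counts of matched / spurious / missed instances; true
  negatives are undefined because the images contain unbounded numbers of
  non-target structures);
* *lumen area detection* — for each matched cell, how accurately was its
  lumen delineated (TP/FP/FN are pixel counts inside the pair).

recall = TP/(TP+FN) measures missed cells (or pixels), precision = TP/(TP+FP)
measures redundant ones, and F1 is their harmonic mean.  High precision with
low recall means the lumen area is underestimated; the reverse means it is
overestimated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .imaging_core import LabelsLike, as_labels
from .instance_matching import MatchResult

__all__ = [
    "PRF",
    "CellPixelMetrics",
    "ImageMetrics",
    "SizeClassHistogram",
    "aggregate_summary",
    "cell_pixel_metrics",
    "fn_size_histogram",
    "high_accuracy_fraction",
    "instance_confusion",
    "prf_from_counts",
]


@dataclass(frozen=True)
class PRF:
    """TP/FP/FN counts with the derived precision, recall and F1.

    Degenerate denominators follow the conservative convention:
    precision := 0 when TP+FP = 0, recall := 0 when TP+FN = 0, and
    F1 := 0 when precision + recall = 0.
    """

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def prf_from_counts(tp: int, fp: int, fn: int) -> PRF:
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    denom = precision + recall
    f1 = 2.0 * precision * recall / denom if denom > 0 else 0.0
    return PRF(tp=int(tp), fp=int(fp), fn=int(fn),
               precision=precision, recall=recall, f1=f1)


@dataclass(frozen=True)
class CellPixelMetrics:
    """Per-matched-cell pixel accounting: one row of the per-cell table.

    Conservation identities hold by construction:
    ``tp + fn = gt_area`` and ``tp + fp = pred_area``.
    """

    gt_id: int
    pred_id: int
    gt_area: int      # "Area" column
    pred_area: int    # "Prediction" column
    prf: PRF


def cell_pixel_metrics(gt: LabelsLike, pred: LabelsLike,
                       pair: Tuple[int, int]) -> CellPixelMetrics:
    """Pixel-level comparison of one matched (gt_id, pred_id) pair.

    TP = pixels in both lumens, FP = prediction-only pixels, FN =
    ground-truth-only pixels.
    """
    g = as_labels(gt)
    p = as_labels(pred)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: gt {g.shape} vs pred {p.shape}")
    gt_id, pred_id = pair
    gmask = g == gt_id
    pmask = p == pred_id
    gt_area = int(gmask.sum())
    pred_area = int(pmask.sum())
    if gt_area == 0 or pred_area == 0:
        raise ValueError(f"pair {pair} refers to an absent instance")
    tp = int((gmask & pmask).sum())
    if tp == 0:
        raise ValueError(f"pair {pair} does not overlap; not a matched pair")
    return CellPixelMetrics(
        gt_id=int(gt_id), pred_id=int(pred_id),
        gt_area=gt_area, pred_area=pred_area,
        prf=prf_from_counts(tp, pred_area - tp, gt_area - tp),
    )


def instance_confusion(result: MatchResult) -> PRF:
    """Instance-level confusion counts of a match result: TP = matched pairs,
    FP = unmatched predictions, FN = unmatched ground-truth cells."""
    return prf_from_counts(len(result.matched), len(result.fp), len(result.fn))


@dataclass(frozen=True)
class ImageMetrics:
    """Evaluation of one image: instance confusion plus per-cell pixel rows."""

    instance: PRF
    cells: Tuple[CellPixelMetrics, ...]


def aggregate_summary(per_image: Sequence, mode: str = "macro") -> PRF | Dict[str, float]:
    """Aggregate instance statistics over several images.

    ``macro``    unweighted mean of the per-image precision/recall/F1;
    ``micro``    precision/recall/F1 of the pooled TP/FP/FN counts;
    ``per_cell`` mean of the pixel precision/recall/F1 over all matched cells
                 of all images (the lumen-area average).

    ``per_image`` items may be :class:`PRF` (macro/micro only) or anything
    with ``.instance`` (a PRF) and ``.cells`` (CellPixelMetrics) attributes.
    """
    if len(per_image) == 0:
        raise ValueError("need at least one per-image result")
    prfs = [item.instance if hasattr(item, "instance") else item for item in per_image]
    if mode == "macro":
        return {
            "precision": float(np.mean([r.precision for r in prfs])),
            "recall": float(np.mean([r.recall for r in prfs])),
            "f1": float(np.mean([r.f1 for r in prfs])),
        }
    if mode == "micro":
        pooled = prf_from_counts(sum(r.tp for r in prfs),
                                 sum(r.fp for r in prfs),
                                 sum(r.fn for r in prfs))
        return {"precision": pooled.precision, "recall": pooled.recall, "f1": pooled.f1}
    if mode == "per_cell":
        cells: List[CellPixelMetrics] = []
        for item in per_image:
            if not hasattr(item, "cells"):
                raise ValueError("per_cell aggregation needs per-cell metrics")
            cells.extend(item.cells)
        if not cells:
            return {"precision": 0.0, "recall": 0.0, "f1": 0.0}
        return {
            "precision": float(np.mean([c.prf.precision for c in cells])),
            "recall": float(np.mean([c.prf.recall for c in cells])),
            "f1": float(np.mean([c.prf.f1 for c in cells])),
        }
    raise ValueError(f"unknown aggregation mode {mode!r}")


def high_accuracy_fraction(cells: Sequence[CellPixelMetrics],
                           threshold: float = 0.9) -> float:
    """Fraction of matched cells whose pixel F1 reaches the threshold — the
    share of cells segmented accurately enough to need no manual editing."""
    if len(cells) == 0:
        raise ValueError("need at least one cell")
    return sum(1 for c in cells if c.prf.f1 >= threshold) / len(cells)


@dataclass(frozen=True)
class SizeClassHistogram:
    """Missed-cell counts per ground-truth area class."""

    bin_edges: Tuple[float, ...]
    fn_counts: Tuple[int, ...]
    total_fn: int


def fn_size_histogram(gt: LabelsLike, result: MatchResult, n_bins: int = 10,
                      binning: str = "equal_width") -> SizeClassHistogram:
    """Bin the FN (missed-class) ground-truth cells by their pixel area.

    Edges span the observed area range of all non-excluded ground-truth cells,
    so the histogram shows which size classes are hardest to detect (typically
    the small latewood cells).
    """
    g = as_labels(gt)
    areas = np.bincount(g.ravel())
    excluded = set(result.excluded_gt)
    live_ids = [i for i in range(1, len(areas)) if areas[i] > 0 and i not in excluded]
    if not live_ids:
        raise ValueError("no ground-truth cells to bin")
    live_areas = np.array([areas[i] for i in live_ids], dtype=float)
    if binning == "equal_width":
        edges = np.linspace(live_areas.min(), live_areas.max(), n_bins + 1)
    elif binning == "quantile":
        edges = np.quantile(live_areas, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)  # collapse ties; fewer bins is fine
    else:
        raise ValueError(f"unknown binning {binning!r}")
    if edges[0] == edges[-1]:  # all cells the same size
        edges = np.array([edges[0], edges[0] + 1.0])
    fn_areas = np.array([areas[i] for i, _ in result.fn], dtype=float)
    counts, _ = np.histogram(fn_areas, bins=edges)
    return SizeClassHistogram(
        bin_edges=tuple(float(e) for e in edges),
        fn_counts=tuple(int(c) for c in counts),
        total_fn=int(counts.sum()),
    )
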
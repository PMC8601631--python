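"""Per-cell and summary tables, export, and multi-method comparison.

The canonical per-cell table has the columns
``Area, Prediction, TP, FP, FN, Precision, Recall, F1`` — ground-truth lumen
area, predicted lumen area, the pixel confusion counts, and the derived
statistics for one matched cell.  Numbers are stored at full precision;
only the *display* format rounds to two decimals (CSV/JSON keep full
precision so exports round-trip losslessly).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .imaging_core import LabelsLike, as_labels
from .instance_matching import MatchConfig, MatchResult, match_instances
from .metrics import (
    CellPixelMetrics,
    PRF,
    SizeClassHistogram,
    cell_pixel_metrics,
    fn_size_histogram,
    high_accuracy_fraction,
    instance_confusion,
    prf_from_counts,
)

__all__ = ["EvaluationReport", "evaluate", "export_report", "load_report",
           "compare_methods"]

PER_CELL_COLUMNS = ["GT_ID", "Pred_ID", "Area", "Prediction",
                    "TP", "FP", "FN", "Precision", "Recall", "F1"]

# Training hyperparameters of the out-of-scope DCNN adapter, recorded as
# documented constants only; nothing in this package computes with them.
DCNN_REFERENCE_CONFIG = {
    "optimizer": "SGD",
    "learning_rate": 0.005,
    "momentum": 0.9,
    "weight_decay": 0.0005,
    "epochs": 20,
    "batch_size": 1,
}


def _config_hash(cfg: MatchConfig) -> str:
    payload = json.dumps({"iou_threshold": cfg.iou_threshold,
                          "containment_fraction": cfg.containment_fraction,
                          "border_exclusion": cfg.border_exclusion},
                         sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class EvaluationReport:
    """Full evaluation of one prediction against one ground truth."""

    per_cell: List[CellPixelMetrics]
    instance_summary: Dict[str, Dict[str, float]]   # mode -> {precision, recall, f1}
    instance_counts: Dict[str, int]                 # category -> count
    high_accuracy_fraction: Optional[float]
    fn_histogram: Optional[SizeClassHistogram]
    provenance: Dict[str, object]

    def per_cell_frame(self) -> pd.DataFrame:
        rows = [{
            "GT_ID": c.gt_id, "Pred_ID": c.pred_id,
            "Area": c.gt_area, "Prediction": c.pred_area,
            "TP": c.prf.tp, "FP": c.prf.fp, "FN": c.prf.fn,
            "Precision": c.prf.precision, "Recall": c.prf.recall, "F1": c.prf.f1,
        } for c in self.per_cell]
        return pd.DataFrame(rows, columns=PER_CELL_COLUMNS)


def evaluate(gt: LabelsLike, pred: LabelsLike, cfg: MatchConfig | None = None,
             gt_path: str | None = None, pred_path: str | None = None,
             seed: int | None = None,
             f1_threshold: float = 0.9, n_bins: int = 10) -> EvaluationReport:
    """Match, score and summarise one prediction against the ground truth."""
    cfg = cfg or MatchConfig()
    g = as_labels(gt)
    p = as_labels(pred)
    result = match_instances(g, p, cfg)
    cells = [cell_pixel_metrics(g, p, (m.gt_id, m.pred_id)) for m in result.matched]
    inst = instance_confusion(result)

    pixel_prf = _pooled_pixel_prf(cells)
    summary = {
        "instance_macro": {"precision": inst.precision, "recall": inst.recall,
                           "f1": inst.f1},
        "instance_micro": {"precision": inst.precision, "recall": inst.recall,
                           "f1": inst.f1},
        "lumen_per_cell": _mean_cell_prf(cells),
        "lumen_micro": {"precision": pixel_prf.precision,
                        "recall": pixel_prf.recall, "f1": pixel_prf.f1},
    }
    haf = high_accuracy_fraction(cells, f1_threshold) if cells else None
    try:
        hist = fn_size_histogram(g, result, n_bins=n_bins)
    except ValueError:
        hist = None
    return EvaluationReport(
        per_cell=cells,
        instance_summary=summary,
        instance_counts=result.category_counts(),
        high_accuracy_fraction=haf,
        fn_histogram=hist,
        provenance={
            "gt_path": gt_path, "pred_path": pred_path, "seed": seed,
            "config_hash": _config_hash(cfg),
            "iou_threshold": cfg.iou_threshold,
            "containment_fraction": cfg.containment_fraction,
            "border_exclusion": cfg.border_exclusion,
            "version": _pkg_version,
        },
    )


def _mean_cell_prf(cells: Sequence[CellPixelMetrics]) -> Dict[str, float]:
    if not cells:
        return {"precision": 0.0, "recall": 0.0, "f1": 0.0}
    return {"precision": float(np.mean([c.prf.precision for c in cells])),
            "recall": float(np.mean([c.prf.recall for c in cells])),
            "f1": float(np.mean([c.prf.f1 for c in cells]))}


def _pooled_pixel_prf(cells: Sequence[CellPixelMetrics]) -> PRF:
    return prf_from_counts(sum(c.prf.tp for c in cells),
                           sum(c.prf.fp for c in cells),
                           sum(c.prf.fn for c in cells))


def export_report(report: EvaluationReport, path: str | os.PathLike,
                  format: str = "csv") -> None:
    """Write the report; csv/json round-trip losslessly, xlsx gets one sheet
    per table with a 2-decimal display format on the statistic columns."""
    path = str(path)
    frame = report.per_cell_frame()
    if format == "csv":
        frame.to_csv(path, index=False)
    elif format == "json":
        payload = {
            "per_cell": frame.to_dict(orient="records"),
            "instance_summary": report.instance_summary,
            "instance_counts": report.instance_counts,
            "high_accuracy_fraction": report.high_accuracy_fraction,
            "fn_histogram": None if report.fn_histogram is None else {
                "bin_edges": list(report.fn_histogram.bin_edges),
                "fn_counts": list(report.fn_histogram.fn_counts),
                "total_fn": report.fn_histogram.total_fn,
            },
            "provenance": report.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    elif format == "xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            frame.to_excel(writer, sheet_name="per_cell", index=False)
            summary = pd.DataFrame(report.instance_summary).T
            summary.to_excel(writer, sheet_name="summary")
            counts = pd.DataFrame([report.instance_counts])
            counts.to_excel(writer, sheet_name="instance_counts", index=False)
            ws = writer.sheets["per_cell"]
            stat_cols = [PER_CELL_COLUMNS.index(c) + 1
                         for c in ("Precision", "Recall", "F1")]
            for row in ws.iter_rows(min_row=2):
                for j in stat_cols:
                    row[j - 1].number_format = "0.00"
    else:
        raise ValueError(f"unknown export format {format!r}")


def load_report(path: str | os.PathLike) -> EvaluationReport:
    """Reload a JSON report written by :func:`export_report`."""
    with open(path) as fh:
        payload = json.load(fh)
    cells = [CellPixelMetrics(
        gt_id=row["GT_ID"], pred_id=row["Pred_ID"],
        gt_area=row["Area"], pred_area=row["Prediction"],
        prf=prf_from_counts(row["TP"], row["FP"], row["FN"]),
    ) for row in payload["per_cell"]]
    hist = payload.get("fn_histogram")
    return EvaluationReport(
        per_cell=cells,
        instance_summary=payload["instance_summary"],
        instance_counts=payload["instance_counts"],
        high_accuracy_fraction=payload["high_accuracy_fraction"],
        fn_histogram=None if hist is None else SizeClassHistogram(
            bin_edges=tuple(hist["bin_edges"]),
            fn_counts=tuple(hist["fn_counts"]),
            total_fn=hist["total_fn"]),
        provenance=payload["provenance"],
    )


def compare_methods(gt: LabelsLike, predictions: Mapping[str, LabelsLike],
                    cfg: MatchConfig | None = None) -> pd.DataFrame:
    """One row per method: instance PRF, lumen-area PRF (per-cell mean and
    pooled), and the high-accuracy cell fraction.  Row order = input order."""
    cfg = cfg or MatchConfig()
    g = as_labels(gt)
    rows = []
    for name, pred in predictions.items():
        p = as_labels(pred)
        if p.shape != g.shape:
            raise ValueError(
                f"prediction {name!r} has shape {p.shape}, ground truth {g.shape}")
        rep = evaluate(g, p, cfg)
        inst = rep.instance_summary["instance_micro"]
        lum = rep.instance_summary["lumen_per_cell"]
        rows.append({
            "method": name,
            "inst_precision": inst["precision"], "inst_recall": inst["recall"],
            "inst_f1": inst["f1"],
            "lumen_precision": lum["precision"], "lumen_recall": lum["recall"],
            "lumen_f1": lum["f1"],
            "high_accuracy_fraction": (rep.high_accuracy_fraction
                                       if rep.high_accuracy_fraction is not None
                                       else 0.0),
            "matched": rep.instance_counts["matched"],
            "fn": rep.instance_counts["fn_missed"]
            + rep.instance_counts["fn_merged_negative"]
            + rep.instance_counts["fn_disconnected_victim"],
            "fp": rep.instance_counts["fp_spurious"]
            + rep.instance_counts["fp_disconnected_positive"]
            + rep.instance_counts["fp_merged_prediction"],
        })
    return pd.DataFrame(rows).set_index("method")
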
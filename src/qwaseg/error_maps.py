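"""Colour-coded error maps: the visual comparison of a prediction against the
ground truth.

For matched cells the map shows pixel-level agreement (TP / FN / FP pixels);
unmatched instances are filled whole with their category colour (missed cell,
spurious prediction, split fragments, merged cells) and border-incomplete
cells are greyed out.  The maps let an analyst see *where* and *why* a
segmentation fails — e.g. a blue block of missed cells under a stain, or a
dark-green rim around a systematically underestimated lumen.

Painting order (later layers win): background < incomplete < merged cells <
missed cells < matched-cell pixels < split fragments < spurious predictions.
On scenes where instances of a category do not overlap instances of another
(the normal case), an unblended render reconciles exactly with the metric
counts via :func:`color_census`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from PIL import Image as PILImage, ImageDraw

from .imaging_core import LabelsLike, as_labels
from .instance_matching import (
    FN_MERGED,
    FN_MISSED,
    FN_SPLIT_VICTIM,
    FP_SPLIT_FRAGMENT,
    FP_SPURIOUS,
    MatchResult,
)

__all__ = ["ErrorPalette", "render_error_map", "color_census", "add_legend"]

Color = Tuple[int, int, int]


@dataclass(frozen=True)
class ErrorPalette:
    """Category → RGB colour of the error map.

    Anchored choices: FN pixels dark green, FP pixels orange, missed cells
    blue.  The rest are this package's defaults and fully configurable.
    """

    tp_pixel: Color = (144, 238, 144)            # light green
    fn_pixel: Color = (0, 100, 0)                # dark green
    fp_pixel: Color = (255, 165, 0)              # orange
    fn_instance: Color = (0, 0, 255)             # blue: missed cell
    fp_instance: Color = (255, 0, 0)             # red: spurious prediction
    disconnected_positive: Color = (255, 0, 255)  # magenta: split fragments
    merged_negative: Color = (0, 255, 255)       # cyan: merged gt cells
    incomplete: Color = (128, 128, 128)          # grey: border-cut cells
    background: Color = (0, 0, 0)

    def __post_init__(self) -> None:
        colors = list(self.as_dict().values())
        if len(set(colors)) != len(colors):
            raise ValueError("palette colours must be pairwise distinct")

    def as_dict(self) -> Dict[str, Color]:
        return {
            "tp_pixel": self.tp_pixel,
            "fn_pixel": self.fn_pixel,
            "fp_pixel": self.fp_pixel,
            "fn_instance": self.fn_instance,
            "fp_instance": self.fp_instance,
            "disconnected_positive": self.disconnected_positive,
            "merged_negative": self.merged_negative,
            "incomplete": self.incomplete,
            "background": self.background,
        }


def render_error_map(gt: LabelsLike, pred: LabelsLike, result: MatchResult,
                     palette: ErrorPalette | None = None,
                     base: Optional[np.ndarray] = None,
                     alpha: float = 0.6,
                     legend: bool = False) -> np.ndarray:
    """Render the error map as an (H, W, 3) uint8 RGB array.

    With ``base`` given, the category colours are alpha-blended over the
    original section image; blended maps are for human eyes only and cannot be
    fed to :func:`color_census`.  ``legend=True`` appends a labelled swatch
    strip (also census-incompatible).
    """
    palette = palette or ErrorPalette()
    g = as_labels(gt)
    p = as_labels(pred)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: gt {g.shape} vs pred {p.shape}")
    if base is not None and base.shape[:2] != g.shape:
        raise ValueError("base image shape does not match the label maps")

    overlay = np.zeros(g.shape + (3,), dtype=np.uint8)
    overlay[:] = palette.background
    painted = np.zeros(g.shape, dtype=bool)

    def paint(mask: np.ndarray, color: Color) -> None:
        overlay[mask] = color
        painted[mask] = True

    # incomplete (excluded) instances
    for gid in result.excluded_gt:
        paint(g == gid, palette.incomplete)
    for pid in result.excluded_pred:
        paint(p == pid, palette.incomplete)
    # merged gt cells
    for gid, reason in result.fn:
        if reason == FN_MERGED:
            paint(g == gid, palette.merged_negative)
    # missed gt cells
    for gid, reason in result.fn:
        if reason == FN_MISSED:
            paint(g == gid, palette.fn_instance)
    # matched cells: per-pixel tp/fn/fp
    for m in result.matched:
        gmask = g == m.gt_id
        pmask = p == m.pred_id
        paint(gmask & pmask, palette.tp_pixel)
        paint(gmask & ~pmask, palette.fn_pixel)
        paint(pmask & ~gmask, palette.fp_pixel)
    # split fragments and spurious predictions on top
    for pid, reason in result.fp:
        if reason == FP_SPLIT_FRAGMENT:
            paint(p == pid, palette.disconnected_positive)
    for pid, reason in result.fp:
        if reason == FP_SPURIOUS:
            paint(p == pid, palette.fp_instance)

    if base is not None:
        base_rgb = np.asarray(base, dtype=np.float64)
        if base_rgb.ndim == 2:
            base_rgb = np.stack([base_rgb] * 3, axis=-1)
        out = base_rgb.copy()
        out[painted] = alpha * overlay[painted] + (1 - alpha) * base_rgb[painted]
        overlay = np.clip(np.rint(out), 0, 255).astype(np.uint8)

    if legend:
        overlay = add_legend(overlay, palette)
    return overlay


def color_census(image: np.ndarray, palette: ErrorPalette | None = None) -> Dict[str, int]:
    """Exact per-category pixel counts of an unblended, legend-free render.

    Raises if the image contains a colour outside the palette — the guard that
    the render used exactly this palette with no blending.
    """
    palette = palette or ErrorPalette()
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    flat = img.reshape(-1, 3)
    # pack RGB into a single integer per pixel for fast counting
    packed = (flat[:, 0].astype(np.int64) << 16) | (flat[:, 1].astype(np.int64) << 8) \
        | flat[:, 2].astype(np.int64)
    uniq, counts = np.unique(packed, return_counts=True)
    by_color = {int(u): int(c) for u, c in zip(uniq, counts)}
    census: Dict[str, int] = {}
    known = {}
    for name, (r, gch, b) in palette.as_dict().items():
        known[(r << 16) | (gch << 8) | b] = name
        census[name] = 0
    for packed_color, count in by_color.items():
        if packed_color not in known:
            r, gch, b = (packed_color >> 16) & 255, (packed_color >> 8) & 255, packed_color & 255
            raise ValueError(f"unknown colour ({r}, {gch}, {b}) in error map")
        census[known[packed_color]] += count
    return census


def add_legend(image: np.ndarray, palette: ErrorPalette | None = None,
               row_height: int = 18) -> np.ndarray:
    """Append a labelled colour-swatch strip below an error map."""
    palette = palette or ErrorPalette()
    entries = [(k, v) for k, v in palette.as_dict().items() if k != "background"]
    h, w = image.shape[:2]
    strip_h = row_height * len(entries) + 4
    strip = PILImage.new("RGB", (w, strip_h), (255, 255, 255))
    draw = ImageDraw.Draw(strip)
    for i, (name, color) in enumerate(entries):
        y = 2 + i * row_height
        draw.rectangle([2, y, 2 + row_height - 4, y + row_height - 4], fill=color)
        draw.text((row_height + 4, y), name.replace("_", " "), fill=(0, 0, 0))
    return np.vstack([image, np.asarray(strip, dtype=np.uint8)])
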
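"""Model-agnostic tiled inference.

Whole slide sections are far larger than the patches a segmentation model is
trained on (1000 x 1000 px for most wood types, 2000 x 3000 px presets for
ring-porous species whose earlywood vessels are huge).  The pipeline cuts the
image into overlapping tiles, runs a pluggable backend on each tile, and
stitches the per-tile label maps into one whole-image map, deduplicating cells
seen by several tiles.

For ring-porous wood the vessel sizes span two orders of magnitude, so two
specialised passes are run: a fine pass at native resolution for the small
latewood vessels and a coarse pass at half resolution (double field of view)
for the large earlywood vessels; :func:`merge_dual_scale` combines them with a
size gate plus IoU deduplication, keeping either pass's instances as a
fallback so no object class is silently dropped.

The bundled :class:`ThresholdWatershedBackend` is a classical
threshold + watershed segmenter: it lets every pipeline component run and be
tested end-to-end with no trained network, and doubles as a reference method
in comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Protocol, Sequence, Tuple, runtime_checkable

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2gray
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.morphology import disk
from skimage.segmentation import watershed

from .imaging_core import LabelMap, LabelsLike, as_labels, binary_mask_to_labelmap

__all__ = [
    "TileSpec",
    "SegmentationBackend",
    "DualScaleConfig",
    "BaselineParams",
    "ThresholdWatershedBackend",
    "make_tiles",
    "stitch",
    "merge_dual_scale",
    "baseline_segment",
    "run_tiled",
    "run_dual_scale",
]

Confidences = Dict[int, float]


@dataclass(frozen=True)
class TileSpec:
    """Tile geometry; the ring-porous preset is TileSpec(2000, 3000)."""

    tile_height: int = 1000
    tile_width: int = 1000
    overlap: int = 100

    def __post_init__(self) -> None:
        if self.tile_height < 1 or self.tile_width < 1:
            raise ValueError("tile dimensions must be positive")
        if self.overlap < 0 or self.overlap >= min(self.tile_height, self.tile_width):
            raise ValueError("overlap must be smaller than both tile dimensions")


@runtime_checkable
class SegmentationBackend(Protocol):
    """Anything that maps an RGB image to (LabelMap, per-id confidence)."""

    name: str

    def segment(self, image: np.ndarray) -> Tuple[LabelMap, Confidences]:
        ...


@dataclass(frozen=True)
class DualScaleConfig:
    """Combination rule for the fine (small-vessel) and coarse (large-vessel)
    passes: instances at least ``size_gate`` px big come from the coarse pass,
    smaller ones from the fine pass; cross-pass duplicates at
    IoU >= ``dedup_iou`` are resolved by confidence."""

    size_gate: int = 2000
    dedup_iou: float = 0.5
    scale_factor: int = 2

    def __post_init__(self) -> None:
        if self.scale_factor < 1:
            raise ValueError("scale_factor must be >= 1")
        if not 0.0 < self.dedup_iou <= 1.0:
            raise ValueError("dedup_iou must lie in (0, 1]")


def _axis_offsets(total: int, tile: int, step: int) -> List[int]:
    if total <= tile:
        return [0]
    offsets = list(range(0, total - tile, step))
    offsets.append(total - tile)
    return offsets


def make_tiles(image: np.ndarray, spec: TileSpec | None = None
               ) -> List[Tuple[np.ndarray, Tuple[int, int]]]:
    """Cut an image into overlapping tiles covering it completely.

    Returns (tile, (row_offset, col_offset)) pairs in raster order.  Trailing
    tiles are shifted (not shrunk) so every tile keeps the nominal size when
    the image is at least one tile big.
    """
    spec = spec or TileSpec()
    img = np.asarray(image)
    if img.ndim not in (2, 3) or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image must be a non-empty 2-D or 3-D array")
    h, w = img.shape[:2]
    row_step = spec.tile_height - spec.overlap
    col_step = spec.tile_width - spec.overlap
    tiles = []
    for r0 in _axis_offsets(h, spec.tile_height, row_step):
        for c0 in _axis_offsets(w, spec.tile_width, col_step):
            tile = img[r0:r0 + spec.tile_height, c0:c0 + spec.tile_width]
            tiles.append((tile, (r0, c0)))
    return tiles


def _instance_records(labels: np.ndarray, offset: Tuple[int, int],
                      confidences: Confidences, image_shape: Tuple[int, int]):
    """Yield (pixel rows, pixel cols, conf, clipped_at_inner_edge) in global
    coordinates for every instance of one tile output."""
    r0, c0 = offset
    th, tw = labels.shape
    h, w = image_shape
    objs = ndi.find_objects(labels)
    for i, sl in enumerate(objs, start=1):
        if sl is None:
            continue
        rs, cs = np.nonzero(labels[sl] == i)
        rs = rs + sl[0].start
        cs = cs + sl[1].start
        # clipped at a tile edge that is strictly inside the whole image?
        clipped = (
            (rs.min() == 0 and r0 > 0)
            or (rs.max() == th - 1 and r0 + th < h)
            or (cs.min() == 0 and c0 > 0)
            or (cs.max() == tw - 1 and c0 + tw < w)
        )
        yield rs + r0, cs + c0, float(confidences.get(i, 0.0)), bool(clipped)


def stitch(tile_outputs: Sequence[Tuple[LabelsLike, Tuple[int, int], Confidences]],
           image_shape: Tuple[int, int], dedup_iou: float = 0.5) -> LabelMap:
    """Merge per-tile label maps into one whole-image label map.

    Duplicates (IoU >= ``dedup_iou`` between instances of different tiles)
    keep the higher-confidence copy.  An instance clipped at a tile edge that
    lies strictly inside the image yields to an unclipped copy from another
    tile; two clipped copies of the same cell are merged by pixel union.
    Output ids are renumbered 1..N in raster order of first pixel.
    """
    h, w = image_shape
    records = []
    for labelmap, offset, confidences in tile_outputs:
        labels = as_labels(labelmap)
        r0, c0 = offset
        if r0 < 0 or c0 < 0 or r0 + labels.shape[0] > h or c0 + labels.shape[1] > w:
            raise ValueError(f"tile at offset {offset} exceeds image bounds {image_shape}")
        records.extend(_instance_records(labels, offset, confidences, (h, w)))
    # unclipped instances take priority, then by confidence (desc), then order
    order = sorted(range(len(records)),
                   key=lambda k: (records[k][3], -records[k][2], k))
    canvas = np.zeros((h, w), dtype=np.int32)
    accepted: List[dict] = []  # {"label": int, "area": int, "clipped": bool}
    next_label = 0
    for k in order:
        rs, cs, conf, clipped = records[k]
        area = len(rs)
        hit = canvas[rs, cs]
        overlap_labels, overlap_counts = np.unique(hit[hit > 0], return_counts=True)
        drop = False
        merge_into = 0
        for lab, inter in zip(overlap_labels, overlap_counts):
            other = accepted[lab - 1]
            iou = inter / (area + other["area"] - inter)
            if iou >= dedup_iou:
                drop = True  # duplicate of a higher-priority instance
                break
            if clipped and other["clipped"] and inter > 0:
                merge_into = int(lab)  # two partial views of one cell
                break
            if clipped and not other["clipped"] and inter > 0:
                drop = True  # a full view of this cell already exists
                break
        if drop:
            continue
        if merge_into:
            free = hit == 0
            canvas[rs[free], cs[free]] = merge_into
            accepted[merge_into - 1]["area"] += int(free.sum())
            continue
        next_label += 1
        free = hit == 0
        canvas[rs[free], cs[free]] = next_label
        accepted.append({"label": next_label, "area": int(free.sum()), "clipped": clipped})
    return LabelMap(_renumber_raster(canvas), normalize=False)


def _renumber_raster(labels: np.ndarray) -> np.ndarray:
    """Relabel 1..N in raster order of each id's first pixel."""
    flat = labels.ravel()
    nz = np.nonzero(flat)[0]
    if nz.size == 0:
        return np.zeros_like(labels)
    ids = flat[nz]
    first = {}
    for pos, i in zip(nz, ids):
        if i not in first:
            first[int(i)] = int(pos)
    order = sorted(first, key=first.get)
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        lut[old] = new
    return lut[labels]


def merge_dual_scale(fine: Tuple[LabelsLike, Confidences],
                     coarse_upsampled: Tuple[LabelsLike, Confidences],
                     cfg: DualScaleConfig | None = None) -> LabelMap:
    """Combine the small-vessel (fine) and large-vessel (coarse) passes.

    The coarse pass output must already be upsampled to the fine grid.
    Primary candidates are fine instances below the size gate and coarse
    instances at or above it; the complementary instances act as fallback and
    are kept only where no primary duplicate (IoU >= dedup_iou) exists.
    """
    cfg = cfg or DualScaleConfig()
    f_labels = as_labels(fine[0])
    c_labels = as_labels(coarse_upsampled[0])
    if f_labels.shape != c_labels.shape:
        raise ValueError("fine and upsampled coarse maps must share dimensions")

    candidates = []  # (primary, conf, source_order, rows, cols)
    for source_order, (labels, confs) in enumerate([(f_labels, fine[1]),
                                                    (c_labels, coarse_upsampled[1])]):
        objs = ndi.find_objects(labels)
        for i, sl in enumerate(objs, start=1):
            if sl is None:
                continue
            rs, cs = np.nonzero(labels[sl] == i)
            rs = rs + sl[0].start
            cs = cs + sl[1].start
            area = len(rs)
            is_fine = source_order == 0
            primary = (is_fine and area < cfg.size_gate) or \
                      (not is_fine and area >= cfg.size_gate)
            candidates.append((primary, float(confs.get(i, 0.0)), source_order, rs, cs))

    # primaries first, each group by confidence desc, fine before coarse on ties
    candidates.sort(key=lambda t: (not t[0], -t[1], t[2]))
    canvas = np.zeros(f_labels.shape, dtype=np.int32)
    areas: List[int] = []
    next_label = 0
    for primary, conf, source_order, rs, cs in candidates:
        area = len(rs)
        hit = canvas[rs, cs]
        labs, counts = np.unique(hit[hit > 0], return_counts=True)
        if any(inter / (area + areas[lab - 1] - inter) >= cfg.dedup_iou
               for lab, inter in zip(labs, counts)):
            continue
        next_label += 1
        free = hit == 0
        canvas[rs[free], cs[free]] = next_label
        areas.append(int(free.sum()))
    return LabelMap(_renumber_raster(canvas), normalize=False)


@dataclass(frozen=True)
class BaselineParams:
    """Parameters of the classical threshold + watershed segmenter.

    opening_radius : radius (px) of the morphological opening that removes
        speckle before componentisation.
    min_area / max_area : instance-size filter in pixels.
    threshold_classes : intensity classes for the automatic threshold; 3
        separates dark walls / mid tissue / bright lumens and keeps only the
        brightest class (falls back to a plain bimodal split when the
        histogram cannot support it).
    marker_fraction : watershed seeds are the connected plateaus where the
        distance transform reaches this fraction of its per-component
        maximum; lower values split touching lumens more aggressively.
    split_touching : run the distance-transform watershed at all.
    """

    opening_radius: int = 1
    min_area: int = 12
    max_area: int | None = None
    threshold_classes: int = 3
    marker_fraction: float = 0.6
    split_touching: bool = True


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        return rgb2gray(img[..., :3])
    gray = img.astype(np.float64)
    return gray / 255.0 if gray.max() > 1 else gray


def _lumen_threshold(gray: np.ndarray, params: BaselineParams) -> float:
    if params.threshold_classes > 2:
        try:
            return float(threshold_multiotsu(gray,
                                             classes=params.threshold_classes)[-1])
        except ValueError:
            pass  # histogram too simple for that many classes
    return float(threshold_otsu(gray))


def baseline_segment(image: np.ndarray, params: BaselineParams | None = None,
                     threshold: float | None = None
                     ) -> Tuple[LabelMap, Confidences]:
    """Classical reference segmentation of bright lumens on darker tissue.

    Grayscale -> automatic multi-class threshold (brightest class = lumen) ->
    morphological opening -> connected components -> distance-transform
    watershed to split touching lumens -> area filter.  Per-instance
    confidence is the instance's distance-peak height normalised by the
    image-wide maximum, a proxy for how unambiguous its interior is.  A
    constant image yields an empty map.

    ``threshold`` overrides the automatic choice — used when a whole-image
    threshold must be shared across tiles.
    """
    params = params or BaselineParams()
    gray = _to_gray(image)
    if gray.max() == gray.min():
        return LabelMap(np.zeros(gray.shape, dtype=np.int32), normalize=False), {}
    thr = threshold if threshold is not None else _lumen_threshold(gray, params)
    fg = gray > thr
    if params.opening_radius > 0:
        fg = ndi.binary_opening(fg, structure=disk(params.opening_radius))
    if not fg.any():
        return LabelMap(np.zeros(gray.shape, dtype=np.int32), normalize=False), {}

    distance = ndi.distance_transform_edt(fg)
    if params.split_touching:
        comp = binary_mask_to_labelmap(fg).labels
        ncomp = int(comp.max())
        comp_max = ndi.maximum(distance, comp, index=np.arange(1, ncomp + 1))
        comp_max = np.concatenate([[1.0], np.atleast_1d(comp_max)])
        marker_mask = fg & (distance >= params.marker_fraction * comp_max[comp])
        markers, _ = ndi.label(marker_mask, structure=np.ones((3, 3), dtype=bool))
        labels = watershed(-distance, markers, mask=fg)
    else:
        labels = binary_mask_to_labelmap(fg).labels.copy()

    # area filter
    areas = np.bincount(labels.ravel())
    kill = np.zeros(len(areas), dtype=bool)
    kill[1:] = areas[1:] < params.min_area
    if params.max_area is not None:
        kill[1:] |= areas[1:] > params.max_area
    labels[kill[labels]] = 0
    labelmap = LabelMap(labels)
    if labelmap.n_instances == 0:
        return labelmap, {}

    peak_height = ndi.maximum(distance, labelmap.labels,
                              index=np.arange(1, labelmap.n_instances + 1))
    top = float(distance.max()) or 1.0
    confidences = {i + 1: float(hv) / top for i, hv in enumerate(np.atleast_1d(peak_height))}
    return labelmap, confidences


class ThresholdWatershedBackend:
    """Backend wrapper around :func:`baseline_segment`.

    :meth:`calibrate` fixes the intensity threshold from a whole image so that
    tile-wise runs share one global threshold instead of re-estimating it on
    every tile (per-tile histograms can promote mid-tone structures such as
    rays into the lumen class).
    """

    def __init__(self, params: BaselineParams | None = None):
        self.name = "threshold-watershed"
        self.params = params or BaselineParams()
        self._threshold: float | None = None

    def calibrate(self, image: np.ndarray) -> None:
        gray = _to_gray(image)
        if gray.max() > gray.min():
            self._threshold = _lumen_threshold(gray, self.params)

    def segment(self, image: np.ndarray) -> Tuple[LabelMap, Confidences]:
        return baseline_segment(image, self.params, threshold=self._threshold)


def run_tiled(image: np.ndarray, backend: SegmentationBackend,
              spec: TileSpec | None = None, dedup_iou: float = 0.5) -> LabelMap:
    """Tile, segment every tile with the backend, stitch.

    Backends exposing a ``calibrate(image)`` method get the whole image first,
    so tile-level runs can share global statistics."""
    spec = spec or TileSpec()
    calibrate = getattr(backend, "calibrate", None)
    if callable(calibrate):
        calibrate(image)
    outputs = []
    for tile, offset in make_tiles(image, spec):
        labelmap, confidences = backend.segment(tile)
        outputs.append((labelmap, offset, confidences))
    return stitch(outputs, np.asarray(image).shape[:2], dedup_iou=dedup_iou)


def run_dual_scale(image: np.ndarray, backend: SegmentationBackend,
                   cfg: DualScaleConfig | None = None,
                   spec: TileSpec | None = None) -> LabelMap:
    """Run the fine pass at native resolution and the coarse pass at
    1/scale_factor resolution (upsampled back), then merge with the size gate."""
    cfg = cfg or DualScaleConfig()
    img = np.asarray(image)
    fine_map = run_tiled(img, backend, spec, dedup_iou=cfg.dedup_iou)
    s = cfg.scale_factor
    small = img[::s, ::s] if img.ndim == 2 else img[::s, ::s, :]
    coarse_map = run_tiled(small, backend, spec, dedup_iou=cfg.dedup_iou)
    up = np.kron(coarse_map.labels, np.ones((s, s), dtype=np.int32))
    up = up[:img.shape[0], :img.shape[1]]
    if up.shape[0] < img.shape[0] or up.shape[1] < img.shape[1]:
        up = np.pad(up, ((0, img.shape[0] - up.shape[0]),
                         (0, img.shape[1] - up.shape[1])))
    fine_conf = {i: 1.0 for i in range(1, fine_map.n_instances + 1)}
    coarse_conf = {i: 1.0 for i in range(1, coarse_map.n_instances + 1)}
    return merge_dual_scale((fine_map, fine_conf), (LabelMap(up), coarse_conf), cfg)
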
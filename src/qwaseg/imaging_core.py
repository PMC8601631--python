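"""Data model and I/O for section images, label maps, instances and boxes.

Conventions used throughout the package:

* arrays are indexed ``(row, col)`` with the origin at the top-left corner and
  y increasing downward (standard raster order);
* a :class:`LabelMap` stores one non-negative integer per pixel, ``0`` meaning
  background and each positive id one cell instance's lumen pixels;
* after normalisation the ids of a label map are exactly ``1..N`` with no gaps;
* bounding boxes use 0-based *inclusive* min/max pixel coordinates, ``x``
  being the column and ``y`` the row.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, List, Union

import numpy as np
from scipy import ndimage as ndi

import imageio.v3 as iio

__all__ = [
    "BBox",
    "Instance",
    "LabelMap",
    "binary_mask_to_labelmap",
    "extract_instances",
    "labelmap_to_boxes",
    "load_annotation",
    "save_labelmap",
    "as_labels",
]

#: neighbourhood structures for connected components
_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box with inclusive pixel bounds (x = column, y = row)."""

    min_x: int
    min_y: int
    max_x: int
    max_y: int

    def __post_init__(self) -> None:
        if self.min_x > self.max_x or self.min_y > self.max_y:
            raise ValueError(f"degenerate bbox: {self}")

    @property
    def width(self) -> int:
        return self.max_x - self.min_x + 1

    @property
    def height(self) -> int:
        return self.max_y - self.min_y + 1


@dataclass(frozen=True)
class Instance:
    """One connected cell instance extracted from a label map."""

    id: int
    area: int
    bbox: BBox
    touches_border: bool
    centroid: tuple  # (row, col)


class LabelMap:
    """2-D map of non-negative instance ids; 0 is background.

    Construction normalises ids to ``1..N`` (ascending original id order) and
    validates the grid.  The underlying array is read-only.
    """

    def __init__(self, labels: np.ndarray, normalize: bool = True):
        arr = np.asarray(labels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("a label map must be a non-empty 2-D integer grid")
        if not np.issubdtype(arr.dtype, np.integer):
            if np.issubdtype(arr.dtype, np.bool_):
                raise TypeError("boolean mask given; use binary_mask_to_labelmap")
            raise TypeError(f"label map must be integer-valued, got dtype {arr.dtype}")
        if arr.min() < 0:
            raise ValueError("label map contains negative ids")
        arr = arr.astype(np.int32, copy=True)
        if normalize:
            ids = np.unique(arr)
            ids = ids[ids > 0]
            if ids.size and (ids[0] != 1 or ids[-1] != ids.size):
                lut = np.zeros(int(ids[-1]) + 1, dtype=np.int32)
                lut[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
                arr = lut[arr]
            n = int(ids.size)
        else:
            n = int(arr.max())
        arr.setflags(write=False)
        self._labels = arr
        self._n = n

    @property
    def labels(self) -> np.ndarray:
        return self._labels

    @property
    def n_instances(self) -> int:
        return self._n

    @property
    def shape(self) -> tuple:
        return self._labels.shape

    @property
    def height(self) -> int:
        return self._labels.shape[0]

    @property
    def width(self) -> int:
        return self._labels.shape[1]

    def ids(self) -> np.ndarray:
        return np.arange(1, self._n + 1)

    def areas(self) -> np.ndarray:
        """Pixel area per id, index 0 unused (area of background not counted)."""
        return np.bincount(self._labels.ravel(), minlength=self._n + 1)

    def mask_of(self, instance_id: int) -> np.ndarray:
        return self._labels == instance_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelMap):
            return NotImplemented
        return self._labels.shape == other._labels.shape and bool(
            np.array_equal(self._labels, other._labels)
        )

    def __repr__(self) -> str:
        h, w = self._labels.shape
        return f"LabelMap({h}x{w}, {self._n} instances)"


LabelsLike = Union[LabelMap, np.ndarray]


def as_labels(obj: LabelsLike) -> np.ndarray:
    """Coerce a :class:`LabelMap` or raw integer array to a label array."""
    if isinstance(obj, LabelMap):
        return obj.labels
    return LabelMap(obj).labels


def binary_mask_to_labelmap(mask: np.ndarray, connectivity: int = 8) -> LabelMap:
    """Componentise a boolean mask: each maximal connected true-region becomes
    one instance, ids assigned in raster-scan order of first-encountered pixel.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError("mask must be a non-empty 2-D grid")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    labeled, _ = ndi.label(mask.astype(bool), structure=_STRUCTURES[connectivity])
    return LabelMap(labeled, normalize=False)


def load_annotation(path: Union[str, os.PathLike], kind: str = "binary_mask",
                    connectivity: int = 8) -> LabelMap:
    """Load a ground-truth annotation file.

    ``kind="binary_mask"``: a drawn mask (any raster format).  When an alpha
    channel is present, pixels with nonzero alpha are foreground (annotations
    drawn on a transparent layer); otherwise any pixel with nonzero luminance.
    The mask is then componentised with the given connectivity.

    ``kind="label_map"``: a single-channel (typically 16-bit) image whose pixel
    values are instance ids, normalised to ``1..N`` on load.
    """
    if kind not in ("binary_mask", "label_map"):
        raise ValueError(f"unknown annotation kind {kind!r}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific messages
        raise ValueError(f"cannot decode image file {path}: {exc}") from exc
    if kind == "label_map":
        if arr.ndim != 2:
            raise ValueError(
                f"{path}: a label map must be a single-channel image with "
                f"integer ids; got shape {arr.shape}"
            )
        return LabelMap(arr.astype(np.int64))
    if arr.ndim == 2:
        fg = arr > 0
    elif arr.ndim == 3 and arr.shape[2] == 4:
        fg = arr[..., 3] > 0
    elif arr.ndim == 3:
        fg = arr.astype(np.float64).sum(axis=2) > 0
    else:
        raise ValueError(f"{path}: unsupported image shape {arr.shape}")
    return binary_mask_to_labelmap(fg, connectivity=connectivity)


def save_labelmap(labelmap: LabelsLike, path: Union[str, os.PathLike]) -> None:
    """Write a label map as a losslessly round-tripping 16-bit grayscale PNG."""
    labels = as_labels(labelmap)
    n = int(labels.max())
    if n > 65535:
        raise ValueError(f"label map has {n} ids; 16-bit PNG holds at most 65535")
    iio.imwrite(path, labels.astype(np.uint16), extension=".png")


def extract_instances(labelmap: LabelsLike) -> List[Instance]:
    """One :class:`Instance` per id, sorted by id.

    Areas sum to the nonzero pixel count of the map; ``touches_border`` is
    true iff at least one pixel lies on the outermost row/column frame.
    """
    labels = as_labels(labelmap)
    n = int(labels.max())
    if n == 0:
        return []
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    # per-id extents via per-row/col presence
    objs = ndi.find_objects(labels)
    # centroid sums
    centroids = ndi.center_of_mass(labels > 0, labels, index=np.arange(1, n + 1))
    border_ids = set(_frame_ids(labels))
    out: List[Instance] = []
    for i in range(1, n + 1):
        sl = objs[i - 1]
        if sl is None:  # id absent (cannot happen on normalized maps)
            continue
        rs, cs = sl
        bbox = BBox(min_x=int(cs.start), min_y=int(rs.start),
                    max_x=int(cs.stop - 1), max_y=int(rs.stop - 1))
        out.append(Instance(
            id=i,
            area=int(areas[i]),
            bbox=bbox,
            touches_border=i in border_ids,
            centroid=(float(centroids[i - 1][0]), float(centroids[i - 1][1])),
        ))
    return out


def labelmap_to_boxes(labelmap: LabelsLike) -> List[BBox]:
    """Minimal enclosing box per id: the min/max x and y pixel coordinates of
    each connected component, in id order."""
    return [inst.bbox for inst in extract_instances(labelmap)]


def _frame_ids(labels: np.ndarray) -> np.ndarray:
    """Ids with at least one pixel on the outer frame of the grid."""
    frame = np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]
    ])
    ids = np.unique(frame)
    return ids[ids > 0]
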
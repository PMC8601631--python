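"""Label-map data model, connected components, and lossless annotation I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from qwaseg import (
    BBox,
    LabelMap,
    binary_mask_to_labelmap,
    extract_instances,
    labelmap_to_boxes,
    load_annotation,
    save_labelmap,
)

from conftest import random_rect_labelmap


def flood_fill_count(mask, connectivity=8):
    """Independent component counter: breadth-first flood fill."""
    mask = mask.astype(bool)
    seen = np.zeros_like(mask)
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    h, w = mask.shape
    count = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                count += 1
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in steps:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] \
                                and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
    return count


class TestBinaryMaskToLabelmap:
    def test_all_false_mask_gives_empty_map(self):
        lm = binary_mask_to_labelmap(np.zeros((5, 7), dtype=bool))
        assert lm.n_instances == 0
        assert (lm.labels == 0).all()

    def test_raster_order_of_ids(self):
        mask = np.zeros((5, 9), dtype=bool)
        mask[1:4, 6:8] = True   # right blob
        mask[2:4, 0:2] = True   # left blob, first pixel later in raster order
        lm = binary_mask_to_labelmap(mask, connectivity=8)
        assert lm.n_instances == 2
        assert lm.labels[1, 6] == 1  # first-encountered blob gets id 1
        assert lm.labels[2, 0] == 2

    def test_connectivity_four_vs_eight_on_diagonal(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        assert binary_mask_to_labelmap(mask, connectivity=8).n_instances == 1
        assert binary_mask_to_labelmap(mask, connectivity=4).n_instances == 2

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            binary_mask_to_labelmap(np.zeros((0, 0), dtype=bool))

    @pytest.mark.parametrize("connectivity", [4, 8])
    @pytest.mark.parametrize("seed", range(5))
    def test_component_count_matches_flood_fill_oracle(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        mask = rng.random((40, 40)) < 0.35
        lm = binary_mask_to_labelmap(mask, connectivity=connectivity)
        assert lm.n_instances == flood_fill_count(mask, connectivity)


class TestLabelMapType:
    def test_normalisation_closes_id_gaps(self):
        arr = np.zeros((4, 6), dtype=np.int32)
        arr[0, 0:2] = 5
        arr[2, 3:5] = 9
        lm = LabelMap(arr)
        assert sorted(np.unique(lm.labels)) == [0, 1, 2]
        assert (lm.labels > 0).sum() == 4  # geometry preserved

    def test_negative_ids_rejected(self):
        with pytest.raises(ValueError):
            LabelMap(np.full((3, 3), -1))

    def test_boolean_array_rejected_with_hint(self):
        with pytest.raises(TypeError, match="binary_mask_to_labelmap"):
            LabelMap(np.ones((3, 3), dtype=bool))


class TestAnnotationIO:
    def test_binary_mask_png_componentised(self, tmp_path):
        import imageio.v3 as iio
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[2:5, 2:5] = 255
        mask[10:14, 10:13] = 255
        mask[16:18, 2:4] = 255
        path = tmp_path / "mask.png"
        iio.imwrite(path, mask)
        lm = load_annotation(path, kind="binary_mask")
        assert lm.n_instances == 3

    def test_alpha_channel_wins_for_rgba_masks(self, tmp_path):
        import imageio.v3 as iio
        rgba = np.zeros((10, 10, 4), dtype=np.uint8)
        rgba[..., :3] = 255           # fully white everywhere
        rgba[3:6, 3:6, 3] = 255       # but only a 3x3 patch is opaque
        path = tmp_path / "mask.png"
        iio.imwrite(path, rgba)
        lm = load_annotation(path, kind="binary_mask")
        assert lm.n_instances == 1
        assert (lm.labels > 0).sum() == 9

    def test_labelmap_roundtrip_identity(self, tmp_path):
        rng = np.random.default_rng(3)
        lm = random_rect_labelmap(rng, shape=(48, 48), max_instances=8)
        path = tmp_path / "labels.png"
        save_labelmap(lm, path)
        back = load_annotation(path, kind="label_map")
        assert back == lm

    def test_sixteen_bit_ids_normalised_on_load(self, tmp_path):
        import imageio.v3 as iio
        arr = np.zeros((8, 8), dtype=np.uint16)
        arr[0:2, 0:2] = 5
        arr[5:7, 5:7] = 9
        path = tmp_path / "labels.png"
        iio.imwrite(path, arr)
        lm = load_annotation(path, kind="label_map")
        assert sorted(np.unique(lm.labels)) == [0, 1, 2]

    def test_multichannel_file_rejected_as_labelmap(self, tmp_path):
        import imageio.v3 as iio
        path = tmp_path / "rgb.png"
        iio.imwrite(path, np.zeros((8, 8, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="single-channel"):
            load_annotation(path, kind="label_map")

    def test_capacity_error_beyond_16bit(self, tmp_path):
        arr = np.arange(70000, dtype=np.int64).reshape(200, 350)
        with pytest.raises(ValueError, match="65535"):
            save_labelmap(LabelMap(arr, normalize=False), tmp_path / "big.png")


class TestInstancesAndBoxes:
    def test_corner_square_touches_border(self):
        arr = np.zeros((10, 10), dtype=np.int32)
        arr[0:5, 0:5] = 1
        inst, = extract_instances(arr)
        assert inst.area == 25
        assert inst.touches_border
        assert inst.bbox == BBox(min_x=0, min_y=0, max_x=4, max_y=4)

    def test_centered_square_centroid_and_border(self):
        arr = np.zeros((10, 10), dtype=np.int32)
        arr[4:7, 4:7] = 1
        inst, = extract_instances(arr)
        assert not inst.touches_border
        assert inst.centroid == (5.0, 5.0)

    def test_l_shape_box_is_minimal_rectangle(self):
        arr = np.zeros((12, 12), dtype=np.int32)
        arr[2:8, 3:5] = 1
        arr[6:8, 3:10] = 1
        box, = labelmap_to_boxes(arr)
        assert (box.min_y, box.max_y, box.min_x, box.max_x) == (2, 7, 3, 9)

    @pytest.mark.parametrize("seed", range(5))
    def test_areas_and_boxes_match_pixel_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lm = random_rect_labelmap(rng, shape=(50, 50))
        instances = extract_instances(lm)
        assert sum(i.area for i in instances) == int((lm.labels > 0).sum())
        for inst in instances:
            rs, cs = np.nonzero(lm.labels == inst.id)
            assert inst.area == len(rs)
            assert inst.bbox == BBox(min_x=int(cs.min()), min_y=int(rs.min()),
                                     max_x=int(cs.max()), max_y=int(rs.max()))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hnp.arrays(np.int8, (12, 15), elements=st.integers(0, 3)))
    def test_area_conservation_property(self, arr):
        lm = LabelMap(arr.astype(np.int32))
        assert sum(i.area for i in extract_instances(lm)) == int((lm.labels > 0).sum())
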
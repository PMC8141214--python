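"""Brush, grow/shrink, merge, and region-table behavior."""

import numpy as np
import pytest

from nucledit import (
    ImageVolume,
    InvalidSelectionError,
    LabelVolume,
    RegionMetadata,
    RegionUnreachableError,
    UnknownLabelError,
    build_region_table,
    count_regions,
    erase,
    grow_region,
    mark_done,
    merge_regions,
    paint,
    shrink_region,
)
from oracles import grow_eligible_brute_force


def _empty(shape=(1, 5, 5)):
    return LabelVolume(np.zeros(shape, dtype=np.int32))


class TestBrush:
    def test_radius_zero_sets_one_voxel(self):
        out = paint(_empty(), 3, 0, (2, 2), 0)
        assert (out.data == 3).sum() == 1
        assert out.data[0, 2, 2] == 3

    def test_radius_one_sets_center_plus_face_neighbors(self):
        out = paint(_empty(), 1, 0, (2, 2), 1)
        # distance <= 1: center and the 4 in-plane face neighbors
        assert (out.data == 1).sum() == 5
        assert out.data[0, 2, 2] == 1 and out.data[0, 1, 2] == 1
        assert out.data[0, 1, 1] == 0  # diagonal is sqrt(2) > 1

    def test_paint_overwrites_other_region_and_flags_it(self):
        labels = _empty()
        labels.data[0, 2, 2] = 7
        meta = RegionMetadata()
        out = paint(LabelVolume(labels.data), 1, 0, (2, 2), 0, meta)
        assert out.data[0, 2, 2] == 1
        assert meta.status(1).modified and meta.status(7).modified

    def test_erase_only_touches_own_label(self):
        labels = _empty()
        labels.data[0, 2, 1] = 1
        labels.data[0, 2, 3] = 2
        out = erase(labels, 1, 0, (2, 2), 2)
        assert out.data[0, 2, 1] == 0
        assert out.data[0, 2, 3] == 2

    def test_erasing_whole_region_removes_it_from_table(self):
        labels = _empty()
        labels.data[0, 2, 2] = 1
        meta = RegionMetadata()
        meta.set_done(1, True)
        out = erase(labels, 1, 0, (2, 2), 1, meta)
        table = build_region_table(out, meta)
        assert len(table) == 0
        assert 1 not in meta.entries

    def test_invalid_label_rejected(self):
        with pytest.raises(UnknownLabelError):
            paint(_empty(), 0, 0, (2, 2), 1)


class TestGrow:
    def test_ramp_grows_to_selected_intensity_and_distance(self, ramp_fixture):
        image, labels = ramp_fixture
        out = grow_region(image, labels, 1, (0, 2, 2))  # select the 80-voxel
        grown = set(map(tuple, np.argwhere(out.data[0] == 1)))
        assert grown == {(2, 0), (2, 1), (2, 2)}  # 100, 90, 80; 70 excluded

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(15):
            img2d = rng.integers(0, 100, size=(7, 7)).astype(np.uint8)
            region2d = np.zeros((7, 7), dtype=bool)
            region2d[3, 3] = region2d[3, 4] = True
            sel = (int(rng.integers(0, 7)), int(rng.integers(0, 7)))
            if region2d[sel]:
                continue
            image = ImageVolume(img2d[None])
            labels = LabelVolume(np.where(region2d, 1, 0)[None].astype(np.int32))
            out = grow_region(image, labels, 1, (0, *sel))
            expected = grow_eligible_brute_force(img2d, region2d, sel)
            assert np.array_equal(out.data[0] == 1, expected)

    def test_bright_voxel_beyond_distance_excluded(self):
        img = np.zeros((1, 5, 5), dtype=np.uint8)
        img[0, 2] = [50, 40, 40, 0, 200]
        labels = _empty()
        labels.data[0, 2, 0] = 1
        out = grow_region(ImageVolume(img), labels, 1, (0, 2, 2))  # d* = 2
        assert out.data[0, 2, 4] == 0  # bright but at distance 4

    def test_never_annexes_other_labels(self):
        img = ImageVolume(np.full((1, 5, 5), 50, dtype=np.uint8))
        labels = _empty()
        labels.data[0, 2, 0] = 1
        labels.data[0, 2, 2] = 2
        out = grow_region(img, labels, 1, (0, 2, 3))
        assert out.data[0, 2, 2] == 2

    def test_selected_voxel_inside_region_warns_noop(self, ramp_fixture):
        image, labels = ramp_fixture
        with pytest.warns(UserWarning):
            out = grow_region(image, labels, 1, (0, 2, 0))
        assert np.array_equal(out.data, labels.data)

    def test_region_absent_from_slice_unreachable(self):
        img = ImageVolume(np.zeros((2, 3, 3), dtype=np.uint8))
        labels = LabelVolume(np.zeros((2, 3, 3), dtype=np.int32))
        labels.data[0, 1, 1] = 1
        with pytest.raises(RegionUnreachableError):
            grow_region(img, labels, 1, (1, 0, 0))

    def test_monotonic_in_selected_intensity(self, rng):
        """A brighter selection grows a subset of a dimmer one at the same spot."""
        img2d = rng.integers(0, 100, size=(9, 9)).astype(np.uint8)
        img2d[4, 4] = 100
        region = np.zeros((9, 9), dtype=bool)
        region[4, 4] = True
        sel = (4, 7)
        lo = img2d.copy()
        hi = img2d.copy()
        lo[sel], hi[sel] = 20, 70
        labels = LabelVolume(np.where(region, 1, 0)[None].astype(np.int32))
        out_lo = grow_region(ImageVolume(lo[None]), labels, 1, (0, *sel))
        out_hi = grow_region(ImageVolume(hi[None]), labels, 1, (0, *sel))
        assert not ((out_hi.data == 1) & ~(out_lo.data == 1)).any()


class TestShrink:
    def test_dimmest_boundary_voxel_removed(self, ramp_fixture):
        image, labels = ramp_fixture
        grown = grow_region(image, labels, 1, (0, 2, 2))
        out = shrink_region(image, grown, 1, (0, 2, 2))
        kept = set(map(tuple, np.argwhere(out.data[0] == 1)))
        # shrink removes intensity <= 80; the 90-voxel stays by the rule
        assert (2, 2) not in kept
        assert kept == {(2, 0), (2, 1)}

    def test_shielded_deeper_voxel_retained(self):
        # dim interior voxel shielded by brighter ring, deeper than selection
        img = np.full((1, 7, 7), 100, dtype=np.uint8)
        img[0, 3, 3] = 10  # dim but interior
        img[0, 1, 1] = 20  # dim boundary voxel
        labels = _empty((1, 7, 7))
        labels.data[0, 1:6, 1:6] = 1
        out = shrink_region(ImageVolume(img), labels, 1, (0, 1, 1))
        assert out.data[0, 1, 1] == 0  # boundary voxel at the selection removed
        assert out.data[0, 3, 3] == 1  # interior voxel deeper than selection kept

    def test_voxel_outside_region_invalid(self, ramp_fixture):
        image, labels = ramp_fixture
        with pytest.raises(InvalidSelectionError):
            shrink_region(image, labels, 1, (0, 0, 0))

    def test_only_selected_slice_changes(self, rng):
        img = ImageVolume(rng.integers(0, 100, size=(3, 6, 6)).astype(np.uint8))
        data = np.zeros((3, 6, 6), dtype=np.int32)
        data[:, 2:5, 2:5] = 1
        labels = LabelVolume(data)
        out = shrink_region(img, labels, 1, (1, 2, 2))
        assert np.array_equal(out.data[0], data[0])
        assert np.array_equal(out.data[2], data[2])


class TestMerge:
    def _two_regions(self):
        data = np.zeros((2, 5, 5), dtype=np.int32)
        data[:, :2, :] = 1  # 20 voxels
        data[:, 3:, :] = 2  # 20 voxels
        data[0, 3, 0] = 2
        return LabelVolume(data)

    def test_conservation_and_count(self):
        labels = self._two_regions()
        before = (labels.data > 0).sum()
        n_before = count_regions(labels)
        out = merge_regions(labels, 1, 2)
        assert (out.data > 0).sum() == before
        assert count_regions(out) == n_before - 1
        assert not (out.data == 2).any()

    def test_metadata_updated(self):
        labels = self._two_regions()
        meta = RegionMetadata()
        meta.set_done(2, True)
        merge_regions(labels, 1, 2, meta)
        assert meta.status(1).modified
        assert 2 not in meta.entries

    def test_absent_label_rejected(self):
        with pytest.raises(UnknownLabelError):
            merge_regions(self._two_regions(), 1, 9)

    def test_self_merge_warns_noop(self):
        labels = self._two_regions()
        with pytest.warns(UserWarning):
            out = merge_regions(labels, 1, 1)
        assert np.array_equal(out.data, labels.data)


class TestRegionTable:
    def test_empty_labels_empty_table(self):
        assert len(build_region_table(_empty())) == 0

    def test_sizes_bboxes_and_sorting(self):
        data = np.zeros((3, 6, 6), dtype=np.int32)
        data[0, 0, 0:2] = 5  # 2 voxels
        data[1:3, 2:5, 1:4] = 9  # 18 voxels
        table = build_region_table(LabelVolume(data))
        assert table.get(5).size == 2
        assert table.get(5).bbox == (0, 0, 0, 0, 0, 1)
        assert table.get(9).size == 18
        assert table.get(9).bbox == (1, 2, 2, 4, 1, 3)
        by_size = table.sorted("size", descending=True)
        assert [r.label for r in by_size] == [9, 5]
        assert table.total_voxels == 20

    def test_flags_merged_from_metadata(self):
        data = np.zeros((1, 3, 3), dtype=np.int32)
        data[0, 0, 0] = 1
        data[0, 2, 2] = 2
        meta = RegionMetadata()
        meta.set_done(1, True)
        table = build_region_table(LabelVolume(data), meta)
        assert table.get(1).done and not table.get(2).done
        assert table.n_done == 1

    def test_mark_done_toggles_and_validates(self):
        data = np.zeros((1, 3, 3), dtype=np.int32)
        data[0, 1, 1] = 4
        labels = LabelVolume(data)
        meta = RegionMetadata()
        mark_done(meta, 4, True, labels)
        assert meta.status(4).done
        mark_done(meta, 4, False, labels)
        assert not meta.status(4).done
        with pytest.raises(UnknownLabelError):
            mark_done(meta, 5, True, labels)
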
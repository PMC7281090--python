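import numpy as np
import pandas as pd
import pytest

from silverquant.io import BinaryMask, ROIMask, ValidationError
from silverquant.quantify import (
    DEFAULT_BIN_EDGES,
    build_report,
    components,
    iou,
    quantify_density,
    size_histogram,
)

from oracles import flood_fill_components


def bmask(arr):
    return BinaryMask(np.asarray(arr, bool))


class TestComponents:
    def test_empty_mask_empty_table(self):
        t = components(bmask(np.zeros((5, 5))), mpp=1.0)
        assert len(t) == 0

    def test_two_blocks_areas_at_half_micron_mpp(self):
        m = np.zeros((10, 10), bool)
        m[1:3, 1:3] = True  # 4 px
        m[6:9, 5:8] = True  # 9 px
        t = components(bmask(m), mpp=0.5)
        assert sorted(t["pixel_count"]) == [4, 9]
        assert sorted(t["area_um2"]) == pytest.approx([1.0, 2.25])

    def test_diagonal_contact_connectivity(self):
        m = np.zeros((6, 6), bool)
        m[1:3, 1:3] = True
        m[3:5, 3:5] = True  # touches only at corner (2,2)-(3,3)
        assert len(components(bmask(m), 1.0, connectivity=2)) == 1
        assert len(components(bmask(m), 1.0, connectivity=1)) == 2

    def test_ids_ordered_by_bbox_topleft(self):
        m = np.zeros((10, 10), bool)
        m[7:9, 0:2] = True
        m[0:2, 7:9] = True
        m[3:5, 3:5] = True
        t = components(bmask(m), 1.0)
        assert list(t["component_id"]) == [1, 2, 3]
        assert list(t["bbox_row0"]) == [0, 3, 7]

    def test_roi_clipping_and_border_exclusion(self):
        m = np.zeros((12, 12), bool)
        m[2:5, 2:5] = True  # fully inside the ROI
        m[4:8, 8:12] = True  # straddles the ROI's right edge
        roi = np.zeros((12, 12), bool)
        roi[:, :10] = True
        clipped = components(bmask(m), 1.0, roi=ROIMask(roi))
        assert sorted(clipped["pixel_count"]) == [8, 9]  # 4x2 in-ROI remnant
        only_inside = components(bmask(m), 1.0, roi=ROIMask(roi), exclude_border=True)
        assert list(only_inside["pixel_count"]) == [9]

    def test_bad_mpp_rejected(self):
        with pytest.raises(ValidationError):
            components(bmask(np.ones((2, 2))), mpp=0.0)

    def test_agrees_with_floodfill_oracle_on_random_masks(self, rng):
        """Count and per-component pixel sets match a BFS oracle, 100 masks."""
        for i in range(100):
            m = rng.random((64, 64)) < rng.uniform(0.05, 0.5)
            t = components(bmask(m), mpp=1.0)
            want = flood_fill_components(m, connectivity=2)
            assert len(t) == len(want)
            assert int(t["pixel_count"].sum()) == int(m.sum())
            # reconstruct pixel sets from labeling via bounding boxes + count
            want_sizes = sorted(len(c) for c in want)
            assert sorted(t["pixel_count"]) == want_sizes


class TestDensity:
    def test_500_positive_px_in_one_mm2(self):
        roi = ROIMask(np.ones((1000, 1000), bool))
        m = np.zeros((1000, 1000), bool)
        m.flat[:500] = True
        d = quantify_density(bmask(m), roi, mpp=1.0)
        assert d.positive_px_per_mm2 == pytest.approx(500.0)
        assert d.percent_positive == pytest.approx(0.05)

    def test_saturated_roi(self):
        roi = ROIMask(np.ones((100, 100), bool))
        d = quantify_density(bmask(np.ones((100, 100))), roi, mpp=1.0)
        assert d.percent_positive == 100.0
        assert d.positive_px_per_mm2 == pytest.approx(1e6)

    def test_empty_mask_zero(self):
        roi = ROIMask(np.ones((50, 50), bool))
        d = quantify_density(bmask(np.zeros((50, 50))), roi, mpp=0.5)
        assert d.positive_px_per_mm2 == 0 and d.percent_positive == 0

    def test_positives_outside_roi_excluded(self):
        roi = np.zeros((10, 10), bool)
        roi[:5] = True
        m = np.ones((10, 10), bool)
        d = quantify_density(bmask(m), ROIMask(roi), mpp=1.0)
        assert d.percent_positive == 100.0
        assert d.positive_pixels == 50

    def test_empty_roi_rejected(self):
        with pytest.raises(ValidationError):
            quantify_density(
                bmask(np.zeros((4, 4))), ROIMask(np.zeros((4, 4), bool)), 1.0
            )

    def test_invariant_px_per_mm2_vs_percent(self, rng):
        roi = ROIMask(rng.random((64, 64)) > 0.2)
        m = rng.random((64, 64)) > 0.8
        mpp = 0.25
        d = quantify_density(bmask(m), roi, mpp)
        px_per_mm2_at_mpp = 1e6 / mpp**2
        assert d.positive_px_per_mm2 == pytest.approx(
            d.percent_positive / 100 * px_per_mm2_at_mpp
        )


class TestSizeHistogram:
    def _table(self, areas):
        return pd.DataFrame(
            {
                "component_id": range(1, len(areas) + 1),
                "slide_id": "s",
                "pixel_count": 1,
                "area_um2": areas,
            }
        )

    def test_empty_table_all_zero(self):
        h = size_histogram(self._table([]))
        assert h.counts.sum() == 0

    def test_known_areas_land_in_expected_bins(self):
        h = size_histogram(self._table([1.0, 2.25, 25.0]))
        # default edges 0.25/0.5/2/10/50/200/inf
        assert list(h.counts) == [0, 1, 1, 1, 0, 0]

    def test_area_conservation(self, rng):
        areas = list(rng.uniform(0.3, 300.0, 50))
        h = size_histogram(self._table(areas))
        assert h.counts.sum() == 50
        assert h.summed_area_um2.sum() == pytest.approx(sum(areas))

    def test_non_ascending_edges_rejected(self):
        with pytest.raises(ValidationError):
            size_histogram(self._table([1.0]), bin_edges=(1.0, 1.0, 2.0))

    def test_dominant_bin_tie_goes_to_larger_area(self):
        h = size_histogram(self._table([1.0, 25.0]))
        assert h.dominant_bin == 3  # [10, 50) beats [0.5, 2) on the tie


class TestReportAndIoU:
    def test_single_slide_means_and_zero_sd(self):
        roi = ROIMask(np.ones((100, 100), bool))
        m = np.zeros((100, 100), bool)
        m[:10, :10] = True
        d = quantify_density(bmask(m), roi, 1.0, organ_label="liver", slide_id="L0")
        t = components(bmask(m), 1.0, slide_id="L0")
        rep = build_report([d], [t])
        s = rep.organs["liver"]
        assert s.mean_px_per_mm2 == pytest.approx(d.positive_px_per_mm2)
        assert s.sd_px_per_mm2 == 0.0

    def test_report_total_identity_one_slide_per_organ(self, rng):
        stats, tables = [], []
        total_pos = 0
        for organ in ["tumor", "liver"]:
            m = rng.random((200, 200)) > 0.9
            total_pos += int(m.sum())
            roi = ROIMask(np.ones((200, 200), bool))
            stats.append(quantify_density(bmask(m), roi, 1.0, organ, organ + "_0"))
            tables.append(components(bmask(m), 1.0, slide_id=organ + "_0"))
        rep = build_report(stats, tables)
        back = sum(
            rep.organs[o].mean_px_per_mm2 * stats[i].roi_area_mm2
            for i, o in enumerate(["tumor", "liver"])
        )
        assert back == pytest.approx(total_pos)

    def test_iou_basics(self):
        full = bmask(np.ones((4, 4)))
        left = bmask(np.c_[np.ones((4, 2)), np.zeros((4, 2))])
        empty = bmask(np.zeros((4, 4)))
        assert iou(full, full) == 1.0
        assert iou(empty, empty) == 1.0
        assert iou(full, left) == pytest.approx(0.5)
        assert iou(left, bmask(np.c_[np.zeros((4, 2)), np.ones((4, 2))])) == 0.0
        with pytest.raises(ValidationError):
            iou(full, bmask(np.ones((3, 3))))
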
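"""Preprocessing and segmentation: 8-bit conversion, Otsu, components,
size filter, frame cropping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mscstage.segment import (
    FieldImage,
    NucleusRegion,
    crop_frames,
    max_frame_size,
    otsu_threshold,
    segment_nuclei,
    size_filter,
    to_uint8_minmax,
)


def brute_force_otsu(img: np.ndarray) -> int:
    """Independent oracle: exhaustive between-class-variance scan."""
    hist = np.bincount(img.ravel().astype(int), minlength=256).astype(float)
    n = hist.sum()
    best_t, best_v = 0, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = n - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (np.arange(t + 1) * hist[: t + 1]).sum() / w0
        mu1 = (np.arange(t + 1, 256) * hist[t + 1 :]).sum() / w1
        v = (w0 / n) * (w1 / n) * (mu0 - mu1) ** 2
        if v > best_v:  # strict: ties stay at the smallest threshold
            best_v, best_t = v, t
    return best_t


class TestToUint8:
    def test_endpoints_forced(self):
        out = to_uint8_minmax(np.array([[100, 355]]))
        assert out.tolist() == [[0, 255]]

    def test_constant_maps_to_zero(self):
        assert np.all(to_uint8_minmax(np.full((5, 5), 777)) == 0)

    def test_rounding_half_to_even(self):
        # midpoint value 127.5 rounds to 128? No: numpy rint -> 128 is even
        out = to_uint8_minmax(np.array([0.0, 1.0, 2.0]))
        assert out.tolist() == [0, 128, 255]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        arrays(np.int32, (6, 7), elements=st.integers(0, 60000)),
        st.integers(1, 5),
        st.integers(0, 1000),
    )
    def test_positive_affine_invariance(self, x, a, b):
        """Exposure rescaling (positive affine map) leaves the output unchanged."""
        assert np.array_equal(to_uint8_minmax(x), to_uint8_minmax(a * x + b))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(arrays(np.uint16, (8, 8), elements=st.integers(0, 65535)))
    def test_range_and_endpoints(self, x):
        out = to_uint8_minmax(x)
        assert out.dtype == np.uint8
        if x.min() != x.max():
            assert out.min() == 0 and out.max() == 255


class TestOtsu:
    def test_bimodal_separates_modes(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:, 5:] = 200
        img[:, :5] = 10
        t = otsu_threshold(img)
        assert 10 <= t < 200
        assert t == brute_force_otsu(img)

    def test_binary_image_foreground(self):
        img = np.zeros((8, 8), dtype=np.uint8)
        img[2:4, 2:4] = 255
        t = otsu_threshold(img)
        assert np.array_equal(img > t, img == 255)

    def test_oracle_equivalence_random_images(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            img = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
            assert otsu_threshold(img) == brute_force_otsu(img)

    def test_constant_image_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            otsu_threshold(np.full((4, 4), 7, dtype=np.uint8))


class TestSegmentNuclei:
    def test_two_disjoint_ellipses(self):
        img = np.zeros((100, 120), dtype=np.uint8)
        rr, cc = np.mgrid[0:100, 0:120]
        img[((rr - 30) / 12) ** 2 + ((cc - 30) / 15) ** 2 <= 1] = 200
        img[((rr - 70) / 10) ** 2 + ((cc - 90) / 8) ** 2 <= 1] = 200
        regions = segment_nuclei(img)
        assert len(regions) == 2
        boxes = sorted(r.bbox for r in regions)
        assert boxes[0] == (18, 15, 43, 46)  # ellipse 1: rows 30+-12, cols 30+-15
        assert boxes[1] == (60, 82, 81, 99)

    def test_all_background_empty_list(self):
        assert segment_nuclei(np.zeros((32, 32), dtype=bool)) == []

    def test_matches_generator_ground_truth(self, small_field_dataset):
        from mscstage.segment import segment_field

        fields, truth = small_field_dataset
        for fimg in fields:
            gt = [r for fid, r in truth if fid == fimg.field_id]
            regions = segment_field(fimg)
            assert len(regions) == len(gt)
            cents = np.array([r.centroid for r in regions])
            for rec in gt:
                d = np.min(np.linalg.norm(cents - np.array(rec.center), axis=1))
                assert d < 2.0

    def test_border_regions_flagged(self):
        img = np.zeros((50, 50), dtype=bool)
        img[0:10, 20:30] = True
        img[20:30, 20:30] = True
        regions = segment_nuclei(img)
        flags = sorted(r.touches_border for r in regions)
        assert flags == [False, True]


def _region(h, w, label=1):
    return NucleusRegion(label=label, bbox=(0, 0, h, w), area_px=h * w, centroid=(h / 2, w / 2))


class TestSizeFilter:
    @pytest.mark.parametrize(
        "h,w,kept",
        [
            (60, 80, True),
            (101, 60, False),
            (49, 60, False),
            (50, 50, True),
            (100, 100, True),
            (60, 101, False),
        ],
    )
    def test_boundary_semantics(self, h, w, kept):
        assert bool(size_filter([_region(h, w)])) is kept

    def test_idempotent_and_order_preserving(self):
        regions = [_region(60, 60, 1), _region(10, 10, 2), _region(99, 55, 3), _region(150, 60, 4)]
        once = size_filter(regions)
        assert size_filter(once) == once
        assert [r.label for r in once] == [1, 3]


class TestMaxFrameSize:
    def test_elementwise_max(self):
        assert max_frame_size([_region(60, 80), _region(90, 55)]) == (90, 80)

    def test_single_region(self):
        assert max_frame_size([_region(70, 70)]) == (70, 70)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            max_frame_size([])

    def test_matches_ground_truth_over_fields(self, small_field_dataset):
        from mscstage.segment import segment_field

        fields, _ = small_field_dataset
        regions = [r for f in fields for r in segment_field(f)]
        h, w = max_frame_size(regions)
        assert h == max(r.height for r in regions)
        assert w == max(r.width for r in regions)


class TestCropFrames:
    def _field(self):
        rng = np.random.default_rng(3)
        return FieldImage(
            field_id="f",
            timepoint_h=0.0,
            channels={
                "nucleus": rng.integers(0, 255, (100, 100)).astype(np.uint8),
                "actin": rng.integers(0, 255, (100, 100)).astype(np.uint8),
            },
            bit_depth=8,
        )

    def test_center_region_equals_direct_slice(self):
        f = self._field()
        reg = NucleusRegion(1, (40, 40, 60, 60), 400, (50.0, 50.0))
        (crop,) = crop_frames(f, [reg], (20, 20))
        assert np.array_equal(crop.channels["nucleus"], f.channels["nucleus"][40:60, 40:60])

    def test_corner_padding_zero_count(self):
        f = self._field()
        reg = NucleusRegion(1, (0, 0, 10, 10), 100, (2.0, 2.0))
        # ensure padding is distinguishable from real pixels
        f.channels["nucleus"] = np.clip(f.channels["nucleus"], 1, 255)
        (crop,) = crop_frames(f, [reg], (30, 30), channels=["nucleus"])
        img = crop.channels["nucleus"]
        # frame rows [-13, 17), cols [-13, 17): analytic out-of-field area
        assert np.count_nonzero(img == 0) == 30 * 30 - 17 * 17
        assert np.all(img[:13, :] == 0) and np.all(img[:, :13] == 0)
        assert np.array_equal(img[13:, 13:], f.channels["nucleus"][:17, :17])

    def test_channel_subset(self):
        f = self._field()
        reg = NucleusRegion(1, (40, 40, 60, 60), 400, (50.0, 50.0))
        (crop,) = crop_frames(f, [reg], (20, 20))
        assert set(crop.channels) == {"nucleus", "actin"}
        assert all(ch.shape == (20, 20) for ch in crop.channels.values())

    def test_frame_smaller_than_bbox_raises(self):
        f = self._field()
        reg = NucleusRegion(1, (10, 10, 60, 60), 2500, (35.0, 35.0))
        with pytest.raises(ValueError, match="smaller than bbox"):
            crop_frames(f, [reg], (40, 40))


class TestPipelineRecall:
    def test_each_inrange_nucleus_yields_one_crop(self, small_field_dataset):
        from mscstage.segment import segment_dataset

        fields, truth = small_field_dataset
        crops = segment_dataset(fields)
        gt_by_field = {}
        for fid, rec in truth:
            gt_by_field.setdefault(fid, []).append(rec)
        n_gt = sum(len(v) for v in gt_by_field.values())
        matched = 0
        for fid, recs in gt_by_field.items():
            fcrops = [c for c in crops if c.field_id == fid]
            for rec in recs:
                hits = [
                    c
                    for c in fcrops
                    if abs(c.centroid[0] - rec.center[0]) < 3 and abs(c.centroid[1] - rec.center[1]) < 3
                ]
                if len(hits) == 1:
                    matched += 1
        assert matched / n_gt >= 0.95
        # every crop contains a ground-truth nucleus within its frame
        for c in crops:
            recs = gt_by_field[c.field_id]
            fh, fw = c.frame_size
            assert any(
                abs(c.centroid[0] - r.center[0]) <= fh / 2 and abs(c.centroid[1] - r.center[1]) <= fw / 2
                for r in recs
            )
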
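"""Flask-bottom image pipeline: channels, segmentation, calibration, summary."""

import numpy as np
import pandas as pd
import pytest

from budscale import (
    FlaskImage,
    MaterialSegmenter,
    SegmentationResult,
    batch_size_measure,
    calibrate_pixels,
    extract_blue_channel,
    representative_size,
    segment_material,
)
from budscale.synthetic import FlaskImageConfig, gen_flask_image


def make_seg_result(areas_px, object_class="bundled"):
    """SegmentationResult with a synthetic table (label mask unused by summary)."""
    table = pd.DataFrame(
        {
            "label": np.arange(1, len(areas_px) + 1),
            "object_class": [object_class] * len(areas_px),
            "area_px": list(areas_px),
        }
    )
    return SegmentationResult(np.zeros((16, 16), dtype=int), table)


class TestChannelExtraction:
    def test_pure_colours(self):
        blue_img = np.zeros((20, 20, 3), dtype=np.uint8)
        blue_img[..., 2] = 255
        assert (extract_blue_channel(blue_img) == 255).all()
        red_img = np.zeros((20, 20, 3), dtype=np.uint8)
        red_img[..., 0] = 255
        assert (extract_blue_channel(red_img) == 0).all()

    def test_per_channel_ramps_recovered(self):
        h, w = 24, 32
        img = np.zeros((h, w, 3))
        img[..., 0] = np.linspace(0, 1, w)
        img[..., 2] = np.linspace(5, 9, w)
        np.testing.assert_array_equal(extract_blue_channel(img), img[..., 2])

    def test_single_channel_passthrough_warns(self):
        mono = np.ones((20, 20))
        with pytest.warns(UserWarning):
            out = extract_blue_channel(mono)
        assert out is mono


class TestSegmentation:
    def test_blank_image_zero_objects(self):
        seg = segment_material(np.zeros((64, 64)))
        assert len(seg.object_table) == 0
        assert seg.label_mask.max() == 0

    def test_single_disk_area_close_to_analytic(self):
        h = w = 128
        rr, cc = np.ogrid[:h, :w]
        disk = (rr - 64) ** 2 + (cc - 64) ** 2 <= 20**2
        img = np.where(disk, 200.0, 0.0)
        seg = segment_material(img)
        assert len(seg.object_table) == 1
        row = seg.object_table.iloc[0]
        assert row["object_class"] == "bundled"
        assert row["area_px"] == disk.sum()
        assert abs(row["area_px"] - np.pi * 400) / (np.pi * 400) < 0.02

    def test_planted_counts_and_exact_areas(self):
        image, truth = gen_flask_image(seed=11)
        seg = segment_material(extract_blue_channel(image))
        found = seg.object_table["object_class"].value_counts()
        assert found["bundled"] == 5 and found["scattered"] == 50
        assert sorted(seg.object_table["area_px"]) == sorted(truth["area_px"])

    def test_area_conservation(self):
        image, _ = gen_flask_image(seed=2)
        seg = segment_material(extract_blue_channel(image), min_object_px=10)
        h, w = seg.label_mask.shape
        background = int((seg.label_mask == 0).sum())
        assert seg.object_table["area_px"].sum() + background == h * w
        # discarded noise pixels are background in the mask but tracked separately
        assert seg.discarded_px > 0  # radius-1 specks fall below 10 px

    def test_rotation_invariance(self):
        image, _ = gen_flask_image(seed=7)
        blue = extract_blue_channel(image)
        a = segment_material(blue).object_table["area_px"]
        b = segment_material(np.rot90(blue)).object_table["area_px"]
        assert sorted(a) == sorted(b)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            segment_material(np.zeros((32, 32)), threshold="magic")
        with pytest.raises(ValueError):
            segment_material(np.zeros((32, 32)), sigma=-1.0)


class TestCalibration:
    def test_scale_arithmetic(self):
        img = FlaskImage(np.zeros((600, 600, 3), dtype=np.uint8), 8.5, (300, 300, 250))
        scale = calibrate_pixels(img)
        assert scale == pytest.approx(0.017)
        assert 1000 * scale**2 == pytest.approx(0.289)

    def test_identity_and_scaling_law(self):
        img1 = FlaskImage(np.zeros((100, 100, 3), dtype=np.uint8), 10.0, (50, 50, 5.0))
        img2 = FlaskImage(np.zeros((100, 100, 3), dtype=np.uint8), 10.0, (50, 50, 10.0))
        assert calibrate_pixels(img1) == 1.0  # radius = diameter/2 in px => scale 1
        assert calibrate_pixels(img2) == 0.5  # doubling the radius halves the scale

    def test_missing_calibration_raises(self):
        img = FlaskImage(np.zeros((100, 100, 3), dtype=np.uint8), 8.5)
        with pytest.raises(ValueError, match="calibrat"):
            calibrate_pixels(img)
        assert calibrate_pixels(img, explicit_scale_cm_per_px=0.02) == 0.02


class TestRepresentativeSize:
    def test_percentile_oracle_1_to_100(self):
        """Areas 1..100: the 95th percentile (linear interpolation) is 95.05
        and the mean of the qualifying set {96..100} is 98, matching an
        exhaustive sort-based computation."""
        seg = make_seg_result(range(1, 101))
        summary = representative_size(seg, pixel_scale_cm_per_px=1.0)
        assert summary.percentile_threshold_cm2 == pytest.approx(95.05)
        assert summary.representative_size_cm2 == pytest.approx(98.0)
        # sort-based oracle
        areas = np.sort(np.arange(1.0, 101.0))
        rank = 0.95 * (len(areas) - 1)
        lo, frac = int(rank), rank - int(rank)
        thr = areas[lo] * (1 - frac) + areas[lo + 1] * frac
        assert summary.percentile_threshold_cm2 == pytest.approx(thr)
        assert summary.representative_size_cm2 == pytest.approx(areas[areas >= thr].mean())

    def test_singleton_and_constant(self):
        seg = make_seg_result([200])
        s = representative_size(seg, pixel_scale_cm_per_px=0.1)
        assert s.representative_size_cm2 == pytest.approx(2.0)
        seg = make_seg_result([50] * 7)
        s = representative_size(seg, pixel_scale_cm_per_px=1.0)
        assert s.representative_size_cm2 == pytest.approx(50.0)

    def test_scattered_objects_excluded(self):
        seg = make_seg_result([10, 20, 30], object_class="scattered")
        s = representative_size(seg, pixel_scale_cm_per_px=1.0)
        assert s.empty and s.representative_size_cm2 == 0.0 and s.n_bundled_objects == 0

    def test_threshold_never_exceeds_summary(self):
        rng = np.random.default_rng(3)
        seg = make_seg_result(rng.integers(100, 5000, size=40))
        s = representative_size(seg, pixel_scale_cm_per_px=0.02)
        assert s.representative_size_cm2 >= s.percentile_threshold_cm2 > 0


class TestBatch:
    def test_identical_images_identical_rows(self):
        image, _ = gen_flask_image(seed=5)
        per_image, per_group = batch_size_measure([image] * 3, groups=["a", "a", "a"])
        sizes = per_image["representative_size_cm2"]
        assert sizes.nunique() == 1
        assert per_group.loc[0, "mean_size_cm2"] == pytest.approx(sizes.iloc[0])

    def test_group_means_track_planted_sizes(self):
        big, _ = gen_flask_image(FlaskImageConfig(bundled_radius_px=(28.0, 34.0)), seed=1)
        small, _ = gen_flask_image(FlaskImageConfig(bundled_radius_px=(12.0, 16.0)), seed=1)
        per_image, per_group = batch_size_measure([big, small], groups=["big", "small"])
        means = per_group.set_index("group")["mean_size_cm2"]
        assert means["big"] > means["small"]

    def test_failures_recorded_batch_continues(self):
        good, _ = gen_flask_image(seed=9)
        bad = FlaskImage(good.pixels, good.flask_inner_diameter_cm)  # no circle -> calibration error
        per_image, _ = batch_size_measure([bad, good], groups=["g", "g"])
        assert per_image.loc[0, "error"] != ""
        assert per_image.loc[1, "error"] == ""
        assert np.isfinite(per_image.loc[1, "representative_size_cm2"])
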
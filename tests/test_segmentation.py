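"""Segmentation against generator ground truth and hand-built images."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import httscreen as hs
from httscreen.errors import ConfigurationError
from httscreen.segmentation import SQRT2, ThresholdMethod

PS = hs.DEFAULT_PIXEL_SIZE_UM


def make_image(px, channel=hs.Channel.MORPHOLOGY):
    return hs.FieldImage(well_id="A01", site_index=1, channel=channel,
                         pixels=px)


def field_with_blob_and_line(n_steps=100, blob_r=8):
    """One soma disc plus one straight 2 px-wide horizontal neurite of
    ``n_steps`` unit steps; returns (image, planted arc length in µm)."""
    img = np.full((256, 256), 200, dtype=np.uint16)
    yy, xx = np.mgrid[0:256, 0:256]
    img[(yy - 40) ** 2 + (xx - 40) ** 2 <= blob_r ** 2] = 6000
    mask = np.zeros((256, 256), bool)
    y, x = 128, 30
    for _ in range(n_steps):
        x += 1
        mask[y, x] = True
    from scipy import ndimage
    mask = ndimage.binary_dilation(mask, np.ones((2, 2), bool))
    img[mask] = 4000
    return make_image(img), n_steps * PS


class TestMorphologySegmentation:
    def test_blank_image_empty_result(self, seg_config):
        seg = hs.segment_morphology(make_image(
            np.zeros((128, 128), dtype=np.uint16)), seg_config)
        assert seg.neuromere_count == 0
        assert seg.neurite_segment_lengths_um == []
        assert hs.neuronal_mask_sizes(seg) == (0, 0)

    def test_noise_only_image_empty_result(self, seg_config):
        rng = np.random.default_rng(0)
        px = (200 + rng.normal(0, 50, (128, 128))).clip(0, 65535) \
            .astype(np.uint16)
        seg = hs.segment_morphology(make_image(px), seg_config)
        assert seg.neuromere_count == 0

    def test_wrong_channel_rejected(self, seg_config):
        img = make_image(np.zeros((16, 16), dtype=np.uint16),
                         hs.Channel.REPORTER)
        with pytest.raises(Exception, match="MORPHOLOGY"):
            hs.segment_morphology(img, seg_config)

    def test_planted_blob_areas_recovered(self, seg_config,
                                          noiseless_control_params):
        """Blob-only noiseless fields: every planted neuromere found and
        each area within 5% of the rendered truth."""
        params = dataclasses.replace(noiseless_control_params,
                                     neurites_per_neuromere=0.0)
        checked = 0
        for seed in range(8):
            _ignored, _, truth = (None, None, None)
            morph, _, truth = hs.generate_culture_field(params, seed=seed)
            seg = hs.segment_morphology(morph, seg_config)
            assert seg.neuromere_count == truth.neuromere_count
            for found, planted in zip(sorted(seg.neuromere_areas_um2),
                                      sorted(truth.neuromere_areas_um2)):
                assert found == pytest.approx(planted, rel=0.05)
                checked += 1
        assert checked >= 4

    def test_straight_neurite_length(self, seg_config):
        img, planted = field_with_blob_and_line()
        seg = hs.segment_morphology(img, seg_config)
        assert len(seg.neurite_segment_lengths_um) == 1
        assert abs(seg.neurite_segment_lengths_um[0] - planted) <= 3 * PS

    def test_outputs_sorted_descending(self, seg_config):
        morph, _, _ = hs.generate_culture_field(hs.control_params(), seed=1)
        seg = hs.segment_morphology(morph, seg_config)
        assert seg.neuromere_areas_um2 == \
            sorted(seg.neuromere_areas_um2, reverse=True)
        assert seg.neurite_segment_lengths_um == \
            sorted(seg.neurite_segment_lengths_um, reverse=True)

    def test_masks_disjoint(self, seg_config):
        morph, _, _ = hs.generate_culture_field(hs.control_params(), seed=2)
        seg = hs.segment_morphology(morph, seg_config, keep_masks=True)
        assert not (seg.neuromere_mask & seg.neurite_mask).any()
        assert seg.neuromere_mask.sum() == seg.neuromere_pixel_mask_size
        assert seg.neurite_mask.sum() == seg.neurite_pixel_mask_size

    def test_scaling_invariance_under_otsu(self, seg_config,
                                           noiseless_control_params):
        morph, _, _ = hs.generate_culture_field(noiseless_control_params,
                                                seed=5)
        seg1 = hs.segment_morphology(morph, seg_config)
        scaled = make_image((morph.pixels.astype(np.uint32) * 4)
                            .astype(np.uint16))
        assert seg_config.morph_threshold_method is ThresholdMethod.OTSU
        seg2 = hs.segment_morphology(scaled, seg_config)
        assert seg1.neuromere_areas_um2 == seg2.neuromere_areas_um2
        assert seg1.neurite_segment_lengths_um == \
            seg2.neurite_segment_lengths_um

    def test_mask_sizes_track_truth(self, seg_config,
                                    noiseless_control_params):
        morph, _, truth = hs.generate_culture_field(noiseless_control_params,
                                                    seed=3)
        seg = hs.segment_morphology(morph, seg_config)
        truth_soma_px = sum(truth.neuromere_areas_um2) / PS ** 2
        assert seg.neuromere_pixel_mask_size == \
            pytest.approx(truth_soma_px, rel=0.10)


class TestAggregateCounting:
    def test_zero_image(self):
        cfg = hs.SegmentationConfig(aggregate_threshold=10)
        img = make_image(np.zeros((8, 8), dtype=np.uint16),
                         hs.Channel.REPORTER)
        assert hs.count_aggregate_pixels(img, cfg) == 0

    def test_constant_above_threshold(self):
        cfg = hs.SegmentationConfig(aggregate_threshold=10)
        img = make_image(np.full((4, 4), 11, dtype=np.uint16),
                         hs.Channel.REPORTER)
        assert hs.count_aggregate_pixels(img, cfg) == 16

    def test_strictly_greater(self):
        cfg = hs.SegmentationConfig(aggregate_threshold=50)
        img = make_image(np.full((4, 4), 50, dtype=np.uint16),
                         hs.Channel.REPORTER)
        assert hs.count_aggregate_pixels(img, cfg) == 0

    def test_saturated_pixels_always_count(self):
        cfg = hs.SegmentationConfig(aggregate_threshold=65535)
        px = np.zeros((4, 4), dtype=np.uint16)
        px[0, :2] = 65535
        img = make_image(px, hs.Channel.REPORTER)
        assert hs.count_aggregate_pixels(img, cfg) == 2

    def test_unset_threshold_rejected(self):
        cfg = hs.SegmentationConfig()
        img = make_image(np.zeros((4, 4), dtype=np.uint16),
                         hs.Channel.REPORTER)
        with pytest.raises(ConfigurationError):
            hs.count_aggregate_pixels(img, cfg)

    def test_noiseless_count_matches_planted_mask(self,
                                                  noiseless_control_params):
        params = dataclasses.replace(noiseless_control_params,
                                     aggregate_rate=10.0,
                                     soluble_reporter_level=800.0)
        _, rep, truth = hs.generate_culture_field(params, seed=6)
        # brute-force oracle: any threshold between soluble and aggregate
        # intensity bands recovers exactly the planted aggregate pixels
        cfg = hs.SegmentationConfig(aggregate_threshold=2000.0)
        brute = int(np.count_nonzero(rep.pixels > 2000.0))
        count = hs.count_aggregate_pixels(rep, cfg)
        assert count == brute == truth.aggregate_pixel_count

    @given(thr=st.integers(0, 120), shift=st.integers(1, 50))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_threshold(self, thr, shift):
        rng = np.random.default_rng(123)
        px = rng.integers(0, 128, (16, 16)).astype(np.uint16)
        img = make_image(px, hs.Channel.REPORTER)
        lo = hs.SegmentationConfig(aggregate_threshold=thr)
        hi = hs.SegmentationConfig(aggregate_threshold=thr + shift)
        assert hs.count_aggregate_pixels(img, lo) >= \
            hs.count_aggregate_pixels(img, hi)


class TestThresholdCalibration:
    def test_constant_reference(self):
        img = make_image(np.full((16, 16), 50, dtype=np.uint16),
                         hs.Channel.REPORTER)
        thr = hs.calibrate_aggregate_threshold([img], q=0.999)
        assert thr == 50.0
        cfg = hs.SegmentationConfig(aggregate_threshold=thr)
        assert hs.count_aggregate_pixels(img, cfg) == 0

    def test_quantile_matches_brute_force(self):
        rng = np.random.default_rng(11)
        px = rng.integers(0, 100, (40, 40)).astype(np.uint16)
        img = make_image(px, hs.Channel.REPORTER)
        thr = hs.calibrate_aggregate_threshold([img], q=0.999)
        assert thr == pytest.approx(np.quantile(px.ravel(), 0.999))
        assert thr > 97

    def test_empty_reference_rejected(self):
        with pytest.raises(ConfigurationError):
            hs.calibrate_aggregate_threshold([])

    def test_calibrated_threshold_separates_genotypes(self):
        """Threshold fitted on control reporter fields yields far higher
        aggregate counts on mutant fields (20 fields per genotype)."""
        ctrl_imgs = [hs.generate_culture_field(hs.control_params(), s)[1]
                     for s in range(20)]
        mut_imgs = [hs.generate_culture_field(hs.mutant_params(), 500 + s)[1]
                    for s in range(20)]
        thr = hs.calibrate_aggregate_threshold(ctrl_imgs)
        cfg = hs.SegmentationConfig(aggregate_threshold=thr)
        ctrl_counts = [hs.count_aggregate_pixels(i, cfg) for i in ctrl_imgs]
        mut_counts = [hs.count_aggregate_pixels(i, cfg) for i in mut_imgs]
        # controls keep only the ~0.1% quantile leftover by construction
        assert np.mean(ctrl_counts) < 0.002 * ctrl_imgs[0].pixels.size
        assert np.mean(mut_counts) > 3 * np.mean(ctrl_counts)


def test_diagonal_length_metric():
    """Segment lengths count diagonal skeleton steps as sqrt(2) pixels."""
    img = np.full((64, 64), 0, dtype=np.uint16)
    mask = np.zeros((64, 64), bool)
    for i in range(30):
        mask[10 + i, 10 + i] = True
    from scipy import ndimage
    mask = ndimage.binary_dilation(mask, np.ones((2, 2), bool))
    img[mask] = 4000
    cfg = hs.SegmentationConfig(morph_threshold_method=ThresholdMethod.FIXED,
                                fixed_threshold=1000,
                                min_neuromere_area_px=10_000)
    seg = hs.segment_morphology(make_image(img), cfg)
    assert len(seg.neurite_segment_lengths_um) == 1
    expected = 29 * SQRT2 * PS
    assert seg.neurite_segment_lengths_um[0] == \
        pytest.approx(expected, rel=0.10)
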
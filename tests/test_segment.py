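"""Dual-sensitivity segmentation: oracle recovery, invariants, degenerate inputs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spheroquant.phantoms import SpheroidPhantomSpec, make_spheroid_images
from spheroquant.segment import (
    SegmentationParams,
    area_to_um2,
    binarize_adaptive,
    segment_spheroid,
)


class TestBinarizeAdaptive:
    def test_constant_image_yields_empty_mask(self):
        mask = binarize_adaptive(np.full((64, 64), 130.0), 9, 0.2)
        assert not mask.any()

    def test_sensitivity_masks_are_nested(self, halo_phantom):
        _, image, _ = halo_phantom
        loose = binarize_adaptive(image["brightfield"], 129, 0.15)
        strict = binarize_adaptive(image["brightfield"], 129, 0.40)
        assert np.all(loose[strict])  # stricter mask contained in looser one

    def test_disk_mask_area_close_to_truth(self, disk_phantom):
        spec, image, truth = disk_phantom
        mask = binarize_adaptive(image["brightfield"], 129, 0.35)
        from scipy.ndimage import binary_fill_holes

        area = binary_fill_holes(mask).sum() * spec.pixel_size_um**2
        assert abs(area - truth.total_area_um2) / truth.total_area_um2 < 0.02

    def test_light_foreground_polarity(self):
        spec = SpheroidPhantomSpec(core_radius_um=150, noise_sd=0.0,
                                   polarity="light_foreground", seed=2)
        image, truth = make_spheroid_images(spec)
        res = segment_spheroid(image["brightfield"],
                               SegmentationParams(polarity="light_foreground"),
                               spec.pixel_size_um)
        err = abs(res.core_area_um2 - truth.core_area_um2) / truth.core_area_um2
        assert err < 0.02

    @pytest.mark.parametrize("window", [2, 4, 1, -3])
    def test_non_odd_window_rejected(self, window):
        with pytest.raises(ValueError):
            binarize_adaptive(np.zeros((8, 8)), window, 0.2)

    def test_empty_or_nonfinite_image_rejected(self):
        with pytest.raises(ValueError):
            binarize_adaptive(np.zeros((0, 0)), 3, 0.2)
        with pytest.raises(ValueError):
            binarize_adaptive(np.full((8, 8), np.nan), 3, 0.2)


class TestSegmentSpheroid:
    def test_no_halo_gives_coincident_areas(self, disk_phantom):
        spec, image, truth = disk_phantom
        res = segment_spheroid(image["brightfield"], pixel_size_um=spec.pixel_size_um)
        assert res.detected
        assert res.halo_area_um2 < 0.01 * res.core_area_um2
        assert abs(res.core_area_um2 - truth.core_area_um2) / truth.core_area_um2 < 0.02

    def test_halo_detected_and_core_accurate(self, halo_phantom):
        spec, image, truth = halo_phantom
        res = segment_spheroid(image["brightfield"], pixel_size_um=spec.pixel_size_um)
        assert res.total_area_um2 > res.core_area_um2
        assert abs(res.core_area_um2 - truth.core_area_um2) / truth.core_area_um2 < 0.05

    def test_core_contained_in_total(self, halo_phantom):
        spec, image, _ = halo_phantom
        res = segment_spheroid(image["brightfield"], pixel_size_um=spec.pixel_size_um)
        assert np.all(res.total_mask[res.core_mask])
        assert res.halo_area_um2 == pytest.approx(res.total_area_um2 - res.core_area_um2)

    def test_blank_noise_image_is_no_spheroid_outcome(self, rng):
        noise = rng.normal(200, 2, (512, 512))
        res = segment_spheroid(noise, pixel_size_um=2.0)
        assert not res.detected
        assert res.core_area_um2 == 0.0 and not res.core_mask.any()

    def test_idempotent_on_rendered_truth_mask(self, disk_phantom):
        spec, _, truth = disk_phantom
        rendered = 200.0 - 140.0 * truth.core_mask
        res = segment_spheroid(rendered, pixel_size_um=spec.pixel_size_um)
        sym_diff = np.logical_xor(res.core_mask, truth.core_mask).sum()
        assert sym_diff <= 0.01 * truth.core_mask.sum()

    def test_area_scale_consistency_under_resampling(self):
        coarse = SpheroidPhantomSpec(core_radius_um=200, noise_sd=0.0,
                                     pixel_size_um=2.0, shape=(512, 512), seed=1)
        fine = SpheroidPhantomSpec(core_radius_um=200, noise_sd=0.0,
                                   pixel_size_um=1.0, shape=(1024, 1024), seed=1)
        areas = []
        for spec in (coarse, fine):
            image, _ = make_spheroid_images(spec)
            res = segment_spheroid(image["brightfield"], pixel_size_um=spec.pixel_size_um)
            areas.append(res.core_area_um2)
        assert abs(areas[0] - areas[1]) / areas[1] < 0.02

    def test_total_sensitivity_must_be_permissive(self):
        with pytest.raises(ValueError):
            SegmentationParams(sensitivity_core=0.2, sensitivity_total=0.4)


class TestAreaConversion:
    def test_arithmetic(self):
        assert area_to_um2(10_000, 2.0) == 40_000.0
        assert area_to_um2(0, 3.5) == 0.0

    @given(count=st.integers(0, 10_000), px=st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_equals_per_pixel_summation(self, count, px):
        per_pixel = np.full(count, px * px).sum() if count else 0.0
        assert area_to_um2(count, px) == pytest.approx(per_pixel)

    def test_nonpositive_pixel_size_rejected(self):
        with pytest.raises(ValueError):
            area_to_um2(10, 0.0)
        with pytest.raises(ValueError):
            area_to_um2(-1, 1.0)
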
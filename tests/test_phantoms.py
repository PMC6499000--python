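"""Generator contracts: ground truth consistent with the generated pixels."""

import numpy as np
import pytest

from spheroquant.phantoms import (
    DnaHistogramSpec,
    GelPhantomSpec,
    SpheroidPhantomSpec,
    make_dna_events,
    make_gel_image,
    make_redox_pair,
    make_spheroid_images,
)


class TestSpheroidPhantom:
    def test_disk_area_matches_geometry(self, disk_phantom):
        spec, _, truth = disk_phantom
        expected = np.pi * spec.core_radius_um**2
        assert abs(truth.total_area_um2 - expected) / expected < 0.02  # pixelation only

    def test_no_halo_means_masks_coincide(self, disk_phantom):
        _, _, truth = disk_phantom
        assert np.array_equal(truth.core_mask, truth.total_mask)

    def test_zero_necrosis_gives_background_pi(self):
        spec = SpheroidPhantomSpec(core_radius_um=150, necrotic_fraction=0.0, noise_sd=0.0)
        image, truth = make_spheroid_images(spec)
        inside = image["pi"][truth.total_mask]
        assert np.allclose(inside, truth.per_channel_truth["pi_background"])

    def test_pi_mean_linear_in_necrotic_fraction(self):
        for nf in (0.2, 0.7):
            spec = SpheroidPhantomSpec(core_radius_um=150, necrotic_fraction=nf, noise_sd=0.0)
            image, truth = make_spheroid_images(spec)
            assert np.isclose(image["pi"][truth.core_mask].mean(),
                              truth.per_channel_truth["pi_mean_in_mask"])

    def test_core_contrast_against_outside(self, disk_phantom):
        _, image, truth = disk_phantom
        bf = image["brightfield"]
        contrast = bf[~truth.total_mask].mean() - bf[truth.core_mask].mean()
        assert contrast >= truth.per_channel_truth["brightfield_contrast"] - 1e-6

    def test_seeded_rerun_is_bit_identical(self):
        spec = SpheroidPhantomSpec(core_radius_um=180, halo_cell_count=50, seed=3)
        a, _ = make_spheroid_images(spec)
        b, _ = make_spheroid_images(spec)
        for name in a.channels:
            assert np.array_equal(a[name], b[name])

    def test_halo_mask_within_total_and_disjoint_from_core(self, halo_phantom):
        _, _, truth = halo_phantom
        assert np.all(truth.total_mask[truth.core_mask])
        assert truth.total_area_um2 > truth.core_area_um2

    @pytest.mark.parametrize(
        "kwargs",
        [dict(core_radius_um=-5), dict(core_radius_um=100, pixel_size_um=0),
         dict(core_radius_um=100, necrotic_fraction=1.5),
         dict(core_radius_um=100, halo_radius_um=50),
         dict(core_radius_um=100, noise_sd=-1)],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SpheroidPhantomSpec(**kwargs)


class TestRedoxPair:
    def test_symmetric_field_gives_equal_channels(self):
        nadh, fad, _ = make_redox_pair(np.full((32, 32), 0.5), noise_sd=0.0)
        assert np.array_equal(nadh, fad)

    def test_zero_field_gives_zero_fad(self):
        _, fad, _ = make_redox_pair(np.zeros((16, 16)), noise_sd=0.0)
        assert np.all(fad == 0)

    def test_direct_division_recovers_truth_exactly(self, rng):
        field = rng.uniform(0.01, 0.99, size=(64, 64))
        nadh, fad, truth = make_redox_pair(field, intensity_scale=256.0, noise_sd=0.0)
        assert np.array_equal(fad / (fad + nadh), truth)

    def test_out_of_range_field_rejected(self):
        with pytest.raises(ValueError):
            make_redox_pair(np.array([[0.5, 1.2]]))


class TestDnaEvents:
    def test_degenerate_mixture_all_at_g1(self):
        spec = DnaHistogramSpec(n_events=100, fractions=(0, 1, 0, 0), cv_g1=0.0)
        events, labels = make_dna_events(spec)
        assert np.allclose(events, spec.g1_mean)
        assert np.all(labels == 1)

    def test_label_fractions_within_binomial_bounds(self):
        fr = (0.24, 0.46, 0.15, 0.15)
        spec = DnaHistogramSpec(n_events=5000, fractions=fr, seed=42)
        _, labels = make_dna_events(spec)
        emp = np.bincount(labels, minlength=4) / 5000
        for p, p_hat in zip(fr, emp):
            half = 2.576 * np.sqrt(p * (1 - p) / 5000)  # 99% binomial bound
            assert abs(p_hat - p) <= half

    def test_same_seed_reproduces_events(self):
        spec = DnaHistogramSpec(n_events=1000, fractions=(0.2, 0.4, 0.2, 0.2), seed=5)
        a, la = make_dna_events(spec)
        b, lb = make_dna_events(spec)
        assert np.array_equal(a, b) and np.array_equal(la, lb)

    def test_phase_supports(self):
        spec = DnaHistogramSpec(n_events=5000, fractions=(0.3, 0.3, 0.2, 0.2), seed=1)
        events, labels = make_dna_events(spec)
        sigma = spec.cv_g1 * spec.g1_mean
        assert events[labels == 0].max() < spec.g1_mean - 3 * sigma  # separable sub-G1
        s_events = events[labels == 2]
        assert s_events.min() >= spec.g1_mean and s_events.max() <= 2 * spec.g1_mean

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            DnaHistogramSpec(n_events=100, fractions=(0.5, 0.4, 0.2, 0.0))


class TestGelPhantom:
    def test_band_pixels_at_designed_level(self):
        spec = GelPhantomSpec(lanes=(("NT", {"PCNA": 145.0, "beta_actin": 100.0}),),
                              background_level=200)
        img, truth, rois = make_gel_image(spec)
        r = next(r for r in rois if r["protein"] == "PCNA")
        r0, r1, c0, c1 = r["rect"]
        assert np.all(img[r0:r1, c0:c1] == 55)  # 200 - 145
        assert truth["NT"]["PCNA"] == 145.0

    def test_zero_contrast_band_blends_into_background(self):
        spec = GelPhantomSpec(lanes=(("NT", {"PCNA": 0.0}),), background_level=180)
        img, _, rois = make_gel_image(spec)
        r0, r1, c0, c1 = rois[0]["rect"]
        assert np.all(img[r0:r1, c0:c1] == 180)

    def test_out_of_range_band_rejected(self):
        with pytest.raises(ValueError):
            GelPhantomSpec(lanes=(("NT", {"PCNA": 250.0}),), background_level=200)

    def test_seeded_noise_is_reproducible(self):
        spec = GelPhantomSpec(lanes=(("NT", {"PCNA": 100.0}),), noise_sd=3.0, seed=9)
        a, _, _ = make_gel_image(spec)
        b, _, _ = make_gel_image(spec)
        assert np.array_equal(a, b)
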
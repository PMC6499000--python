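"""Inversion densitometry and loading-control/reference normalization."""

import numpy as np
import pytest

from spheroquant.densitometry import (
    BandRoi,
    normalize_expression,
    quantify_band,
)
from spheroquant.phantoms import GelPhantomSpec, make_gel_image


def _gel(lanes, **kwargs):
    spec = GelPhantomSpec(lanes=lanes, **kwargs)
    img, truth, roi_dicts = make_gel_image(spec)
    rois = [BandRoi(r["lane_id"], r["protein"], tuple(r["rect"]), r["placement"])
            for r in roi_dicts]
    return img, truth, rois


class TestQuantifyBand:
    def test_stated_inversion_arithmetic(self):
        img = np.full((60, 40), 200, dtype=np.uint8)
        img[30:40, 10:30] = 55
        q = quantify_band(img, BandRoi("L1", "PCNA", (30, 40, 10, 30)))
        assert q.signal == pytest.approx(145.0)  # (255-55) - (255-200)

    def test_band_equal_to_background_gives_zero(self):
        img = np.full((60, 40), 180, dtype=np.uint8)
        q = quantify_band(img, BandRoi("L1", "PCNA", (30, 40, 10, 30)))
        assert q.signal == 0.0

    def test_band_lighter_than_background_clamped(self):
        img = np.full((60, 40), 100, dtype=np.uint8)
        img[30:40, 10:30] = 150  # lighter than surroundings
        q = quantify_band(img, BandRoi("L1", "PCNA", (30, 40, 10, 30)))
        assert q.signal == 0.0

    def test_phantom_signals_exact_without_noise(self):
        img, truth, rois = _gel((("NT", {"PCNA": 120.0, "beta_actin": 150.0}),))
        for roi in rois:
            q = quantify_band(img, roi)
            assert q.signal == pytest.approx(truth["NT"][roi.protein])

    def test_phantom_signals_close_with_noise(self):
        img, truth, rois = _gel((("NT", {"PCNA": 120.0, "beta_actin": 150.0}),),
                                noise_sd=2.0, seed=4)
        for roi in rois:
            q = quantify_band(img, roi)
            assert q.signal == pytest.approx(truth["NT"][roi.protein], rel=0.02)

    def test_global_offset_cancels(self):
        img, _, rois = _gel((("NT", {"PCNA": 100.0, "beta_actin": 150.0}),))
        shifted = np.clip(img.astype(int) + 20, 0, 255).astype(np.uint8)
        for roi in rois:
            assert quantify_band(shifted, roi).signal == quantify_band(img, roi).signal

    def test_16bit_input_rescaled(self):
        img8 = np.full((60, 40), 200, dtype=np.uint8)
        img8[30:40, 10:30] = 55
        img16 = (img8.astype(np.uint16) * 257)  # exact 8->16 bit expansion
        q = quantify_band(img16, BandRoi("L1", "PCNA", (30, 40, 10, 30)))
        assert q.signal == pytest.approx(145.0)

    def test_out_of_bounds_roi_rejected(self):
        with pytest.raises(ValueError):
            quantify_band(np.zeros((20, 20), np.uint8), BandRoi("L", "P", (10, 30, 0, 5)))

    def test_background_falls_back_below_top_edge(self):
        img = np.full((30, 40), 200, dtype=np.uint8)
        img[0:10, 10:30] = 55  # band flush with the top edge
        q = quantify_band(img, BandRoi("L1", "PCNA", (0, 10, 10, 30), placement="above"))
        assert q.background_mean == pytest.approx(200.0)

    def test_overlapping_background_roi_warns(self):
        img = np.full((60, 40), 200, dtype=np.uint8)
        band = BandRoi("L1", "PCNA", (30, 40, 10, 30))
        other = BandRoi("L1", "gH2AX", (22, 32, 10, 30))
        with pytest.warns(UserWarning, match="overlaps"):
            quantify_band(img, band, other_bands=[band, other])


class TestNormalizeExpression:
    def test_reference_lane_maps_to_one(self):
        img, _, rois = _gel((("NT", {"PCNA": 120.0, "beta_actin": 150.0}),
                             ("RT20", {"PCNA": 60.0, "beta_actin": 150.0})))
        quants = normalize_expression([quantify_band(img, r) for r in rois])
        for q in quants:
            if q.lane_id == "NT":
                assert q.normalized_expression == pytest.approx(1.0)

    def test_doubled_signal_with_equal_loading_gives_two(self):
        img, _, rois = _gel((("NT", {"PCNA": 60.0, "beta_actin": 150.0}),
                             ("PDT", {"PCNA": 120.0, "beta_actin": 150.0})))
        quants = normalize_expression([quantify_band(img, r) for r in rois])
        pdt = next(q for q in quants if q.lane_id == "PDT" and q.protein == "PCNA")
        assert pdt.normalized_expression == pytest.approx(2.0)

    def test_designed_ratios_recovered_with_noise(self):
        lanes = (("NT", {"PCNA": 100.0, "gH2AX": 40.0, "beta_actin": 150.0}),
                 ("PDT", {"PCNA": 90.0, "gH2AX": 70.0, "beta_actin": 140.0}),
                 ("RT20", {"PCNA": 110.0, "gH2AX": 120.0, "beta_actin": 160.0}),
                 ("PDT+RT20", {"PCNA": 60.0, "gH2AX": 130.0, "beta_actin": 150.0}))
        img, truth, rois = _gel(lanes, noise_sd=2.0, seed=8)
        quants = normalize_expression([quantify_band(img, r) for r in rois])
        for q in quants:
            expected = (truth[q.lane_id][q.protein] / truth[q.lane_id]["beta_actin"]) / (
                truth["NT"][q.protein] / truth["NT"]["beta_actin"])
            assert q.normalized_expression == pytest.approx(expected, rel=0.05)

    def test_exposure_rescaling_invariance(self):
        scale = lambda lanes, c: tuple(
            (lab, {p: v * c for p, v in bands.items()}) for lab, bands in lanes)
        lanes = (("NT", {"PCNA": 80.0, "beta_actin": 120.0}),
                 ("RT20", {"PCNA": 40.0, "beta_actin": 120.0}))
        out = []
        for c in (1.0, 1.5):
            img, _, rois = _gel(scale(lanes, c))
            quants = normalize_expression([quantify_band(img, r) for r in rois])
            out.append({(q.lane_id, q.protein): q.normalized_expression for q in quants})
        for key in out[0]:
            assert out[0][key] == pytest.approx(out[1][key], rel=1e-6)

    def test_zero_loading_control_flags_lane(self):
        img, _, rois = _gel((("NT", {"PCNA": 100.0, "beta_actin": 150.0}),
                             ("BAD", {"PCNA": 100.0, "beta_actin": 0.0})))
        quants = normalize_expression([quantify_band(img, r) for r in rois])
        bad = [q for q in quants if q.lane_id == "BAD"]
        assert all(q.flagged and q.normalized_expression is None for q in bad)

    def test_missing_loading_band_rejected(self):
        img, _, rois = _gel((("NT", {"PCNA": 100.0, "beta_actin": 150.0}),))
        with pytest.raises(ValueError, match="reference"):
            normalize_expression([quantify_band(img, r) for r in rois],
                                 reference_condition="PDT")
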
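"""Western-blot band densitometry via fixed-ROI 8-bit inversion.

The readout mirrors a manual ImageJ-style workflow: the mean intensity of a
rectangular band ROI and of an identically sized background ROI placed
directly above (or below) the band are measured on an 8-bit grayscale image;
both are inverted (255 - intensity) and the background-corrected signal is
their difference, clamped at zero.  Expression is then normalized lane-wise
to a loading control and across lanes to the no-treatment condition:

    expr(lane, protein) = [S(lane, protein) / S(lane, loading)]
                        / [S(ref,  protein) / S(ref,  loading)]

so the reference condition maps to 1.0 for every protein by construction.
Automatic lane/band detection is out of scope; ROIs are supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["BandRoi", "BandQuantification", "quantify_band", "normalize_expression"]


@dataclass(frozen=True)
class BandRoi:
    """Band rectangle (half-open, row-major, 0-based) with background placement."""

    lane_id: str
    protein: str
    rect: tuple[int, int, int, int]  # (row0, row1, col0, col1)
    placement: str = "above"

    def __post_init__(self) -> None:
        r0, r1, c0, c1 = self.rect
        if not (r0 < r1 and c0 < c1) or min(r0, c0) < 0:
            raise ValueError(f"invalid rect {self.rect}")
        if self.placement not in ("above", "below"):
            raise ValueError(f"placement must be 'above' or 'below', got {self.placement!r}")


@dataclass(frozen=True)
class BandQuantification:
    lane_id: str
    protein: str
    raw_mean: float
    background_mean: float
    signal: float  # (255 - raw) - (255 - background), clamped at 0
    normalized_expression: float | None = None
    flagged: bool = False
    message: str = ""


def _to_8bit(image: np.ndarray) -> np.ndarray:
    """Return the image on the 0-255 scale; 16-bit input is linearly rescaled."""
    image = np.asarray(image)
    if image.dtype == np.uint8:
        return image.astype(float)
    img = image.astype(float)
    if image.dtype == np.uint16:
        return img * (255.0 / 65535.0)
    if img.size and (img.min() < 0 or img.max() > 255):
        raise ValueError("float image must already be on the 0-255 scale")
    return img


def _background_rect(
    roi: BandRoi, shape: tuple[int, int]
) -> tuple[tuple[int, int, int, int], str]:
    """Same-size rect directly above or below the band, falling back to the
    other side when the preferred placement leaves the image bounds."""
    r0, r1, c0, c1 = roi.rect
    h = r1 - r0
    candidates = [roi.placement, "below" if roi.placement == "above" else "above"]
    for placement in candidates:
        rect = (r0 - h, r0, c0, c1) if placement == "above" else (r1, r1 + h, c0, c1)
        if rect[0] >= 0 and rect[1] <= shape[0]:
            return rect, placement
    raise ValueError(f"no in-bounds background ROI for band {roi.lane_id}/{roi.protein}")


def quantify_band(
    image: np.ndarray,
    roi: BandRoi,
    other_bands: list[BandRoi] | None = None,
) -> BandQuantification:
    """Measure one band with the inversion-difference formula.

    ``other_bands`` lets the caller pass the remaining annotations so overlap
    of the background ROI with another band raises a warning.
    """
    img = _to_8bit(image)
    if img.ndim != 2:
        raise ValueError("gel image must be 2-D grayscale")
    r0, r1, c0, c1 = roi.rect
    if r1 > img.shape[0] or c1 > img.shape[1]:
        raise ValueError(f"band ROI {roi.rect} exceeds image bounds {img.shape}")
    bg_rect, _ = _background_rect(roi, img.shape)

    if other_bands:
        b0, b1, d0, d1 = bg_rect
        for other in other_bands:
            o0, o1, p0, p1 = other.rect
            if (other.lane_id, other.protein) != (roi.lane_id, roi.protein) and \
                    b0 < o1 and o0 < b1 and d0 < p1 and p0 < d1:
                warnings.warn(
                    f"background ROI of {roi.lane_id}/{roi.protein} overlaps band "
                    f"{other.lane_id}/{other.protein}", stacklevel=2,
                )

    raw = float(img[r0:r1, c0:c1].mean())
    bg = float(img[bg_rect[0]:bg_rect[1], bg_rect[2]:bg_rect[3]].mean())
    signal = max((255.0 - raw) - (255.0 - bg), 0.0)
    return BandQuantification(roi.lane_id, roi.protein, raw, bg, signal)


def normalize_expression(
    quantifications: list[BandQuantification],
    loading_protein: str = "beta_actin",
    reference_condition: str = "NT",
) -> list[BandQuantification]:
    """Normalize signals to the loading control and the reference condition.

    Lanes with zero loading-control signal are flagged and their expression
    left undefined.  The reference lane maps to 1.0 for every protein.
    """
    loading = {q.lane_id: q.signal for q in quantifications if q.protein == loading_protein}
    missing = {q.lane_id for q in quantifications} - set(loading)
    if missing:
        raise ValueError(f"lanes without a {loading_protein!r} band: {sorted(missing)}")
    if reference_condition not in loading:
        raise ValueError(f"reference condition {reference_condition!r} not among lanes")

    def ratio(q: BandQuantification) -> float | None:
        return q.signal / loading[q.lane_id] if loading[q.lane_id] > 0 else None

    ref_ratio = {
        q.protein: ratio(q) for q in quantifications if q.lane_id == reference_condition
    }
    out: list[BandQuantification] = []
    for q in quantifications:
        r, ref = ratio(q), ref_ratio.get(q.protein)
        if r is None:
            out.append(replace(q, flagged=True, message="zero loading-control signal"))
        elif ref is None or ref == 0:
            out.append(replace(q, flagged=True,
                               message="reference condition has no usable signal"))
        else:
            out.append(replace(q, normalized_expression=r / ref))
    return out
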
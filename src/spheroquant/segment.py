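"""Bright-field spheroid segmentation by dual-sensitivity adaptive thresholding.

The procedure binarizes a transmitted-light image twice with the same local
statistic but two sensitivities: a stringent pass isolates the dense spheroid
core, a permissive pass additionally picks up the halo of loose migrating
cells.  A pixel is foreground when it deviates from the local-window mean by
more than ``sensitivity`` times the local dynamic range, in the direction
given by the contrast polarity.  The core is the largest surviving connected
component (ties broken by centroid proximity to the frame centre — one
spheroid per U-bottom well); the total mask is the union of permissive-pass
components lying within a search radius of the core, plus the core itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "SegmentationParams",
    "SegmentationResult",
    "binarize_adaptive",
    "segment_spheroid",
    "area_to_um2",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the dual-sensitivity segmentation.

    ``window_px`` defaults to an eighth of the image width (made odd): well
    above the halo-cell scale but below the smallest spheroid diameter, and
    local enough that a faint halo cell near the core rim is judged against
    mostly-background statistics rather than a window dominated by the dark
    core.  ``sensitivity_total`` must not exceed ``sensitivity_core`` — the
    total pass is the permissive one.
    """

    window_px: int | None = None
    sensitivity_core: float = 0.35
    sensitivity_total: float = 0.15
    min_object_px: int = 25
    fill_holes: bool = True
    close_radius_px: int = 4  # bridges rim gaps before hole filling (core pass)
    polarity: str = "dark_foreground"
    halo_search_factor: float = 2.5  # x core equivalent radius

    def __post_init__(self) -> None:
        if self.window_px is not None:
            _check_window(self.window_px)
        if self.sensitivity_total > self.sensitivity_core:
            raise ValueError(
                "sensitivity_total must be <= sensitivity_core "
                "(the total pass is the more permissive one)"
            )
        if self.min_object_px < 0:
            raise ValueError("min_object_px must be >= 0")
        if self.close_radius_px < 0:
            raise ValueError("close_radius_px must be >= 0")
        if self.polarity not in ("dark_foreground", "light_foreground"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    def resolved_window(self, image_shape: tuple[int, int]) -> int:
        if self.window_px is not None:
            return self.window_px
        w = max(3, image_shape[1] // 8)
        return w if w % 2 == 1 else w + 1


@dataclass
class SegmentationResult:
    """Core and total (core + halo) masks with areas in square micrometres."""

    core_mask: np.ndarray
    total_mask: np.ndarray
    core_area_um2: float
    total_area_um2: float
    halo_area_um2: float
    detected: bool = True

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "SegmentationResult":
        z = np.zeros(shape, dtype=bool)
        return cls(z, z.copy(), 0.0, 0.0, 0.0, detected=False)


def _check_window(window_px: int) -> None:
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError(f"window_px must be an odd integer >= 3, got {window_px}")


def binarize_adaptive(
    image: np.ndarray,
    window_px: int,
    sensitivity: float,
    polarity: str = "dark_foreground",
) -> np.ndarray:
    """Adaptive local-mean threshold with a dynamic-range sensitivity offset.

    Foreground iff the pixel lies beyond the local mean by
    ``sensitivity * (local max - local min)`` in the polarity direction.
    A constant image therefore yields an empty mask.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty single-channel 2-D array")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    _check_window(window_px)
    mu = ndimage.uniform_filter(image, window_px, mode="reflect")
    local_range = ndimage.maximum_filter(image, window_px, mode="reflect") - ndimage.minimum_filter(
        image, window_px, mode="reflect"
    )
    # Guard against filter round-off on locally constant regions, where the
    # local mean can differ from the pixel value by a few ulp.
    eps = 1e-9 * max(1.0, float(np.abs(image).max()))
    offset = sensitivity * local_range + eps
    if polarity == "dark_foreground":
        return image < mu - offset
    if polarity == "light_foreground":
        return image > mu + offset
    raise ValueError(f"unknown polarity {polarity!r}")


def _clean(mask: np.ndarray, min_object_px: int) -> tuple[np.ndarray, int]:
    labels, n = ndimage.label(mask)
    if n == 0:
        return labels, 0
    if min_object_px > 0:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_object_px) + 1
        mask = np.isin(labels, keep)
        labels, n = ndimage.label(mask)
    return labels, n


def segment_spheroid(
    image: np.ndarray,
    params: SegmentationParams | None = None,
    pixel_size_um: float = 1.0,
) -> SegmentationResult:
    """Run the stringent core pass and the permissive total pass.

    A blank or noise-only image yields an explicit no-spheroid outcome
    (``detected=False``, empty masks, zero areas) rather than an exception.
    """
    params = params or SegmentationParams()
    image = np.asarray(image, dtype=float)
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    window = params.resolved_window(image.shape)

    core_raw = binarize_adaptive(image, window, params.sensitivity_core, params.polarity)
    # Drop speckle first so closing cannot weld noise into pseudo-objects.
    labels, n = _clean(core_raw, params.min_object_px)
    if n == 0:
        return SegmentationResult.empty(image.shape)
    core_raw = labels > 0
    if params.close_radius_px > 0:
        # A crowded halo can locally depress the rim contrast and nick the
        # detected boundary ring; a small closing keeps the ring fill-tight.
        r = params.close_radius_px
        yy, xx = np.ogrid[-r : r + 1, -r : r + 1]
        core_raw = ndimage.binary_closing(core_raw, structure=xx * xx + yy * yy <= r * r)
    if params.fill_holes:
        core_raw = ndimage.binary_fill_holes(core_raw)
    labels, n = ndimage.label(core_raw)
    if n == 0:
        return SegmentationResult.empty(image.shape)

    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    centroids = np.array(ndimage.center_of_mass(labels > 0, labels, index=np.arange(1, n + 1)))
    center = (np.asarray(image.shape) - 1) / 2.0
    dists = np.hypot(*(centroids - center).T)
    # Largest component wins; centroid proximity to the frame centre breaks ties.
    order = np.lexsort((dists, -sizes))
    core_label = order[0] + 1
    core_mask = labels == core_label
    core_centroid = centroids[core_label - 1]
    core_px = float(core_mask.sum())
    r_eq = np.sqrt(core_px / np.pi)

    total_raw = binarize_adaptive(image, window, params.sensitivity_total, params.polarity)
    t_labels, t_n = _clean(total_raw, params.min_object_px)
    total_mask = core_mask.copy()
    if t_n > 0:
        t_centroids = np.array(
            ndimage.center_of_mass(t_labels > 0, t_labels, index=np.arange(1, t_n + 1))
        )
        t_dists = np.hypot(*(t_centroids - core_centroid).T)
        keep = np.flatnonzero(t_dists <= params.halo_search_factor * r_eq) + 1
        if keep.size:
            total_mask |= np.isin(t_labels, keep)

    return SegmentationResult(
        core_mask=core_mask,
        total_mask=total_mask,
        core_area_um2=area_to_um2(core_px, pixel_size_um),
        total_area_um2=area_to_um2(float(total_mask.sum()), pixel_size_um),
        halo_area_um2=area_to_um2(float(total_mask.sum() - core_px), pixel_size_um),
    )


def area_to_um2(pixel_count: float, pixel_size_um: float) -> float:
    """Convert a pixel count to an area in square micrometres."""
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    if pixel_count < 0:
        raise ValueError("pixel_count must be >= 0")
    return float(pixel_count) * float(pixel_size_um) ** 2
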
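"""Seeded synthetic phantoms for every input the analysis pipeline consumes.

Each generator is a pure function of its spec (including the seed) and returns
the generated data together with exact ground truth, so segmentation, redox,
densitometry and cell-cycle code can be validated without any real microscopy,
blot, or flow-cytometry data.

The spheroid phantom emulates a heterocellular pancreatic-cancer spheroid as
seen in transmitted-light microscopy: a dense, optically thick core (modelled
as a disk of depressed intensity on a bright field, or the inverse polarity)
optionally surrounded by a halo of loose, migrating cells (small Gaussian
attenuation bumps scattered in an annulus).  The propidium-iodide (PI) channel
carries a necrosis signal that is linear in the prescribed necrotic fraction;
the calcein channel is its live-cell complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "SpheroidPhantomSpec",
    "PhantomTruth",
    "SpheroidImage",
    "DnaHistogramSpec",
    "GelPhantomSpec",
    "make_spheroid_images",
    "make_redox_pair",
    "make_dna_events",
    "make_gel_image",
]

# Intensity model shared by the bright-field phantoms (8-bit-like scale).
DEFAULT_BACKGROUND = 200.0
DEFAULT_CORE_LEVEL = 60.0
# Loose single cells are far less optically thick than the dense core; their
# weak bright-field contrast is the reason the segmentation needs a second,
# more permissive sensitivity pass at all.
DEFAULT_HALO_DEPTH = 60.0  # peak attenuation of a halo cell below background
PI_BACKGROUND = 5.0
PI_DYNAMIC_RANGE = 150.0


@dataclass(frozen=True)
class SpheroidPhantomSpec:
    """Geometry, staining and noise parameters of one spheroid phantom.

    Lengths are in micrometres; intensities on a nominal 0-255 scale.
    ``necrotic_fraction`` drives the PI channel linearly:
    mean PI inside the spheroid = PI_BACKGROUND + necrotic_fraction * PI_DYNAMIC_RANGE.
    """

    core_radius_um: float
    halo_cell_count: int = 0
    halo_radius_um: float | None = None  # default: core + 120 um migration band
    necrotic_fraction: float = 0.0
    pixel_size_um: float = 2.0
    noise_sd: float = 2.0
    seed: int = 0
    shape: tuple[int, int] = (512, 512)
    polarity: str = "dark_foreground"  # dark core on bright field, or inverse
    halo_cell_radius_um: float = 8.0

    def __post_init__(self) -> None:
        if self.core_radius_um <= 0:
            raise ValueError(f"core_radius_um must be > 0, got {self.core_radius_um}")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not 0.0 <= self.necrotic_fraction <= 1.0:
            raise ValueError(
                f"necrotic_fraction must be in [0, 1], got {self.necrotic_fraction}"
            )
        if self.halo_radius_um is not None and self.halo_radius_um < self.core_radius_um:
            raise ValueError("halo_radius_um must be >= core_radius_um")
        if self.halo_cell_count < 0:
            raise ValueError("halo_cell_count must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.polarity not in ("dark_foreground", "light_foreground"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def effective_halo_radius_um(self) -> float:
        # Cells migrate a characteristic distance off the core rim; the band
        # width does not scale with spheroid size.
        if self.halo_radius_um is not None:
            return self.halo_radius_um
        return self.core_radius_um + 120.0


@dataclass
class SpheroidImage:
    """Registered multi-channel image of one spheroid with its pixel size."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class PhantomTruth:
    """Exact ground truth attached to a generated phantom."""

    core_mask: np.ndarray
    total_mask: np.ndarray
    core_area_um2: float
    total_area_um2: float
    per_channel_truth: dict[str, Any] = field(default_factory=dict)


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius_px: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def make_spheroid_images(spec: SpheroidPhantomSpec) -> tuple[SpheroidImage, PhantomTruth]:
    """Render bright-field, calcein and PI channels plus exact truth masks.

    The halo is a set of ``halo_cell_count`` Gaussian attenuation bumps
    scattered uniformly (by area) in the annulus between the core radius and
    the halo radius; the truth halo mask is the FWHM support of the noiseless
    bump field.  Reruns with the same spec are bit-identical.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    px = spec.pixel_size_um

    r_core_px = spec.core_radius_um / px
    core_mask = _disk_mask(shape, center, r_core_px)

    # Halo: sum of Gaussian bumps; sigma from the FWHM radius of one cell.
    halo_field = np.zeros(shape, dtype=float)
    if spec.halo_cell_count > 0:
        r_halo_px = spec.effective_halo_radius_um / px
        sigma_px = (spec.halo_cell_radius_um / px) / np.sqrt(2.0 * np.log(2.0))
        margin = 3.0 * sigma_px + 1.0
        r_halo_px = min(r_halo_px, min(shape) / 2.0 - margin)
        r_halo_px = max(r_halo_px, r_core_px)
        # Uniform by area in the annulus [r_core, r_halo].
        u = rng.uniform(size=spec.halo_cell_count)
        radii = np.sqrt(r_core_px**2 + u * (r_halo_px**2 - r_core_px**2))
        angles = rng.uniform(0.0, 2.0 * np.pi, size=spec.halo_cell_count)
        rows = center[0] + radii * np.sin(angles)
        cols = center[1] + radii * np.cos(angles)
        rr = np.arange(shape[0])[:, None]
        cc = np.arange(shape[1])[None, :]
        for r0, c0 in zip(rows, cols):
            halo_field += np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma_px**2))
    halo_mask = halo_field >= 0.5  # FWHM support of unit-amplitude bumps
    halo_mask &= ~core_mask
    total_mask = core_mask | halo_mask

    contrast_core = DEFAULT_BACKGROUND - DEFAULT_CORE_LEVEL
    attenuation = contrast_core * core_mask + DEFAULT_HALO_DEPTH * np.clip(halo_field, 0, 1) * ~core_mask
    brightfield = DEFAULT_BACKGROUND - attenuation
    if spec.polarity == "light_foreground":
        brightfield = 255.0 - brightfield

    pi_level = PI_BACKGROUND + spec.necrotic_fraction * PI_DYNAMIC_RANGE
    calcein_level = PI_BACKGROUND + (1.0 - spec.necrotic_fraction) * PI_DYNAMIC_RANGE
    pi = np.where(total_mask, pi_level, PI_BACKGROUND)
    calcein = np.where(total_mask, calcein_level, PI_BACKGROUND)

    channels = {}
    for name, chan in (("brightfield", brightfield), ("calcein", calcein), ("pi", pi)):
        noisy = chan + rng.normal(0.0, spec.noise_sd, size=shape) if spec.noise_sd > 0 else chan.astype(float)
        channels[name] = np.clip(noisy, 0.0, 255.0).astype(np.float32)

    area = float(px**2)
    truth = PhantomTruth(
        core_mask=core_mask,
        total_mask=total_mask,
        core_area_um2=float(core_mask.sum()) * area,
        total_area_um2=float(total_mask.sum()) * area,
        per_channel_truth={
            "pi_mean_in_mask": pi_level,
            "pi_background": PI_BACKGROUND,
            "calcein_mean_in_mask": calcein_level,
            "necrotic_fraction": spec.necrotic_fraction,
            "brightfield_contrast": contrast_core,
        },
    )
    return SpheroidImage(channels=channels, pixel_size_um=px), truth


def make_redox_pair(
    orr_field: np.ndarray,
    intensity_scale: float = 256.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build an (NADH, FAD) channel pair realizing a prescribed per-pixel ORR.

    Per pixel FAD = intensity_scale * orr and NADH = intensity_scale - FAD, so
    in the noiseless case FAD / (FAD + NADH) inverts to the truth field
    bit-exactly.  Returns ``(nadh, fad, truth)`` where ``truth`` is the
    noiseless per-pixel ORR.
    """
    orr_field = np.asarray(orr_field, dtype=float)
    if orr_field.size == 0:
        raise ValueError("orr_field is empty")
    if np.any(orr_field < 0.0) or np.any(orr_field > 1.0):
        raise ValueError("orr_field values must lie in [0, 1]")
    if intensity_scale <= 0:
        raise ValueError("intensity_scale must be > 0")
    fad = intensity_scale * orr_field
    nadh = intensity_scale - fad
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        nadh = nadh + rng.normal(0.0, noise_sd, size=orr_field.shape)
        fad = fad + rng.normal(0.0, noise_sd, size=orr_field.shape)
    return nadh, fad, orr_field.copy()


@dataclass(frozen=True)
class DnaHistogramSpec:
    """Mixture spec for a single-parameter DNA-content event list.

    ``fractions`` are the (sub-G1, G1, S, G2/M) proportions and must sum to 1.
    The G2/M mean is fixed at twice the G1 mean (4N vs 2N DNA content); S-phase
    events are uniform between the two peaks; sub-G1 (apoptotic, degraded DNA)
    events follow a broad truncated exponential strictly below the G1 peak.
    """

    n_events: int
    fractions: tuple[float, float, float, float]
    g1_mean: float = 100.0
    cv_g1: float = 0.05
    seed: int = 0
    subg1_floor_frac: float = 0.10  # lower support of sub-G1, as fraction of g1_mean

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if len(self.fractions) != 4 or any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be four non-negative proportions")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(self.fractions)}")
        if self.g1_mean <= 0:
            raise ValueError("g1_mean must be > 0")
        if self.cv_g1 < 0:
            raise ValueError("cv_g1 must be >= 0")


PHASE_NAMES = ("sub_g1", "g1", "s", "g2m")


def make_dna_events(spec: DnaHistogramSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw DNA-content events from the four-phase mixture.

    Returns ``(events, labels)`` with labels as integer phase indices into
    :data:`PHASE_NAMES` (retained as ground truth for recovery tests).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_events
    labels = rng.choice(4, size=n, p=np.asarray(spec.fractions, dtype=float))
    events = np.empty(n, dtype=float)

    sigma_g1 = spec.cv_g1 * spec.g1_mean
    g2m_mean = 2.0 * spec.g1_mean
    sigma_g2m = spec.cv_g1 * g2m_mean

    # Sub-G1: truncated exponential on [floor, g1_mean - 3 sigma], mass rising
    # towards the upper bound (heavily degraded DNA is rarer than mildly
    # degraded DNA), strictly separable from G1 by the 3-sigma gate.
    upper = spec.g1_mean - 3.0 * sigma_g1
    lower = spec.subg1_floor_frac * spec.g1_mean
    if upper <= lower:
        upper = max(lower + 1e-6, 0.5 * spec.g1_mean)
    scale = (upper - lower) / 2.0
    m = labels == 0
    if m.any():
        u = rng.uniform(size=int(m.sum()))
        z = 1.0 - np.exp(-(upper - lower) / scale)
        events[m] = upper + scale * np.log1p(-u * z)
    m = labels == 1
    if m.any():
        events[m] = rng.normal(spec.g1_mean, sigma_g1, size=int(m.sum()))
    m = labels == 2
    if m.any():
        events[m] = rng.uniform(spec.g1_mean, g2m_mean, size=int(m.sum()))
    m = labels == 3
    if m.any():
        events[m] = rng.normal(g2m_mean, sigma_g2m, size=int(m.sum()))
    np.clip(events, 1e-9, None, out=events)
    return events, labels


@dataclass(frozen=True)
class GelPhantomSpec:
    """Multi-lane western-blot phantom with known band intensities.

    ``lanes`` maps an ordered list of condition labels to per-protein true
    signals, where signal is the inverted-intensity difference a densitometry
    readout should recover: band pixel value = background_level - signal.
    """

    lanes: tuple[tuple[str, dict[str, float]], ...]
    background_level: float = 200.0
    band_height_px: int = 18
    band_width_px: int = 36
    lane_gap_px: int = 18
    row_gap_px: int = 60
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lanes:
            raise ValueError("at least one lane required")
        if not 0 <= self.background_level <= 255:
            raise ValueError("background_level must be an 8-bit intensity")
        proteins = list(self.lanes[0][1])
        for label, bands in self.lanes:
            if list(bands) != proteins:
                raise ValueError(f"lane {label!r} does not list the same proteins")
            for prot, sig in bands.items():
                value = self.background_level - sig
                if not 0 <= value <= 255 or sig < 0:
                    raise ValueError(
                        f"band {label}/{prot}: signal {sig} leaves 8-bit range"
                    )

    @property
    def proteins(self) -> list[str]:
        return list(self.lanes[0][1])


def make_gel_image(spec: GelPhantomSpec) -> tuple[np.ndarray, dict[str, dict[str, float]], list[dict]]:
    """Render an 8-bit grayscale gel image with rectangular bands.

    Returns ``(image, truth, rois)`` where ``truth[condition][protein]`` is the
    designed signal and ``rois`` lists band rectangles as dicts with keys
    ``lane_id``, ``protein``, ``rect`` (row0, row1, col0, col1 half-open) and
    ``placement`` suitable for the densitometry module.
    """
    n_lanes = len(spec.lanes)
    proteins = spec.proteins
    h, w = spec.band_height_px, spec.band_width_px
    width = spec.lane_gap_px + n_lanes * (w + spec.lane_gap_px)
    height = spec.row_gap_px + len(proteins) * (h + spec.row_gap_px)
    img = np.full((height, width), spec.background_level, dtype=float)

    truth: dict[str, dict[str, float]] = {}
    rois: list[dict] = []
    for j, (label, bands) in enumerate(spec.lanes):
        truth[label] = dict(bands)
        c0 = spec.lane_gap_px + j * (w + spec.lane_gap_px)
        for i, prot in enumerate(proteins):
            r0 = spec.row_gap_px + i * (h + spec.row_gap_px)
            img[r0 : r0 + h, c0 : c0 + w] = spec.background_level - bands[prot]
            rois.append(
                {
                    "lane_id": label,
                    "protein": prot,
                    "rect": (r0, r0 + h, c0, c0 + w),
                    "placement": "above",
                }
            )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, truth, rois
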
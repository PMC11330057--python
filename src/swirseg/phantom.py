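"""Synthetic SWIR and CP-OCT phantoms with known ground truth.

Clinical frames of interproximal lesions are not publicly deposited, so every
downstream stage of this package is exercised on phantoms that reproduce the
statistical structure the segmentation relies on:

* **Reflectance** frames: lesions scatter strongly and appear *brighter* than
  sound enamel; specular highlights appear as bright spots away from the
  contact.  Lesion pixels are placed at ``I_s / (1 - c)`` so the reflectance
  contrast transform ``(I_t - I_s) / I_t`` recovers the target contrast ``c``
  exactly in the noise-free limit.
* **Transillumination** frames (occlusal and proximal): lesions absorb and
  appear *darker*; direct light that bypasses tooth structure saturates the
  frame margins.  Lesion pixels sit at ``I_s * (1 - c)`` so
  ``(I_s - I_t) / I_s`` recovers ``c``.
* **CP-OCT b-scans**: a bright surface echo, exponential depth attenuation in
  sound enamel, sinusoidal birefringence banding, and — in lesion columns —
  an elevated-reflectivity subsurface band whose two flanking intensity
  minima are separated by the requested lesion depth (stored as optical
  distance; the generator multiplies the physical depth by the refractive
  index when placing the minima).

Lesions are half-ellipses clipped at the proximal contact line, so the
"adjoining the contact" selection rule is exercised by construction, and all
artifacts are kept at least 10 px away from the contact so ground truth stays
unambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .images import Bscan, IntensityImage, Modality, TRANSILLUMINATION

#: Fixed default seed for fixture generation.
DEFAULT_SEED = 20240817

#: Minimum clearance (px) between artifacts and the contact line.
ARTIFACT_CLEARANCE_PX = 10

#: Multiplicative speckle level used for "moderate speckle" OCT studies.
MODERATE_SPECKLE_SIGMA = 0.10


@dataclass
class PhantomConfig:
    """Parameters of one synthetic frame.

    Intensities live in [0, 1] (written as 16-bit TIFF by the I/O layer).
    ``lesion_axes`` are the (axial/row, lateral/col) semi-axes of the
    elliptical lesion in pixels; for SWIR phantoms the half-ellipse extends
    away from ``contact_line``, for OCT phantoms the column semi-axis sets
    the lateral half-width of the lesion band.

    OCT-specific fields: ``oct_attenuation`` (1/mm, applied along the optical
    path), ``oct_band_period`` (mm optical, birefringence banding),
    ``oct_lesion_depth_true`` (mm of *physical* distance between the two
    flanking minima; ``None`` generates a lesion-free scan),
    ``oct_axial_extent_mm`` (optical scan depth, 7 mm for the system
    emulated), ``oct_surface_row`` / ``oct_surface_slope`` (surface geometry
    in pixels / rows-per-column).
    """

    image_height: int = 192
    image_width: int = 256
    mm_per_pixel: float = 0.03
    modality: Modality = Modality.REFLECTANCE
    sound_intensity: float = 0.5
    lesion_contrast_true: float = 0.2
    lesion_center: Optional[tuple[int, int]] = None
    lesion_axes: tuple[int, int] = (28, 36)
    contact_line: Optional[int] = None
    noise_sigma: float = 0.005
    specular_spots: Optional[Sequence[tuple[tuple[int, int], int, float]]] = None
    bleed_margin: int = 16
    oct_attenuation: float = 0.8
    oct_band_period: float = 0.35
    oct_band_amplitude: float = 0.18
    oct_lesion_depth_true: Optional[float] = 1.0
    oct_axial_extent_mm: float = 7.0
    oct_surface_row: int = 24
    oct_surface_slope: float = 0.0
    refractive_index: float = 1.6
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        if not (0.0 < self.sound_intensity <= 1.0):
            raise ValueError("sound_intensity must lie in (0, 1]")
        if self.lesion_contrast_true < 0:
            raise ValueError("lesion_contrast_true must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not self.mm_per_pixel > 0:
            raise ValueError("mm_per_pixel must be positive")
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")
        if self.contact_line is None:
            self.contact_line = self.image_width // 2
        if self.lesion_center is None:
            self.lesion_center = (self.image_height // 2, self.contact_line)


@dataclass
class GroundTruth:
    """What the generator actually drew, for comparison with pipeline output."""

    lesion_mask: np.ndarray
    true_area_px: int
    true_mean_contrast: float
    true_depth_mm: Optional[float]
    contact_line: int

    def __post_init__(self) -> None:
        self.lesion_mask = np.asarray(self.lesion_mask, dtype=bool)
        if self.true_area_px != int(self.lesion_mask.sum()):
            raise ValueError("true_area_px inconsistent with lesion_mask")


def _lesion_half_ellipse(cfg: PhantomConfig) -> np.ndarray:
    """Boolean mask of the half-ellipse lesion clipped at the contact line."""
    h, w = cfg.image_height, cfg.image_width
    r0, c0 = cfg.lesion_center
    a, b = cfg.lesion_axes
    if a <= 0 or b <= 0:
        raise ValueError("lesion_axes must be positive")
    rr, cc = np.mgrid[0:h, 0:w]
    ellipse = ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0
    # keep the half extending away from the contact (toward larger columns
    # when the center sits at/right of the contact, else toward smaller)
    if c0 >= cfg.contact_line:
        mask = ellipse & (cc >= cfg.contact_line)
    else:
        mask = ellipse & (cc <= cfg.contact_line)
    if not mask.any():
        raise ValueError("lesion ellipse lies fully outside the image")
    cols = np.unique(np.nonzero(mask)[1])
    if np.min(np.abs(cols - cfg.contact_line)) > 1:
        raise ValueError("lesion ellipse does not intersect the contact line")
    return mask


def make_swir_phantom(cfg: PhantomConfig) -> tuple[IntensityImage, GroundTruth]:
    """Generate a SWIR reflectance or transillumination phantom.

    Returns the frame and its ground truth.  Deterministic in ``cfg.seed``.
    """
    if cfg.modality not in (
        Modality.REFLECTANCE,
        Modality.OCCLUSAL_TRANS,
        Modality.PROXIMAL_TRANS,
    ):
        raise ValueError(f"not a SWIR modality: {cfg.modality}")
    c = cfg.lesion_contrast_true
    i_s = cfg.sound_intensity
    if cfg.modality is Modality.REFLECTANCE and c >= 1:
        raise ValueError("reflectance contrast >= 1 implies unbounded intensity")

    mask = _lesion_half_ellipse(cfg)
    img = np.full((cfg.image_height, cfg.image_width), i_s, dtype=float)
    if cfg.modality is Modality.REFLECTANCE:
        img[mask] = i_s / (1.0 - c)
    else:
        img[mask] = i_s * (1.0 - c)

    if cfg.modality is Modality.REFLECTANCE:
        spots = cfg.specular_spots
        if spots is None:
            spots = [((28, 36), 9, 0.95)]
        for (r0, c0), radius, intensity in spots:
            if abs(c0 - cfg.contact_line) - radius < ARTIFACT_CLEARANCE_PX:
                raise ValueError("specular spot too close to the contact line")
            rr, cc = np.mgrid[0 : cfg.image_height, 0 : cfg.image_width]
            spot = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
            if (spot & mask).any():
                raise ValueError("specular spot overlaps the lesion")
            img[spot] = intensity
    elif cfg.bleed_margin > 0:
        m = cfg.bleed_margin
        if min(cfg.contact_line, cfg.image_width - 1 - cfg.contact_line) < (
            m + ARTIFACT_CLEARANCE_PX
        ):
            raise ValueError("bleed margin too close to the contact line")
        img[:, :m] = 1.0
        img[:, -m:] = 1.0

    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)

    cols = np.nonzero(mask)[1]
    depth_mm = float((cols.max() - cols.min() + 1) * cfg.mm_per_pixel)
    truth = GroundTruth(
        lesion_mask=mask,
        true_area_px=int(mask.sum()),
        true_mean_contrast=float(c),
        true_depth_mm=depth_mm,
        contact_line=cfg.contact_line,
    )
    frame = IntensityImage(img, cfg.modality, mm_per_pixel=cfg.mm_per_pixel)
    return frame, truth


# CP-OCT phantom profile constants (intensity units in [0, 1]):
_OCT_BACKGROUND = 0.02
_OCT_SURFACE_PEAK = 1.0
_OCT_SOUND_AMPLITUDE = 0.55
_OCT_MIN_UPPER = 0.06  # flanking minimum above the lesion
_OCT_MIN_LOWER = 0.05  # flanking minimum below the lesion (the lowest)
_OCT_LESION_PEAK = 0.60
_OCT_REBOUND = 0.28
_OCT_TAIL_FLOOR = 0.12
_OCT_SURFACE_WIDTH_PX = 2
_OCT_SURFACE_GAP_MM = 0.15  # optical mm from surface echo to upper minimum
_OCT_REBOUND_PX = 6


def _sound_profile(depth_mm: np.ndarray, cfg: PhantomConfig) -> np.ndarray:
    """Attenuated, banded sound-enamel A-line as a function of optical depth."""
    band = 1.0 + cfg.oct_band_amplitude * np.sin(
        2.0 * np.pi * depth_mm / cfg.oct_band_period
    )
    return _OCT_SOUND_AMPLITUDE * np.exp(-cfg.oct_attenuation * depth_mm) * band


def make_oct_phantom(cfg: PhantomConfig) -> tuple[Bscan, GroundTruth]:
    """Generate a CP-OCT b-scan phantom.

    The axial axis is stored as optical distance.  In lesion columns the
    A-line is built from piecewise-linear knots so that the two lowest local
    minima sit exactly at the constructed rows, separated by
    ``oct_lesion_depth_true * refractive_index`` of optical distance (to the
    nearest axial pixel).  Banding is suppressed inside the lesion span —
    demineralized enamel depolarizes and washes out the birefringence bands —
    which keeps the ground-truth minima unambiguous.
    """
    if cfg.modality is not Modality.OCT_BSCAN:
        raise ValueError(f"not an OCT modality: {cfg.modality}")
    rows, cols = cfg.image_height, cfg.image_width
    ax = cfg.oct_axial_extent_mm / rows  # optical mm per axial px
    n = cfg.refractive_index

    depth_true = cfg.oct_lesion_depth_true
    if depth_true is not None:
        if depth_true <= 0:
            raise ValueError("oct_lesion_depth_true must be positive")
        if depth_true > cfg.oct_axial_extent_mm / n:
            raise ValueError(
                "lesion depth exceeds the physical scan range "
                f"({cfg.oct_axial_extent_mm / n:.3f} mm)"
            )

    rr = np.arange(rows)
    surf_rows = np.rint(
        cfg.oct_surface_row + cfg.oct_surface_slope * (np.arange(cols) - cols / 2)
    ).astype(int)
    if surf_rows.min() < 0 or surf_rows.max() > rows // 3:
        raise ValueError("surface line outside the expected upper third")

    img = np.empty((rows, cols), dtype=float)
    lesion_mask = np.zeros((rows, cols), dtype=bool)
    half_width = cfg.lesion_axes[1]
    lesion_cols = np.zeros(cols, dtype=bool)
    gap_px = max(2, int(round(_OCT_SURFACE_GAP_MM / ax)))

    realized_depth_mm: Optional[float] = None
    depth_px = 0
    if depth_true is not None:
        depth_px = int(round(depth_true * n / ax))
        if depth_px < 5:
            raise ValueError("lesion depth below axial resolution")
        realized_depth_mm = depth_px * ax / n
        c0 = cfg.lesion_center[1]
        lesion_cols = np.abs(np.arange(cols) - c0) <= half_width
        z_check = surf_rows[lesion_cols].max() + _OCT_SURFACE_WIDTH_PX + gap_px
        if z_check + depth_px + _OCT_REBOUND_PX + 4 >= rows:
            raise ValueError("lesion does not fit in the scan depth")

    for col in range(cols):
        zs = surf_rows[col]
        prof = np.full(rows, _OCT_BACKGROUND)
        top = zs + _OCT_SURFACE_WIDTH_PX
        prof[zs : top + 1] = _OCT_SURFACE_PEAK
        below = rr > top
        d_mm = (rr[below] - top) * ax
        if lesion_cols[col]:
            z1 = top + gap_px
            z2 = z1 + depth_px
            zmid = (z1 + z2) // 2
            z3 = z2 + _OCT_REBOUND_PX
            # flanking minima get a 3-px flat bottom: the dark zones above
            # and below a lesion have finite thickness, and a single-pixel
            # minimum would not survive the kernel-3 median despeckling
            knots_z = [top, z1 - 1, z1 + 1, zmid, z2 - 1, z2 + 1, z3]
            knots_v = [
                _OCT_SURFACE_PEAK,
                _OCT_MIN_UPPER,
                _OCT_MIN_UPPER,
                _OCT_LESION_PEAK,
                _OCT_MIN_LOWER,
                _OCT_MIN_LOWER,
                _OCT_REBOUND,
            ]
            seg = (rr > top) & (rr <= z3)
            prof[seg] = np.interp(rr[seg], knots_z, knots_v)
            tail = rr > z3
            d_tail = (rr[tail] - z3) * ax
            base = np.maximum(
                _OCT_TAIL_FLOOR, _OCT_REBOUND * np.exp(-cfg.oct_attenuation * d_tail)
            )
            band = 1.0 + 0.3 * cfg.oct_band_amplitude * np.sin(
                2.0 * np.pi * d_tail / cfg.oct_band_period
            )
            prof[tail] = base * band
            lesion_mask[z1 : z2 + 1, col] = True
        else:
            prof[below] = _sound_profile(d_mm, cfg)
        img[:, col] = prof

    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        img = img * (1.0 + rng.normal(0.0, cfg.noise_sigma, img.shape))
    img = np.clip(img, 0.0, 1.0)

    truth = GroundTruth(
        lesion_mask=lesion_mask,
        true_area_px=int(lesion_mask.sum()),
        true_mean_contrast=float("nan"),
        true_depth_mm=realized_depth_mm,
        contact_line=cfg.contact_line,
    )
    scan = Bscan(
        img,
        mm_per_pixel_axial_optical=ax,
        mm_per_pixel_lateral=cfg.mm_per_pixel,
        refractive_index=n,
    )
    return scan, truth
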
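"""Common image and ROI containers.

All pipelines in this package operate on plain 2-D numpy intensity grids
carried by small dataclasses that keep track of the acquisition modality and
the pixel scale.  Coordinates are row-major, 0-based, and refer to pixel
centers throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np


class Modality(str, enum.Enum):
    """Imaging geometry of a frame.

    ``reflectance``     SWIR occlusal reflectance (lesions bright).
    ``occlusal_trans``  SWIR occlusal transillumination (lesions dark).
    ``proximal_trans``  SWIR proximal transillumination (lesions dark).
    ``radiograph``      bitewing radiograph (lesions radiolucent/dark).
    ``oct_bscan``       CP-OCT cross-sectional scan (rows = optical depth).
    """

    REFLECTANCE = "reflectance"
    OCCLUSAL_TRANS = "occlusal_trans"
    PROXIMAL_TRANS = "proximal_trans"
    RADIOGRAPH = "radiograph"
    OCT_BSCAN = "oct_bscan"


#: Modalities that use the transillumination contrast transform.
TRANSILLUMINATION = frozenset(
    {Modality.OCCLUSAL_TRANS, Modality.PROXIMAL_TRANS}
)


def _as_pixel_array(pixels) -> np.ndarray:
    arr = np.asarray(pixels, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite intensities")
    if np.any(arr < 0):
        raise ValueError("image contains negative intensities")
    return arr


@dataclass
class IntensityImage:
    """A 2-D grayscale frame with modality tag and millimetre scale.

    Parameters
    ----------
    pixels : ndarray
        2-D array of finite, non-negative intensities (arbitrary units).
    modality : Modality or str
        Acquisition geometry; decides which contrast transform applies.
    mm_per_pixel : float, optional
        Isotropic pixel pitch in mm.  May be left unset until calibration
        (see :func:`swirseg.segmentation.calibrate_px_to_mm`).
    """

    pixels: np.ndarray
    modality: Modality
    mm_per_pixel: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = _as_pixel_array(self.pixels)
        self.modality = Modality(self.modality)
        if self.mm_per_pixel is not None and not self.mm_per_pixel > 0:
            raise ValueError("mm_per_pixel must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_scale(self, mm_per_pixel: float) -> "IntensityImage":
        """Return a copy carrying the given pixel pitch."""
        if not mm_per_pixel > 0:
            raise ValueError("mm_per_pixel must be positive")
        return replace(self, mm_per_pixel=mm_per_pixel)


def _as_coord_array(coords, name: str) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(coords, dtype=int))
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"{name} must be an (N, 2) array of (row, col)")
    return arr


@dataclass
class RoiSet:
    """Manual regions of interest for the semi-automatic procedure.

    ``sound_region``
        Pixels of sound enamel adjacent to the interproximal contact; their
        mean intensity defines the reference I_s of the contrast transform.
    ``contact_roi``
        The proximal contact, rasterized to a thin band of pixels; mask
        components must adjoin it to count as the lesion.
    ``lesion_roi``
        Examiner-drawn lesion area (radiographs only).
    """

    sound_region: np.ndarray
    contact_roi: np.ndarray
    lesion_roi: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.sound_region = _as_coord_array(self.sound_region, "sound_region")
        self.contact_roi = _as_coord_array(self.contact_roi, "contact_roi")
        if self.lesion_roi is not None:
            self.lesion_roi = _as_coord_array(self.lesion_roi, "lesion_roi")
        if len(self.sound_region) == 0:
            raise ValueError("sound_region must be non-empty")
        sound = set(map(tuple, self.sound_region))
        contact = set(map(tuple, self.contact_roi))
        if sound & contact:
            raise ValueError("sound_region must be disjoint from contact_roi")

    def contact_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize the contact ROI into a boolean image of ``shape``."""
        return coords_to_mask(self.contact_roi, shape)

    def sound_mask(self, shape: tuple[int, int]) -> np.ndarray:
        return coords_to_mask(self.sound_region, shape)


def coords_to_mask(coords: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    if len(coords):
        rr = np.clip(coords[:, 0], 0, shape[0] - 1)
        cc = np.clip(coords[:, 1], 0, shape[1] - 1)
        mask[rr, cc] = True
    return mask


def mask_to_coords(mask: np.ndarray) -> np.ndarray:
    return np.argwhere(np.asarray(mask, dtype=bool))


@dataclass
class Bscan:
    """A CP-OCT b-scan: rows are axial OPTICAL depth, columns are lateral.

    The axial pitch is stored as optical distance (what the interferometer
    measures); conversion to physical depth inside enamel divides by the
    refractive index (default 1.6).
    """

    pixels: np.ndarray
    mm_per_pixel_axial_optical: float
    mm_per_pixel_lateral: float
    refractive_index: float = 1.6

    def __post_init__(self) -> None:
        self.pixels = _as_pixel_array(self.pixels)
        if not self.mm_per_pixel_axial_optical > 0:
            raise ValueError("axial scale must be positive")
        if not self.mm_per_pixel_lateral > 0:
            raise ValueError("lateral scale must be positive")
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def axial_extent_optical_mm(self) -> float:
        """Scan depth in optical millimetres (in air)."""
        return self.shape[0] * self.mm_per_pixel_axial_optical
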
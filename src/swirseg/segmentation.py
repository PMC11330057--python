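"""Semi-automatic SWIR lesion segmentation.

The procedure mirrors the clinical image-processing chain: a raw frame is
converted to a per-pixel contrast map against a manually selected
sound-enamel reference, thresholded at contrast 0.1, and the connected
components of the resulting mask that adjoin the proximal contact are taken
as the lesion.  Components away from the contact — specular highlights in
reflectance, direct-light bleed in transillumination — are discarded.

Contrast transforms (``i_s`` = mean intensity of the sound ROI, ``I_t`` =
target pixel):

* reflectance:        ``(I_t - i_s) / I_t``  (lesions brighter than sound)
* transillumination:  ``(i_s - I_t) / i_s``  (lesions darker than sound)

A positive detection is a non-empty contact-adjoining lesion component; a
failed segmentation is a negative detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure

from .images import (
    IntensityImage,
    Modality,
    RoiSet,
    TRANSILLUMINATION,
    coords_to_mask,
)

#: Clinical detection threshold on the contrast map.
DEFAULT_CONTRAST_THRESHOLD = 0.1


@dataclass
class ContrastMap:
    """Per-pixel dimensionless contrast against the sound reference.

    ``valid`` flags pixels where the transform is defined; under reflectance
    a zero-intensity target pixel has no finite contrast and is excluded
    from all masks.
    """

    values: np.ndarray
    i_s: float
    modality: Modality
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)


@dataclass
class LesionSegment:
    """The selected contact-adjoining lesion component and its metrics."""

    mask: np.ndarray
    detected: bool
    area_px: int
    area_mm2: Optional[float] = None
    mean_contrast: Optional[float] = None
    depth_mm: Optional[float] = None
    depth_px: Optional[float] = None


def contrast_map(img: IntensityImage, roi: RoiSet) -> ContrastMap:
    """Convert a frame to a contrast map using the modality's transform.

    ``i_s`` is the arithmetic mean over the sound ROI (use ``reducer`` via
    :func:`contrast_map_with` for a median alternative).
    """
    return contrast_map_with(img, roi, reducer=np.mean)


def contrast_map_with(img: IntensityImage, roi: RoiSet, reducer=np.mean) -> ContrastMap:
    sound = img.pixels[roi.sound_region[:, 0], roi.sound_region[:, 1]]
    if sound.size == 0:
        raise ValueError("empty sound region")
    i_s = float(reducer(sound))
    if i_s <= 0:
        raise ValueError("sound reference intensity must be positive")
    pix = img.pixels
    if img.modality in TRANSILLUMINATION:
        values = (i_s - pix) / i_s
        valid = np.ones_like(pix, dtype=bool)
    elif img.modality is Modality.REFLECTANCE:
        valid = pix > 0
        values = np.full_like(pix, -np.inf)
        np.divide(pix - i_s, pix, out=values, where=valid)
    else:
        raise ValueError(f"no contrast transform for modality {img.modality}")
    return ContrastMap(values=values, i_s=i_s, modality=img.modality, valid=valid)


def threshold_mask(cm: ContrastMap, threshold: float = DEFAULT_CONTRAST_THRESHOLD) -> np.ndarray:
    """Binary mask of pixels with contrast >= threshold.

    The boundary is kept: pixels at exactly the threshold survive (only
    contrast strictly lower than the threshold is removed).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return (cm.values >= threshold) & cm.valid


def select_lesion(
    mask: np.ndarray, roi: RoiSet, connectivity: int = 2
) -> LesionSegment:
    """Keep the mask components that adjoin the proximal contact.

    Components are labeled with 8-connectivity by default
    (``connectivity=2`` in scikit-image terms); a component adjoins the
    contact if any of its pixels shares or is 8-adjacent to a contact-ROI
    pixel.  Multiple adjoining components are merged into one lesion.
    """
    mask = np.asarray(mask, dtype=bool)
    if len(roi.contact_roi) == 0:
        raise ValueError("contact_roi must be non-empty")
    if not mask.any():
        return LesionSegment(mask=mask.copy(), detected=False, area_px=0)
    labels = measure.label(mask, connectivity=connectivity)
    contact = coords_to_mask(roi.contact_roi, mask.shape)
    struct = np.ones((3, 3), dtype=bool) if connectivity == 2 else None
    reach = ndimage.binary_dilation(contact, structure=struct)
    touching = np.unique(labels[reach & (labels > 0)])
    lesion = np.isin(labels, touching) & (labels > 0) if touching.size else np.zeros_like(mask)
    return LesionSegment(
        mask=lesion, detected=bool(lesion.any()), area_px=int(lesion.sum())
    )


def _contact_direction(contact: np.ndarray) -> np.ndarray:
    """Unit vector (drow, dcol) along the contact line (principal axis)."""
    pts = contact.astype(float)
    if len(pts) < 2:
        return np.array([1.0, 0.0])
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    norm = np.linalg.norm(direction)
    if norm == 0:
        return np.array([1.0, 0.0])
    return direction / norm


def lesion_metrics(
    seg: LesionSegment,
    cm: ContrastMap,
    roi: RoiSet,
    mm_per_pixel: Optional[float] = None,
) -> LesionSegment:
    """Fill in area, mean contrast and depth for a detected lesion.

    Lesion depth on a 2-D SWIR projection is taken as the maximal extent of
    the segmented component measured perpendicular to the contact line
    (penetration away from the proximal surface), in pixel units
    ``max - min projection + 1`` and converted with ``mm_per_pixel``.  If no
    scale is available the metric stays in pixels and a warning is issued.
    """
    if not seg.detected:
        raise ValueError("lesion_metrics requires a detected lesion")
    coords = np.argwhere(seg.mask).astype(float)
    mean_contrast = float(cm.values[seg.mask].mean())
    along = _contact_direction(roi.contact_roi)
    perp = np.array([-along[1], along[0]])
    proj = coords @ perp
    depth_px = float(proj.max() - proj.min() + 1.0)
    seg.mean_contrast = mean_contrast
    seg.depth_px = depth_px
    if mm_per_pixel is not None and mm_per_pixel > 0:
        seg.depth_mm = depth_px * mm_per_pixel
        seg.area_mm2 = seg.area_px * mm_per_pixel**2
    else:
        warnings.warn(
            "mm_per_pixel unset: depth and area reported in pixels only",
            stacklevel=2,
        )
    return seg


def segment_lesion(
    img: IntensityImage,
    roi: RoiSet,
    threshold: float = DEFAULT_CONTRAST_THRESHOLD,
    connectivity: int = 2,
) -> tuple[ContrastMap, LesionSegment]:
    """Full chain: contrast map -> threshold -> contact selection -> metrics."""
    cm = contrast_map(img, roi)
    seg = select_lesion(threshold_mask(cm, threshold), roi, connectivity)
    if seg.detected:
        seg = lesion_metrics(seg, cm, roi, img.mm_per_pixel)
    return cm, seg


def calibrate_px_to_mm(
    img: IntensityImage, reference_length_mm: float, reference_length_px: float
) -> IntensityImage:
    """Attach a mm-per-pixel scale from a reference target of known length."""
    if not reference_length_mm > 0 or not reference_length_px > 0:
        raise ValueError("reference lengths must be positive")
    return img.with_scale(reference_length_mm / reference_length_px)
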
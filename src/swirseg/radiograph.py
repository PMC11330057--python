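"""Radiographic lesion contrast and SWIR-to-radiograph scale transfer.

Radiographic contrast is ``(I_S - I_L) / I_S`` where ``I_L`` is the mean
intensity over the examiner-drawn lesion area and ``I_S`` the mean over a
sound position directly above or below it (same column band, so the X-ray
path crosses a similar enamel thickness).  Lesions are radiolucent, so true
lesions give positive contrast; a ``polarity`` flag covers inverted
(film-style) intensity conventions.

There is no automatic radiographic lesion detection here: a contrast
threshold separates lesion from sound for SWIR imaging but not for
radiography, so radiographic calls remain examiner-supplied labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .images import IntensityImage, RoiSet

#: Required column overlap between sound and lesion ROIs ("directly
#: above or below" => similar enamel thickness along the beam).
DEFAULT_COLUMN_OVERLAP = 0.8


@dataclass
class RadiographMeasurement:
    i_l: float
    i_s: float
    contrast: float
    lesion_like: bool
    lesion_depth_mm: Optional[float] = None


def radiograph_contrast(
    img: IntensityImage,
    roi: RoiSet,
    polarity: str = "dark_lesion",
    min_column_overlap: float = DEFAULT_COLUMN_OVERLAP,
) -> RadiographMeasurement:
    """Compute radiographic lesion contrast from examiner ROIs.

    ``polarity='dark_lesion'`` (digital convention, lesions radiolucent and
    darker) uses the intensities as stored; ``'bright_lesion'`` flips the
    sign convention by swapping the roles of the two ROI means.
    """
    if roi.lesion_roi is None or len(roi.lesion_roi) == 0:
        raise ValueError("radiograph_contrast requires a lesion ROI")
    i_l = float(img.pixels[roi.lesion_roi[:, 0], roi.lesion_roi[:, 1]].mean())
    i_s = float(img.pixels[roi.sound_region[:, 0], roi.sound_region[:, 1]].mean())
    if polarity == "bright_lesion":
        i_l, i_s = i_s, i_l
    elif polarity != "dark_lesion":
        raise ValueError(f"unknown polarity {polarity!r}")
    if i_s == 0:
        raise ValueError("sound reference intensity is zero")

    lesion_cols = set(roi.lesion_roi[:, 1].tolist())
    sound_cols = set(roi.sound_region[:, 1].tolist())
    overlap = len(lesion_cols & sound_cols) / len(lesion_cols)
    if overlap < min_column_overlap:
        warnings.warn(
            f"sound ROI covers only {overlap:.0%} of the lesion columns; "
            "it should sit directly above or below the lesion "
            "(similar enamel thickness)",
            stacklevel=2,
        )

    contrast = (i_s - i_l) / i_s
    return RadiographMeasurement(
        i_l=i_l, i_s=i_s, contrast=contrast, lesion_like=contrast > 0
    )


def transfer_scale(
    radiograph: IntensityImage,
    swir: IntensityImage,
    span_rad_px: float,
    span_swir_px: float,
) -> IntensityImage:
    """Transfer the mm scale from a calibrated SWIR frame to a radiograph.

    The mesial-to-distal span of the tooth, measured in pixels on both
    images, ties the two scales together:
    ``mm_per_pixel_rad = mm_per_pixel_swir * span_swir_px / span_rad_px``.
    """
    if swir.mm_per_pixel is None:
        raise ValueError("SWIR image has no mm_per_pixel scale set")
    if not span_rad_px > 0 or not span_swir_px > 0:
        raise ValueError("spans must be positive")
    return radiograph.with_scale(swir.mm_per_pixel * span_swir_px / span_rad_px)


def depth_from_segment(
    p1: tuple[float, float], p2: tuple[float, float], mm_per_pixel: float
) -> float:
    """Lesion depth from a two-point segment (enamel surface -> lesion front)."""
    if not mm_per_pixel > 0:
        raise ValueError("mm_per_pixel must be positive")
    d = np.hypot(p2[0] - p1[0], p2[1] - p1[1])
    return float(d * mm_per_pixel)
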
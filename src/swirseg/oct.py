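"""CP-OCT lesion depth via the cylindrical-ruler procedure.

A b-scan is despeckled with a 3x3 median filter, a virtual ruler is dropped
perpendicular to the detected enamel surface, and the intensity along the
ruler is summarized at each step as the mean inside a 100-um-diameter disk
around the ruler axis (in a 2-D b-scan the disk reduces to a transverse
segment of that width).  In sound enamel the signal decays monotonically
with depth apart from birefringence banding; a subsurface lesion produces an
elevated-reflectivity band flanked by two intensity minima.  Lesion depth is
the axial distance between the two lowest local minima of the profile,
divided by the enamel refractive index (default 1.6) to convert the optical
path to physical distance.

A prominence guard — the profile must rise by a stated fraction of its
dynamic range between the two minima — prevents a maximum in one of the
birefringence bands from being mistaken for a lesion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage, signal

from .images import Bscan
from .stats import round_half_up

DEFAULT_MEDIAN_KERNEL = 3
DEFAULT_DISK_DIAMETER_UM = 100.0
DEFAULT_STEP_UM = 10.0
DEFAULT_SMOOTH_WINDOW = 3
#: Minimum rise between the two minima, as a fraction of the profile's
#: dynamic range; relative so depth is invariant to global intensity scaling.
DEFAULT_PROMINENCE = 0.1


@dataclass
class RulerProfile:
    """Axial intensity profile along the ruler (distances in optical mm)."""

    axis_origin: tuple[float, float]  # (row, col) in pixels
    axis_direction: tuple[float, float]  # unit (d_axial, d_lateral) in mm space
    distances_mm: np.ndarray
    intensities: np.ndarray


@dataclass
class DepthMeasurement:
    """Outcome of :func:`measure_depth`; ``detected`` False means no lesion."""

    detected: bool
    depth_mm_physical: Optional[float] = None
    minima_mm_optical: Optional[tuple[float, float]] = None
    minima_intensity: Optional[tuple[float, float]] = None


def despeckle(b: Bscan, kernel: int = DEFAULT_MEDIAN_KERNEL) -> Bscan:
    """Median-filter a b-scan to reduce speckle noise.

    Edge pixels use reduced (clipped) neighborhoods — the median is taken
    over the in-bounds pixels only.  ``kernel=1`` is the identity.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel must be an odd integer >= 1")
    if kernel == 1:
        return replace(b, pixels=b.pixels.copy())
    pad = kernel // 2
    padded = np.pad(b.pixels, pad, constant_values=np.nan)
    windows = sliding_window_view(padded, (kernel, kernel))
    filtered = np.nanmedian(windows.reshape(*b.pixels.shape, -1), axis=-1)
    return replace(b, pixels=filtered)


def detect_surface(
    b: Bscan, lateral_pos: int, rise_fraction: float = 0.5
) -> int:
    """First axial index where the column rises above ``rise_fraction`` of
    its maximum — the enamel surface echo."""
    col = b.pixels[:, lateral_pos]
    peak = col.max()
    if peak <= 0:
        raise ValueError(f"no signal in column {lateral_pos}")
    idx = np.nonzero(col >= rise_fraction * peak)[0]
    if idx.size == 0:
        raise ValueError(f"no surface found in column {lateral_pos}")
    return int(idx[0])


def surface_normal(
    b: Bscan,
    lateral_pos: int,
    window: int = 10,
    rise_fraction: float = 0.5,
) -> np.ndarray:
    """Unit normal to the surface at ``lateral_pos``, pointing into the tissue.

    The surface line is least-squares fit over a +/-``window``-pixel lateral
    neighborhood in millimetre coordinates (axial optical mm vs lateral mm);
    the returned vector is (d_axial, d_lateral) with positive axial component.
    """
    cols = np.arange(
        max(0, lateral_pos - window), min(b.shape[1], lateral_pos + window + 1)
    )
    surf = []
    for c in cols:
        try:
            surf.append((c, detect_surface(b, int(c), rise_fraction)))
        except ValueError:
            continue
    if len(surf) < 2:
        raise ValueError("no surface found in lateral window")
    arr = np.asarray(surf, dtype=float)
    x = arr[:, 0] * b.mm_per_pixel_lateral
    z = arr[:, 1] * b.mm_per_pixel_axial_optical
    slope = np.polyfit(x, z, 1)[0]  # dz/dx
    normal = np.array([1.0, -slope])
    return normal / np.linalg.norm(normal)


def ruler_profile(
    b: Bscan,
    origin: tuple[float, float],
    direction: Optional[np.ndarray] = None,
    disk_diameter_um: float = DEFAULT_DISK_DIAMETER_UM,
    step_um: float = DEFAULT_STEP_UM,
) -> RulerProfile:
    """Sample the mean intensity in a disk marched along the ruler axis.

    ``origin`` is (row, col) in pixels, normally the surface point;
    ``direction`` is a unit (d_axial, d_lateral) vector in mm coordinates
    (default straight down the axial axis).  Samples are taken every
    ``step_um`` of optical path until the axis center exits the image;
    intensities are bilinearly interpolated and averaged over a transverse
    segment of the disk diameter.
    """
    if direction is None:
        direction = np.array([1.0, 0.0])
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if not norm > 0:
        raise ValueError("direction must be non-zero")
    direction = direction / norm
    if direction[0] <= 0:
        raise ValueError("ruler direction must point into the tissue")

    ax, lat = b.mm_per_pixel_axial_optical, b.mm_per_pixel_lateral
    step_mm = step_um / 1000.0
    radius_mm = disk_diameter_um / 2000.0
    z0 = origin[0] * ax
    x0 = origin[1] * lat
    h, w = b.shape

    # steps until the axis center leaves the image
    n_steps = 0
    while True:
        z = z0 + (n_steps + 1) * step_mm * direction[0]
        x = x0 + (n_steps + 1) * step_mm * direction[1]
        if not (0 <= z / ax <= h - 1 and 0 <= x / lat <= w - 1):
            break
        n_steps += 1
    if n_steps == 0:
        raise ValueError("ruler axis immediately exits the image")

    t = np.arange(n_steps + 1) * step_mm
    perp = np.array([-direction[1], direction[0]])
    n_off = max(3, int(round(disk_diameter_um / (min(ax, lat) * 1000.0 / 2.0))) | 1)
    offsets = np.linspace(-radius_mm, radius_mm, n_off)

    z_mm = z0 + t[:, None] * direction[0] + offsets[None, :] * perp[0]
    x_mm = x0 + t[:, None] * direction[1] + offsets[None, :] * perp[1]
    coords = np.stack([z_mm / ax, x_mm / lat])
    samples = ndimage.map_coordinates(
        b.pixels, coords.reshape(2, -1), order=1, mode="nearest"
    ).reshape(n_steps + 1, n_off)
    return RulerProfile(
        axis_origin=tuple(float(v) for v in origin),
        axis_direction=(float(direction[0]), float(direction[1])),
        distances_mm=t,
        intensities=samples.mean(axis=1),
    )


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    pad = window // 2
    padded = np.pad(y.astype(float), pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def measure_depth(
    p: RulerProfile,
    b: Bscan,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    prominence: float = DEFAULT_PROMINENCE,
) -> DepthMeasurement:
    """Lesion depth from the two lowest intensity minima along the ruler.

    The profile is lightly smoothed (moving average, plateau minima resolved
    at their midpoint), local minima are collected, and the two with the
    lowest intensities are taken to flank the lesion.  The measurement is
    rejected ("no lesion") unless the profile rises between them by at least
    ``prominence`` times its dynamic range above both minima — birefringence
    band maxima fail this guard.  The inter-minima optical distance divided
    by the refractive index gives physical depth.
    """
    y = _smooth(p.intensities, smooth_window)
    rng_y = float(y.max() - y.min())
    if rng_y == 0:
        raise ValueError("degenerate (constant) ruler profile")
    minima, _ = signal.find_peaks(-y)  # plateau middles via find_peaks
    if minima.size < 2:
        return DepthMeasurement(detected=False)
    order = np.argsort(y[minima], kind="stable")
    i1, i2 = sorted(minima[order[:2]])
    interior = y[i1 : i2 + 1].max()
    if interior < max(y[i1], y[i2]) + prominence * rng_y:
        return DepthMeasurement(detected=False)
    d1, d2 = p.distances_mm[i1], p.distances_mm[i2]
    depth = float(abs(d2 - d1) / b.refractive_index)
    return DepthMeasurement(
        detected=True,
        depth_mm_physical=depth,
        minima_mm_optical=(float(d1), float(d2)),
        minima_intensity=(float(y[i1]), float(y[i2])),
    )


def measure_bscan_depth(
    b: Bscan,
    lateral_pos: Optional[int] = None,
    kernel: int = DEFAULT_MEDIAN_KERNEL,
    auto_normal: bool = True,
    disk_diameter_um: float = DEFAULT_DISK_DIAMETER_UM,
    step_um: float = DEFAULT_STEP_UM,
    prominence: float = DEFAULT_PROMINENCE,
) -> DepthMeasurement:
    """Convenience chain: despeckle -> surface -> ruler -> depth.

    ``lateral_pos`` defaults to the brightest subsurface column (a cheap
    surrogate for pointing the ruler at the lesion).
    """
    filtered = despeckle(b, kernel)
    if lateral_pos is None:
        surf_guess = int(
            np.median([detect_surface(filtered, c) for c in range(0, b.shape[1], 8)])
        )
        sub = filtered.pixels[surf_guess + 5 :, :]
        sums = sub.sum(axis=0)
        # middle of the near-maximal band, not the raw argmax: at a lesion
        # edge the averaging disk would mix in sound A-lines
        near_max = np.nonzero(sums >= 0.95 * sums.max())[0]
        lateral_pos = int(round(near_max.mean()))
    surf_row = detect_surface(filtered, lateral_pos)
    direction = (
        surface_normal(filtered, lateral_pos) if auto_normal else np.array([1.0, 0.0])
    )
    profile = ruler_profile(
        filtered,
        (surf_row, lateral_pos),
        direction,
        disk_diameter_um=disk_diameter_um,
        step_um=step_um,
    )
    return measure_depth(profile, filtered, prominence=prominence)


def max_physical_range(b: Bscan) -> float:
    """Deepest physical depth the scan can represent, to one decimal (mm).

    The axial scan range is an optical distance in air; inside enamel the
    refractive index compresses it (7 mm in air -> 4.4 mm at n = 1.6).
    """
    return float(
        round_half_up(b.axial_extent_optical_mm / b.refractive_index, 1)
    )
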
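"""Reading and writing of images, ROIs, phantoms and detection tables.

Image I/O is restricted to grayscale TIFF/PNG (8/16-bit) and CSV intensity
matrices.  Floating-point frames in [0, 1] are written as 16-bit TIFF to
preserve contrast resolution around the 0.1 detection threshold.  ROIs and
ground truth travel as JSON sidecars; detection tables as long-format CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage import draw as skdraw

from .images import Bscan, IntensityImage, Modality, RoiSet
from .phantom import GroundTruth, PhantomConfig
from .stats import TABLE_COLUMNS

PathLike = Union[str, Path]


def _normalize(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    return arr.astype(float)


def read_image_array(path: PathLike) -> np.ndarray:
    """Read a grayscale TIFF/PNG/CSV into a float array (ints rescaled to [0,1])."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = iio.imread(path)
    elif suffix == ".csv":
        arr = np.loadtxt(path, delimiter=",", dtype=float)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse accidental RGB
        arr = arr[..., 0]
    return _normalize(arr)


def write_image_array(path: PathLike, arr: np.ndarray) -> None:
    """Write a float [0, 1] array as 16-bit TIFF/PNG, or CSV as-is."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        np.savetxt(path, np.asarray(arr, dtype=float), delimiter=",")
        return
    data = np.clip(np.asarray(arr, dtype=float), 0.0, 1.0)
    encoded = np.round(data * 65535.0).astype(np.uint16)
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, encoded)
    elif suffix == ".png":
        iio.imwrite(path, encoded)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")


def write_mask_png(path: PathLike, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask_png(path: PathLike) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 0


def _roi_entry_to_coords(entry) -> np.ndarray:
    """Decode a JSON ROI entry: pixel list or {'polyline': [...]} vertices."""
    if isinstance(entry, dict) and "polyline" in entry:
        verts = np.asarray(entry["polyline"], dtype=int)
        if len(verts) < 2:
            return verts.reshape(-1, 2)
        pts = []
        for (r0, c0), (r1, c1) in zip(verts[:-1], verts[1:]):
            rr, cc = skdraw.line(int(r0), int(c0), int(r1), int(c1))
            pts.append(np.column_stack([rr, cc]))
        coords = np.vstack(pts)
        # drop duplicated joints
        _, idx = np.unique(coords, axis=0, return_index=True)
        return coords[np.sort(idx)]
    return np.asarray(entry, dtype=int).reshape(-1, 2)


def read_roi(path: PathLike) -> RoiSet:
    with open(path) as fh:
        data = json.load(fh)
    lesion = data.get("lesion_roi")
    return RoiSet(
        sound_region=_roi_entry_to_coords(data["sound_region"]),
        contact_roi=_roi_entry_to_coords(data["contact_roi"]),
        lesion_roi=_roi_entry_to_coords(lesion) if lesion is not None else None,
    )


def write_roi(path: PathLike, roi: RoiSet) -> None:
    data = {
        "sound_region": roi.sound_region.tolist(),
        "contact_roi": roi.contact_roi.tolist(),
    }
    if roi.lesion_roi is not None:
        data["lesion_roi"] = roi.lesion_roi.tolist()
    with open(path, "w") as fh:
        json.dump(data, fh)


def write_phantom(
    out_dir: PathLike,
    stem: str,
    image,
    truth: GroundTruth,
    config: PhantomConfig,
) -> dict[str, Path]:
    """Write a phantom as 16-bit TIFF + mask PNG + JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out_dir / f"{stem}.tif",
        "mask": out_dir / f"{stem}_mask.png",
        "sidecar": out_dir / f"{stem}.json",
    }
    write_image_array(paths["image"], image.pixels)
    write_mask_png(paths["mask"], truth.lesion_mask)
    cfg = dataclasses.asdict(config)
    cfg["modality"] = config.modality.value
    sidecar = {
        "config": cfg,
        "ground_truth": {
            "true_area_px": truth.true_area_px,
            "true_mean_contrast": None
            if np.isnan(truth.true_mean_contrast)
            else truth.true_mean_contrast,
            "true_depth_mm": truth.true_depth_mm,
            "contact_line": truth.contact_line,
        },
    }
    if isinstance(image, Bscan):
        sidecar["bscan"] = {
            "mm_per_pixel_axial_optical": image.mm_per_pixel_axial_optical,
            "mm_per_pixel_lateral": image.mm_per_pixel_lateral,
            "refractive_index": image.refractive_index,
        }
    with open(paths["sidecar"], "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    return paths


def read_bscan(
    path: PathLike,
    header: Optional[PathLike] = None,
    mm_per_pixel_axial_optical: Optional[float] = None,
    mm_per_pixel_lateral: Optional[float] = None,
    refractive_index: float = 1.6,
) -> Bscan:
    """Read a b-scan from TIFF/PNG/CSV plus scales (inline or JSON header)."""
    pixels = read_image_array(path)
    if header is not None:
        with open(header) as fh:
            meta = json.load(fh)
        meta = meta.get("bscan", meta)
        mm_per_pixel_axial_optical = meta["mm_per_pixel_axial_optical"]
        mm_per_pixel_lateral = meta["mm_per_pixel_lateral"]
        refractive_index = meta.get("refractive_index", refractive_index)
    if mm_per_pixel_axial_optical is None or mm_per_pixel_lateral is None:
        raise ValueError("b-scan scales missing: pass a header or explicit scales")
    return Bscan(
        pixels,
        mm_per_pixel_axial_optical=mm_per_pixel_axial_optical,
        mm_per_pixel_lateral=mm_per_pixel_lateral,
        refractive_index=refractive_index,
    )


def read_intensity_image(
    path: PathLike, modality, mm_per_pixel: Optional[float] = None
) -> IntensityImage:
    return IntensityImage(
        read_image_array(path), Modality(modality), mm_per_pixel=mm_per_pixel
    )


def write_detection_table(path: PathLike, table: pd.DataFrame) -> None:
    table = table.reindex(columns=TABLE_COLUMNS)
    table.to_csv(path, index=False)


def read_detection_table(path: PathLike) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"detection table missing columns: {sorted(missing)}")
    # 'detected' round-trips as object with NaN for missing calls
    table["detected"] = table["detected"].map(
        lambda v: v if pd.isna(v) else bool(v) if isinstance(v, (bool, np.bool_)) else str(v) == "True"
    )
    return table
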
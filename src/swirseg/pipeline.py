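"""End-to-end synthetic study: simulate -> segment -> oct-depth -> stats.

``run_all`` generates a full detection study on phantoms: N proximal
contacts, each contributing a restored and an opposing lesion surface,
imaged by every method.  Whether a lesion is *visible* to a given method on
a given surface is drawn from per-method visibility rates (the study's
conditions); visible SWIR lesions get a target contrast from the method's
contrast distribution and are then pushed through the actual segmentation
pipeline, visible OCT lesions get a target depth and are pushed through the
cylindrical-ruler pipeline, and radiograph / visual calls are examiner-style
labels.  The assembled detection table then feeds the statistics layer:
detection rates, Fisher's exact test of each method against radiography on
the opposing surfaces, and repeated-measures ANOVA with compact letter
display for lesion contrast and lesion depth.

Everything is reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .images import IntensityImage, Modality, RoiSet
from .oct import measure_bscan_depth
from .phantom import (
    DEFAULT_SEED,
    MODERATE_SPECKLE_SIGMA,
    PhantomConfig,
    make_oct_phantom,
    make_swir_phantom,
)
from .radiograph import depth_from_segment, radiograph_contrast
from .segmentation import DEFAULT_CONTRAST_THRESHOLD, segment_lesion
from .stats import (
    DEFAULT_ALPHA,
    RmAnovaResult,
    TABLE_COLUMNS,
    compare_measure,
    detection_rates,
    fisher_exact,
    rates_frame,
)

logger = logging.getLogger("swirseg")

SWIR_METHODS = {
    "swir_r": Modality.REFLECTANCE,
    "swir_ot": Modality.OCCLUSAL_TRANS,
    "swir_pt": Modality.PROXIMAL_TRANS,
}

# Per-method, per-surface lesion visibility used as the study's generating
# conditions (restored, opposing).  The radiograph restored entry uses the
# value consistent with the all-surface and opposing-surface rates.
DEFAULT_VISIBILITY = {
    "radiograph": {"restored": 0.86, "opposing": 0.38},
    "oct": {"restored": 0.83, "opposing": 0.76},
    "visual_before": {"restored": 0.10, "opposing": 0.0},
    "visual_after": {"restored": None, "opposing": 0.86},
    "swir_r": {"restored": 0.90, "opposing": 0.93},
    "swir_ot": {"restored": 0.76, "opposing": 0.72},
    "swir_pt": {"restored": 0.93, "opposing": 0.86},
}

# Lesion contrast (mean, SD) per method for visible lesions.
DEFAULT_CONTRAST_DIST = {
    "radiograph": (0.13, 0.064),
    "swir_r": (0.22, 0.063),
    "swir_ot": (0.20, 0.010),
    "swir_pt": (0.27, 0.013),
}

# Lesion depth in um (mean, SD) per method for visible lesions.
DEFAULT_DEPTH_DIST_UM = {
    "radiograph": (851.0, 422.0),
    "oct": (1069.0, 363.0),
    "swir_r": (830.0, 379.0),
    "swir_ot": (1049.0, 514.0),
    "swir_pt": (289.0, 189.0),
}


@dataclass
class PipelineConfig:
    """Study-level configuration; defaults are the printed clinical parameters
    (contrast threshold 0.1, median kernel 3, 100-um disk, n = 1.6,
    alpha = 0.05) plus the phantom-study generating conditions."""

    n_contacts: int = 29
    seed: int = DEFAULT_SEED
    contrast_threshold: float = DEFAULT_CONTRAST_THRESHOLD
    median_kernel: int = 3
    disk_diameter_um: float = 100.0
    refractive_index: float = 1.6
    alpha: float = DEFAULT_ALPHA
    mm_per_pixel: float = 0.03
    oct_speckle_sigma: float = MODERATE_SPECKLE_SIGMA
    visibility: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_VISIBILITY.items()})
    contrast_dist: dict = field(default_factory=lambda: dict(DEFAULT_CONTRAST_DIST))
    depth_dist_um: dict = field(default_factory=lambda: dict(DEFAULT_DEPTH_DIST_UM))
    write_overlays: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        defaults = cls()
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, value in data.items():
            if getattr(defaults, key) != value:
                logger.info("config override: %s = %r", key, value)
        return cls(**data)


@dataclass
class StudyReport:
    table: pd.DataFrame
    rates: pd.DataFrame
    fisher_p: dict[str, float]
    contrast_anova: Optional[RmAnovaResult]
    depth_anova: Optional[RmAnovaResult]
    n_surfaces: int
    out_dir: Optional[Path] = None


def default_swir_rois(cfg: PhantomConfig) -> RoiSet:
    """Standard manual ROIs for a phantom frame: a sound rectangle beside the
    contact (on the side opposite the lesion) and the contact column band."""
    h, w = cfg.image_height, cfg.image_width
    contact = cfg.contact_line
    rows = np.arange(10, h - 10)
    contact_roi = np.column_stack([rows, np.full_like(rows, contact)])
    rr, cc = np.mgrid[10 : h // 3, max(1, contact - 24) : contact - 8]
    sound = np.column_stack([rr.ravel(), cc.ravel()])
    return RoiSet(sound_region=sound, contact_roi=contact_roi)


def _swir_surface_call(
    method: str,
    visible: bool,
    contrast_draw: float,
    depth_draw_um: float,
    cfg_kwargs: dict,
    threshold: float,
    seed: int,
) -> dict:
    modality = SWIR_METHODS[method]
    mmpp = cfg_kwargs.get("mm_per_pixel", 0.03)
    if visible:
        half_cols = max(3, int(round(depth_draw_um / 1000.0 / mmpp)) - 1)
        c_true = float(np.clip(contrast_draw, 0.02, 0.9))
    else:
        half_cols = 6
        c_true = 0.0
    cfg = PhantomConfig(
        modality=modality,
        lesion_contrast_true=c_true,
        lesion_axes=(max(6, 2 * half_cols), half_cols),
        seed=seed,
        **cfg_kwargs,
    )
    frame, _ = make_swir_phantom(cfg)
    roi = default_swir_rois(cfg)
    _, seg = segment_lesion(frame, roi, threshold=threshold)
    return {
        "detected": seg.detected,
        "contrast": seg.mean_contrast if seg.detected else np.nan,
        "depth_um": seg.depth_mm * 1000.0 if seg.detected and seg.depth_mm else np.nan,
        "mask": seg.mask,
    }


def _oct_surface_call(
    visible: bool, depth_draw_mm: float, pc: PipelineConfig, seed: int
) -> dict:
    cfg = PhantomConfig(
        modality=Modality.OCT_BSCAN,
        mm_per_pixel=pc.mm_per_pixel,
        noise_sigma=pc.oct_speckle_sigma,
        oct_lesion_depth_true=depth_draw_mm if visible else None,
        refractive_index=pc.refractive_index,
        seed=seed,
    )
    scan, _ = make_oct_phantom(cfg)
    result = measure_bscan_depth(
        scan, kernel=pc.median_kernel, disk_diameter_um=pc.disk_diameter_um
    )
    return {
        "detected": result.detected,
        "contrast": np.nan,
        "depth_um": result.depth_mm_physical * 1000.0 if result.detected else np.nan,
    }


def _radiograph_surface_call(
    visible: bool, contrast_draw: float, depth_draw_um: float, mmpp: float
) -> dict:
    if not visible:
        return {"detected": False, "contrast": np.nan, "depth_um": np.nan}
    c = float(np.clip(contrast_draw, 0.02, 0.6))
    h, w = 96, 128
    img = np.full((h, w), 0.7)
    rr, cc = np.mgrid[0:h, 0:w]
    lesion = ((rr - 60) / 10.0) ** 2 + ((cc - 64) / 14.0) ** 2 <= 1.0
    img[lesion] = 0.7 * (1.0 - c)
    lesion_coords = np.argwhere(lesion)
    cols = np.unique(lesion_coords[:, 1])
    sr, sc = np.mgrid[20:35, cols.min() : cols.max() + 1]
    roi = RoiSet(
        sound_region=np.column_stack([sr.ravel(), sc.ravel()]),
        contact_roi=np.column_stack([np.arange(40, 80), np.full(40, 2)]),
        lesion_roi=lesion_coords,
    )
    meas = radiograph_contrast(IntensityImage(img, Modality.RADIOGRAPH), roi)
    depth_px = max(1.0, depth_draw_um / 1000.0 / mmpp)
    depth_mm = depth_from_segment((0.0, 0.0), (depth_px, 0.0), mmpp)
    return {"detected": True, "contrast": meas.contrast, "depth_um": depth_mm * 1000.0}


def simulate_study(pc: PipelineConfig, overlay_dir=None) -> pd.DataFrame:
    """Build the long-format detection table for the whole synthetic study.

    With ``overlay_dir`` set, the segmented lesion mask of every SWIR frame
    is written there as a PNG overlay.
    """
    if overlay_dir is not None:
        overlay_dir = Path(overlay_dir)
        overlay_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(pc.seed)
    rows = []
    swir_kwargs = {"mm_per_pixel": pc.mm_per_pixel}
    max_depth_mm = 7.0 / pc.refractive_index - 1.0
    for contact in range(1, pc.n_contacts + 1):
        for surface in ("restored", "opposing"):
            for method, per_surface in pc.visibility.items():
                rate = per_surface[surface]
                if rate is None:
                    rows.append((contact, surface, method, np.nan, np.nan, np.nan))
                    continue
                visible = bool(rng.random() < rate)
                seed = int(rng.integers(2**31 - 1))
                if method in SWIR_METHODS:
                    mu, sd = pc.contrast_dist[method]
                    dmu, dsd = pc.depth_dist_um[method]
                    call = _swir_surface_call(
                        method,
                        visible,
                        rng.normal(mu, sd),
                        float(np.clip(rng.normal(dmu, dsd), 150.0, 3000.0)),
                        swir_kwargs,
                        pc.contrast_threshold,
                        seed,
                    )
                    mask = call.pop("mask", None)
                    if overlay_dir is not None and mask is not None:
                        sio.write_mask_png(
                            overlay_dir / f"c{contact:02d}_{surface}_{method}.png",
                            mask,
                        )
                elif method == "oct":
                    dmu, dsd = pc.depth_dist_um[method]
                    depth = float(
                        np.clip(rng.normal(dmu, dsd) / 1000.0, 0.3, max_depth_mm)
                    )
                    call = _oct_surface_call(visible, depth, pc, seed)
                elif method == "radiograph":
                    mu, sd = pc.contrast_dist[method]
                    dmu, dsd = pc.depth_dist_um[method]
                    call = _radiograph_surface_call(
                        visible,
                        rng.normal(mu, sd),
                        float(np.clip(rng.normal(dmu, dsd), 100.0, 3000.0)),
                        pc.mm_per_pixel,
                    )
                else:  # visual examination: label only
                    call = {
                        "detected": visible,
                        "contrast": np.nan,
                        "depth_um": np.nan,
                    }
                rows.append(
                    (
                        contact,
                        surface,
                        method,
                        call["detected"],
                        call["contrast"],
                        call["depth_um"],
                    )
                )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def run_all(pc: PipelineConfig, out_dir=None) -> StudyReport:
    """Run the full synthetic study and optionally write the report bundle."""
    overlay_dir = (
        Path(out_dir) / "overlays" if out_dir is not None and pc.write_overlays else None
    )
    table = simulate_study(pc, overlay_dir=overlay_dir)
    rates = rates_frame(table)
    n_surfaces = table.groupby(["contact_id", "surface"]).ngroups

    summaries = {r.method: r for r in detection_rates(table) if r.group == "opposing"}
    fisher_p: dict[str, float] = {}
    rad = summaries.get("radiograph")
    if rad is not None:
        for method, summ in summaries.items():
            if method == "radiograph":
                continue
            fisher_p[method] = fisher_exact(
                summ.k_detected, summ.n, rad.k_detected, rad.n
            )

    def _try_compare(measure, methods):
        try:
            return compare_measure(table, measure, methods, alpha=pc.alpha)
        except ValueError as exc:
            logger.warning("%s comparison skipped: %s", measure, exc)
            return None

    contrast_anova = _try_compare(
        "contrast", ["radiograph", "swir_r", "swir_ot", "swir_pt"]
    )
    depth_anova = _try_compare(
        "depth_um", ["radiograph", "oct", "swir_r", "swir_ot", "swir_pt"]
    )

    report = StudyReport(
        table=table,
        rates=rates,
        fisher_p=fisher_p,
        contrast_anova=contrast_anova,
        depth_anova=depth_anova,
        n_surfaces=n_surfaces,
    )
    if out_dir is not None:
        report.out_dir = _write_report(report, pc, Path(out_dir))
    return report


def simulate_letter_pattern_recovery(
    n_replicates: int = 500,
    means: tuple[float, ...] = (0.13, 0.22, 0.20, 0.27),
    sigma: float = 0.03,
    n_subjects: int = 26,
    subject_sigma: float = 0.05,
    target: tuple[str, ...] = ("a", "b", "b", "c"),
    alpha: float = DEFAULT_ALPHA,
    seed: int = DEFAULT_SEED,
) -> float:
    """Fraction of replicate studies whose compact letter display matches
    ``target``.

    Each replicate draws ``n_subjects`` complete cases of per-method lesion
    contrast (method means plus a shared subject effect plus within-subject
    noise of SD ``sigma``) and runs the repeated-measures ANOVA with Tukey
    pairwise comparisons.  Used to ask how often a study under these
    conditions reproduces a published letter grouping.
    """
    from .stats import rm_anova

    rng = np.random.default_rng(seed)
    mu = np.asarray(means, dtype=float)
    hits = 0
    for _ in range(n_replicates):
        subj = rng.normal(0.0, subject_sigma, size=(n_subjects, 1))
        y = mu + subj + rng.normal(0.0, sigma, size=(n_subjects, mu.size))
        res = rm_anova(y, alpha=alpha, correction="tukey", compute_p=False)
        letters = tuple(res.letters[m] for m in res.methods)
        hits += letters == tuple(target)
    return hits / n_replicates


def _anova_summary(res: Optional[RmAnovaResult]) -> Optional[dict]:
    if res is None:
        return None
    return {
        "methods": res.methods,
        "n_complete": res.n,
        "means": [float(m) for m in res.means],
        "f_stat": res.f_stat,
        "p_value": res.p_value,
        "letters": res.letters,
        "correction": res.correction,
    }


def _write_report(report: StudyReport, pc: PipelineConfig, out_dir: Path) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    sio.write_detection_table(out_dir / "detection_table.csv", report.table)
    report.rates.to_csv(out_dir / "rates.csv", index=False)
    summary = {
        "n_contacts": pc.n_contacts,
        "n_surfaces": report.n_surfaces,
        "seed": pc.seed,
        "rates": report.rates.to_dict(orient="records"),
        "fisher_p_vs_radiograph_opposing": report.fisher_p,
        "contrast_anova": _anova_summary(report.contrast_anova),
        "depth_anova": _anova_summary(report.depth_anova),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return out_dir
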
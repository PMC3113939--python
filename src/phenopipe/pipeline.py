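"""Batch orchestration: discover images, analyse each, emit results.

One analysis run walks a directory of plant photographs whose file
names encode plant id, view and time point, applies the per-view
calibration to each image (segment -> extract plant -> opening ->
measure), and writes a CSV result table plus, optionally, annotated
images and per-image processing stacks.  Failures are collected and
reported, never silently dropped, and a rerun over identical inputs
reproduces the CSV byte for byte (fixed column order, fixed float
formatting, no timestamps).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import __version__
from .annotate import AnnotationStyle, build_stack, render_annotation
from .calibration import ViewConfig
from .measurement import MeasurementRecord, measure
from .regions import rasterize, scale_region
from .segmentation import extract_plant, opening, render_label_image, segment_image

__all__ = [
    "ImageJob",
    "ResultTable",
    "BatchResult",
    "discover_jobs",
    "run_batch",
    "write_result_table",
]

log = logging.getLogger("phenopipe")

#: Fixed column order of the result table.
TABLE_COLUMNS = (
    "plant_id",
    "view",
    "timepoint",
    "x_extent_mm",
    "y_extent_mm",
    "diameter_mm",
    "width_mm",
    "height_mm",
    "projected_shoot_area_mm2",
    "pixel_count",
    "empty_flag",
    "source_path",
    "config_id",
    "software_version",
)

_FIELD_PATTERNS = {
    "plant_id": r"(?P<plant_id>[A-Za-z0-9.-]+)",
    "view": r"(?P<view>top|side)",
    "timepoint": r"(?P<timepoint>[A-Za-z0-9.-]+)",
}


@dataclass(frozen=True)
class ImageJob:
    """One image to analyse, with its identity metadata."""

    path: Path
    plant_id: str
    view: str
    timepoint: str

    def __post_init__(self) -> None:
        if self.view not in ("top", "side"):
            raise ValueError("view must be 'top' or 'side'")
        if not self.plant_id or not self.timepoint:
            raise ValueError("plant_id and timepoint must be non-empty")
        object.__setattr__(self, "path", Path(self.path))


@dataclass
class ResultTable:
    """Ordered measurement records with provenance columns."""

    records: List[MeasurementRecord] = field(default_factory=list)
    provenance: List[Dict[str, str]] = field(default_factory=list)

    def append(self, rec: MeasurementRecord, source_path: str, config_id: str) -> None:
        self.records.append(rec)
        self.provenance.append(
            {
                "source_path": source_path,
                "config_id": config_id,
                "software_version": __version__,
            }
        )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class BatchResult:
    table: ResultTable
    failures: List[Tuple[ImageJob, str]]

    @property
    def ok(self) -> bool:
        return not self.failures


def template_to_regex(pattern: str) -> "re.Pattern[str]":
    """Compile a filename template such as ``{plant_id}_{view}_d{timepoint}.png``
    into a regular expression with named groups."""
    out = []
    pos = 0
    for m in re.finditer(r"\{(plant_id|view|timepoint)\}", pattern):
        out.append(re.escape(pattern[pos : m.start()]))
        out.append(_FIELD_PATTERNS[m.group(1)])
        pos = m.end()
    out.append(re.escape(pattern[pos:]))
    rx = "".join(out)
    for fieldname in ("plant_id", "view", "timepoint"):
        if f"(?P<{fieldname}>" not in rx:
            raise ValueError(f"pattern must contain {{{fieldname}}}")
    return re.compile("^" + rx + "$")


def discover_jobs(root, pattern: str = "{plant_id}_{view}_d{timepoint}.png") -> List[ImageJob]:
    """Scan a directory for analysable images.

    Files are matched against the template in lexicographic order;
    non-matching files are skipped with a logged warning.
    """
    root = Path(root)
    if not root.is_dir():
        raise IOError(f"not a readable directory: {root}")
    rx = template_to_regex(pattern)
    image_exts = (".png", ".tif", ".tiff", ".jpg", ".jpeg")
    jobs = []
    for p in sorted(root.iterdir()):
        if not p.is_file() or p.suffix.lower() not in image_exts:
            continue
        m = rx.match(p.name)
        if m is None:
            log.warning("skipping %s: does not match pattern %r", p.name, pattern)
            continue
        jobs.append(ImageJob(path=p, **m.groupdict()))
    return jobs


def _load_rgb(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[-1] == 4:  # drop alpha
        img = img[..., :3]
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"{path}: not an RGB image")
    return img.astype(np.uint8)


def analyse_image(
    img: np.ndarray,
    cfg: ViewConfig,
    plant_id: str,
    timepoint: str,
) -> Tuple[MeasurementRecord, np.ndarray, "np.ndarray"]:
    """Run the per-image pipeline; returns (record, plant mask, label image)."""
    label_image = segment_image(img, cfg)
    raw = extract_plant(label_image)
    mask = opening(raw, cfg.opening_radius)
    rec = measure(mask, cfg, plant_id, timepoint)
    return rec, mask, label_image


def _regions_overlay(img: np.ndarray, cfg: ViewConfig) -> np.ndarray:
    from scipy import ndimage

    out = img.copy()
    h, w = img.shape[:2]
    for reg in cfg.regions:
        m = rasterize(scale_region(reg, cfg.region_scale), w, h)
        edge = m & ~ndimage.binary_erosion(m, np.ones((3, 3), bool), border_value=0)
        out[edge] = (255, 255, 255)
    return out


def run_batch(
    jobs: Sequence[ImageJob],
    configs: Dict[str, ViewConfig],
    out_dir,
    stacks: bool = False,
    annotate: bool = False,
    style: Optional[AnnotationStyle] = None,
) -> BatchResult:
    """Analyse every job; one table row per success, failures collected.

    ``configs`` maps view name to its calibration and must cover every
    job's view (checked up front).  Jobs are independent; processing
    order follows the input order.
    """
    import imageio.v3 as iio

    missing = sorted({j.view for j in jobs} - set(configs))
    if missing:
        raise ValueError(f"no configuration for view(s): {', '.join(missing)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    style = style or AnnotationStyle()
    table = ResultTable()
    failures: List[Tuple[ImageJob, str]] = []
    for job in jobs:
        cfg = configs[job.view]
        try:
            img = _load_rgb(job.path)
            rec, mask, label_image = analyse_image(img, cfg, job.plant_id, job.timepoint)
            stem = f"{job.plant_id}_{job.view}_{job.timepoint}"
            if annotate or stacks:
                annotated = render_annotation(img, mask, rec, style, cfg.mm_per_px)
                if annotate:
                    iio.imwrite(out / f"{stem}_annotated.png", annotated)
                if stacks:
                    stages = [
                        img,
                        _regions_overlay(img, cfg),
                        render_label_image(label_image, cfg),
                        extract_plant(label_image),
                        mask,
                        annotated,
                    ]
                    build_stack(stages, out / f"{stem}_stack.tiff")
            table.append(rec, source_path=str(job.path), config_id=cfg.config_id)
        except Exception as exc:  # noqa: BLE001 — batch must not abort
            log.error("failed to process %s: %s", job.path, exc)
            failures.append((job, str(exc)))
    return BatchResult(table=table, failures=failures)


def _fmt_len(v: Optional[float]) -> str:
    return "" if v is None else f"{v:.2f}"


def write_result_table(table: ResultTable, path) -> None:
    """Write the result table as UTF-8 CSV with a fixed column order.

    Lengths carry two decimals (mm), areas one decimal (mm^2); fields
    of the other view are left empty.
    """
    lines = [",".join(TABLE_COLUMNS)]
    for rec, prov in zip(table.records, table.provenance):
        lines.append(
            ",".join(
                [
                    rec.plant_id,
                    rec.view,
                    rec.timepoint,
                    _fmt_len(rec.x_extent_mm),
                    _fmt_len(rec.y_extent_mm),
                    _fmt_len(rec.diameter_mm),
                    _fmt_len(rec.width_mm),
                    _fmt_len(rec.height_mm),
                    f"{rec.projected_shoot_area_mm2:.1f}",
                    str(rec.pixel_count),
                    "true" if rec.empty_flag else "false",
                    prov["source_path"],
                    prov["config_id"],
                    prov["software_version"],
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
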
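"""Phenotypic parameters computed from the refined plant mask.

Top view yields x-extent, y-extent and the plant diameter; side view
yields width and height; both views yield the projected shoot area —
the plant pixel count converted to mm^2, a 2-D proxy for shoot biomass.

Conventions: extents use the inclusive pixel-count rule
(``max - min + 1``; a single pixel is one pixel wide), the diameter is
the maximum Feret diameter — the largest Euclidean distance between any
two plant-pixel centres — and all measurements are taken after the
morphological opening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .calibration import ViewConfig

__all__ = [
    "MeasurementRecord",
    "extents",
    "width_height",
    "max_diameter",
    "feret_endpoints",
    "projected_area",
    "measure",
    "summarize_groups",
]


@dataclass(frozen=True)
class MeasurementRecord:
    """One image's phenotypic parameters, already converted to millimetres.

    Top-view records populate ``x_extent_mm``/``y_extent_mm``/
    ``diameter_mm``; side-view records populate ``width_mm``/
    ``height_mm``; fields of the other view are ``None``.  An image in
    which no plant pixel survives the cleanup carries ``empty_flag`` and
    zeros throughout.
    """

    plant_id: str
    view: str
    timepoint: str
    projected_shoot_area_mm2: float
    pixel_count: int
    empty_flag: bool
    x_extent_mm: Optional[float] = None
    y_extent_mm: Optional[float] = None
    diameter_mm: Optional[float] = None
    width_mm: Optional[float] = None
    height_mm: Optional[float] = None


def extents(mask: np.ndarray) -> Tuple[int, int]:
    """Inclusive bounding-box extents ``(x_extent_px, y_extent_px)``.

    ``(0, 0)`` for an empty mask.
    """
    mask = np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        return 0, 0
    return int(cols[-1] - cols[0] + 1), int(rows[-1] - rows[0] + 1)


def width_height(mask: np.ndarray) -> Tuple[int, int]:
    """Side-view width (horizontal) and height (vertical) in pixels."""
    return extents(mask)


def _plant_points(mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    return np.column_stack([xs, ys]).astype(np.float64)


def feret_endpoints(mask: np.ndarray) -> Optional[Tuple[Tuple[int, int], Tuple[int, int]]]:
    """Pixel-centre pair ``((x1, y1), (x2, y2))`` realising the maximum
    Feret diameter, or ``None`` for masks with fewer than two pixels."""
    pts = _plant_points(mask)
    if len(pts) < 2:
        return None
    cand = pts
    if len(pts) > 3:
        try:
            cand = pts[ConvexHull(pts).vertices]
        except QhullError:
            # Degenerate (collinear) point sets: extremes along the line.
            d = pts - pts.mean(axis=0)
            proj = d @ d[np.argmax(np.linalg.norm(d, axis=1))]
            cand = pts[[int(np.argmin(proj)), int(np.argmax(proj))]]
    diff = cand[:, None, :] - cand[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    p1 = (int(cand[i, 0]), int(cand[i, 1]))
    p2 = (int(cand[j, 0]), int(cand[j, 1]))
    return p1, p2


def max_diameter(mask: np.ndarray) -> float:
    """Maximum Feret diameter in pixels (0 for empty or single-pixel masks).

    The maximum pairwise distance between pixel centres is attained on
    the convex hull, so the hull is computed first and the pairwise
    maximum taken over its vertices.
    """
    ends = feret_endpoints(mask)
    if ends is None:
        return 0.0
    (x1, y1), (x2, y2) = ends
    return float(np.hypot(x2 - x1, y2 - y1))


def projected_area(mask: np.ndarray, mm_per_px: float) -> float:
    """Projected shoot area in mm^2: pixel count times ``mm_per_px`` squared."""
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    return float(np.count_nonzero(np.asarray(mask, dtype=bool))) * mm_per_px**2


def measure(
    mask: np.ndarray,
    cfg: ViewConfig,
    plant_id: str,
    timepoint: str,
) -> MeasurementRecord:
    """Compute the view-appropriate parameter set from a plant mask."""
    mask = np.asarray(mask, dtype=bool)
    count = int(np.count_nonzero(mask))
    f = cfg.mm_per_px
    if count == 0:
        zeros = dict.fromkeys(
            ("x_extent_mm", "y_extent_mm", "diameter_mm")
            if cfg.view == "top"
            else ("width_mm", "height_mm"),
            0.0,
        )
        return MeasurementRecord(
            plant_id=plant_id,
            view=cfg.view,
            timepoint=timepoint,
            projected_shoot_area_mm2=0.0,
            pixel_count=0,
            empty_flag=True,
            **zeros,
        )
    ex, ey = extents(mask)
    area = projected_area(mask, f)
    if cfg.view == "top":
        return MeasurementRecord(
            plant_id=plant_id,
            view="top",
            timepoint=timepoint,
            projected_shoot_area_mm2=area,
            pixel_count=count,
            empty_flag=False,
            x_extent_mm=ex * f,
            y_extent_mm=ey * f,
            diameter_mm=max_diameter(mask) * f,
        )
    return MeasurementRecord(
        plant_id=plant_id,
        view="side",
        timepoint=timepoint,
        projected_shoot_area_mm2=area,
        pixel_count=count,
        empty_flag=False,
        width_mm=ex * f,
        height_mm=ey * f,
    )


def summarize_groups(
    records: Iterable[MeasurementRecord],
    groups: Dict[str, str],
) -> pd.DataFrame:
    """Per-group, per-timepoint mean ± standard error of projected shoot area.

    ``groups`` maps each ``plant_id`` to its group label (e.g.
    ``"Morex/well-watered"``).  The standard error is the sample
    (``n - 1``) standard deviation over ``sqrt(n)``; groups with a
    single replicate at a timepoint report ``SE = 0`` with a warning.

    Returns a DataFrame with columns ``group``, ``timepoint``, ``n``,
    ``mean_area_mm2`` and ``se_area_mm2``, sorted by group then
    timepoint.
    """
    rows = []
    for rec in records:
        if rec.plant_id not in groups:
            raise KeyError(f"no group label for plant {rec.plant_id!r}")
        rows.append(
            {
                "group": groups[rec.plant_id],
                "timepoint": rec.timepoint,
                "area": rec.projected_shoot_area_mm2,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["group", "timepoint", "n", "mean_area_mm2", "se_area_mm2"])
    df = pd.DataFrame(rows)
    out = []
    for (group, tp), sub in df.groupby(["group", "timepoint"], sort=True):
        n = len(sub)
        mean = float(sub["area"].mean())
        if n == 1:
            warnings.warn(
                f"group {group!r} at timepoint {tp!r} has a single replicate; SE set to 0",
                stacklevel=2,
            )
            se = 0.0
        else:
            se = float(sub["area"].std(ddof=1) / np.sqrt(n))
        out.append(
            {"group": group, "timepoint": tp, "n": n, "mean_area_mm2": mean, "se_area_mm2": se}
        )
    return pd.DataFrame(out)
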
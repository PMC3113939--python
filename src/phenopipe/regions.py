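"""Image regions that confine where non-plant object classes may occur.

Greenhouse imaging rigs keep the camera and the scene furniture (pot
carrier, support cages, sticks, conveyor belt, soil surface) in fixed
positions, so each such object can only appear inside a known part of
the frame.  Restricting a class's colour thresholds to its region is
what prevents, e.g., a green-tinted cage reflection from being counted
as plant.  The plant itself carries no region — leaves can reach
anywhere in the image.

Coordinates are 0-based pixel coordinates, ``x`` = column, ``y`` = row,
origin at the top-left.  A pixel belongs to a region iff its integer
centre coordinate satisfies the closed region inequality.  Regions are
scaled about their centroid (they "grow and shrink" in place when the
camera zoom changes) and may extend beyond the frame; rasterization
clips them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import math
import numpy as np

__all__ = ["Region", "scale_region", "rasterize"]

_SHAPES = ("rectangle", "circle")


@dataclass(frozen=True)
class Region:
    """A named rectangle ``(x0, y0, x1, y1)`` or circle ``(cx, cy, radius)``."""

    name: str
    shape: str
    geometry: Tuple[float, ...]

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown region shape {self.shape!r}")
        geom = tuple(float(g) for g in self.geometry)
        object.__setattr__(self, "geometry", geom)
        if self.shape == "rectangle":
            if len(geom) != 4:
                raise ValueError("rectangle geometry is (x0, y0, x1, y1)")
            x0, y0, x1, y1 = geom
            if x0 > x1 or y0 > y1:
                raise ValueError("rectangle requires x0 <= x1 and y0 <= y1")
        else:
            if len(geom) != 3:
                raise ValueError("circle geometry is (cx, cy, radius)")
            if geom[2] <= 0:
                raise ValueError("circle radius must be positive")

    @property
    def centroid(self) -> Tuple[float, float]:
        if self.shape == "rectangle":
            x0, y0, x1, y1 = self.geometry
            return (x0 + x1) / 2.0, (y0 + y1) / 2.0
        cx, cy, _ = self.geometry
        return cx, cy


def scale_region(region: Region, factor: float) -> Region:
    """Scale a region about its centroid by ``factor`` (> 0)."""
    if factor <= 0:
        raise ValueError("scaling factor must be positive")
    if region.shape == "rectangle":
        x0, y0, x1, y1 = region.geometry
        cx, cy = region.centroid
        hw = (x1 - x0) / 2.0 * factor
        hh = (y1 - y0) / 2.0 * factor
        return Region(region.name, "rectangle", (cx - hw, cy - hh, cx + hw, cy + hh))
    cx, cy, r = region.geometry
    return Region(region.name, "circle", (cx, cy, r * factor))


def rasterize(region: Region, width: int, height: int) -> np.ndarray:
    """Boolean mask of shape ``(height, width)``: pixel centres inside the region.

    Rectangle: ``x0 <= x <= x1 and y0 <= y <= y1``; circle:
    ``(x - cx)^2 + (y - cy)^2 <= radius^2``.  Geometry outside the frame
    is clipped; a region fully outside yields an all-false mask.
    """
    if width <= 0 or height <= 0:
        raise ValueError("image dimensions must be positive")
    mask = np.zeros((height, width), dtype=bool)
    if region.shape == "rectangle":
        x0, y0, x1, y1 = region.geometry
        c0 = max(0, math.ceil(x0))
        c1 = min(width - 1, math.floor(x1))
        r0 = max(0, math.ceil(y0))
        r1 = min(height - 1, math.floor(y1))
        if c0 <= c1 and r0 <= r1:
            mask[r0 : r1 + 1, c0 : c1 + 1] = True
        return mask
    cx, cy, rad = region.geometry
    yy, xx = np.ogrid[:height, :width]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= rad**2
    return mask
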
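"""Visual analysis output: outline, extent/diameter overlays, scale bar, stacks.

Every processing stage of a plant image can be inspected visually: the
annotated result shows the plant outline (red by default), the
bounding-box extent lines (light green) and — in top view — the maximal
diameter chord (orange), plus a horizontal scale bar (100 mm by
default) anchored at the bottom-right so the physical plant size can be
judged at a glance.  All stages of one image are bundled into a
multi-page TIFF stack for side-by-side comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .measurement import MeasurementRecord, feret_endpoints

__all__ = ["AnnotationStyle", "trace_outline", "render_annotation", "build_stack"]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class AnnotationStyle:
    """Colours and geometry of the annotation overlay.

    ``scale_bar_mm=None`` suppresses the scale bar entirely.
    """

    outline_colour: Tuple[int, int, int] = (255, 0, 0)
    extent_colour: Tuple[int, int, int] = (144, 238, 144)
    diameter_colour: Tuple[int, int, int] = (255, 165, 0)
    scale_bar_colour: Tuple[int, int, int] = (255, 255, 255)
    scale_bar_mm: Optional[float] = 100.0
    line_width: int = 1

    def __post_init__(self) -> None:
        if self.scale_bar_mm is not None and self.scale_bar_mm <= 0:
            raise ValueError("scale_bar_mm must be positive (or None for no bar)")
        if self.line_width < 1:
            raise ValueError("line_width must be at least 1")


def trace_outline(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of a mask: true pixels with a false (or out-of-frame)
    4-neighbour."""
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)
    return mask & ~interior


def _thicken(overlay: np.ndarray, line_width: int) -> np.ndarray:
    if line_width <= 1:
        return overlay
    r = (line_width - 1 + 1) // 2
    return ndimage.binary_dilation(overlay, structure=np.ones((2 * r + 1, 2 * r + 1), bool))


def _line_mask(shape, p1, p2) -> np.ndarray:
    from skimage.draw import line

    rr, cc = line(p1[1], p1[0], p2[1], p2[0])
    m = np.zeros(shape, dtype=bool)
    keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    m[rr[keep], cc[keep]] = True
    return m


def _bbox_edges(mask: np.ndarray) -> np.ndarray:
    """Edges of the plant bounding box (the extent lines)."""
    edges = np.zeros(mask.shape, dtype=bool)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return edges
    r0, r1 = ys.min(), ys.max()
    c0, c1 = xs.min(), xs.max()
    edges[r0, c0 : c1 + 1] = True
    edges[r1, c0 : c1 + 1] = True
    edges[r0 : r1 + 1, c0] = True
    edges[r0 : r1 + 1, c1] = True
    return edges


def render_annotation(
    img: np.ndarray,
    mask: np.ndarray,
    rec: MeasurementRecord,
    style: AnnotationStyle,
    mm_per_px: float,
) -> np.ndarray:
    """Overlay outline, extent lines, diameter chord and scale bar on a copy
    of the original image.

    The scale bar is ``round(scale_bar_mm / mm_per_px)`` pixels long,
    ``line_width`` pixels thick, inset 10 px from the bottom-right
    corner; a bar wider than the image is clipped with a warning.
    Output dimensions always equal the input's.
    """
    img = np.asarray(img)
    mask = np.asarray(mask, dtype=bool)
    if img.shape[:2] != mask.shape:
        raise ValueError("image and mask dimensions differ")
    out = img.copy()
    lw = style.line_width

    if mask.any():
        out[_thicken(_bbox_edges(mask), lw)] = style.extent_colour
        if rec.view == "top":
            ends = feret_endpoints(mask)
            if ends is not None:
                out[_thicken(_line_mask(mask.shape, *ends), lw)] = style.diameter_colour
        out[_thicken(trace_outline(mask), lw)] = style.outline_colour

    if style.scale_bar_mm is not None:
        h, w = mask.shape
        bar_len = int(round(style.scale_bar_mm / mm_per_px))
        margin = 10
        x1 = w - margin
        x0 = x1 - bar_len
        if x0 < 0:
            warnings.warn("scale bar longer than image width; drawing clipped", stacklevel=2)
            x0 = 0
        y1 = h - margin
        y0 = max(0, y1 - lw)
        out[y0:y1, max(0, x0) : x1] = style.scale_bar_colour
    return out


def build_stack(stages: Sequence[np.ndarray], path) -> None:
    """Write the ordered processing stages of one image as a stack.

    ``path`` ending in ``.tif``/``.tiff`` produces one multi-page TIFF;
    any other path is treated as a directory receiving a numbered PNG
    series (``stage_00.png``, ``stage_01.png``, ...).  All stages must
    share dimensions; stage order is original, regions overlay, label
    map, extracted plant, opened plant, annotated result.
    """
    if not stages:
        raise ValueError("need at least one stage image")
    shape = np.asarray(stages[0]).shape[:2]
    pages = []
    for s in stages:
        arr = np.asarray(s)
        if arr.shape[:2] != shape:
            raise ValueError("all stages must share dimensions")
        if arr.ndim == 2:  # binary / grey stages rendered as RGB for uniform pages
            arr = np.stack([arr.astype(np.uint8) * 255] * 3, axis=-1)
        pages.append(arr.astype(np.uint8))
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, np.stack(pages), photometric="rgb")
    else:
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        for i, page in enumerate(pages):
            iio.imwrite(path / f"stage_{i:02d}.png", page)
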
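"""Pixel classification (MHT), plant extraction and morphological cleanup.

Multidimensional histogram thresholding is purely per-pixel: a pixel
belongs to a class iff all six of its channel values (R, G, B and the
derived H, S, V) lie inside one of the class's threshold boxes, and —
for region-bound classes — the pixel sits inside the class's scaled
region.  No neighbourhood information is used.  Classes are tested in
declaration order and the first match wins; unmatched pixels are
``background``.

The extracted plant mask is then cleaned with a morphological opening
(erosion followed by dilation with the same square structuring
element), which removes misclassified specks smaller than the element
while preserving the plant silhouette.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .calibration import BACKGROUND, ViewConfig
from .colorspace import rgb_to_hsv
from .regions import rasterize, scale_region

__all__ = [
    "LabelImage",
    "region_masks",
    "classify_pixel",
    "segment_image",
    "extract_plant",
    "erode",
    "dilate",
    "opening",
    "render_label_image",
]


@dataclass(frozen=True)
class LabelImage:
    """Per-pixel class assignment.

    ``labels`` holds small integers indexing into ``names``;
    ``names[0]`` is always ``"background"`` and the remaining entries
    follow the view configuration's class order.
    """

    labels: np.ndarray
    names: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if self.names[0] != BACKGROUND:
            raise ValueError("names[0] must be 'background'")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.labels.shape

    def mask_for(self, name: str) -> np.ndarray:
        """Boolean mask of the pixels carrying class ``name``."""
        return self.labels == self.names.index(name)

    def name_at(self, x: int, y: int) -> str:
        return self.names[int(self.labels[y, x])]


def region_masks(cfg: ViewConfig, width: int, height: int) -> Dict[str, np.ndarray]:
    """Rasterize every region of ``cfg`` once, after applying region_scale."""
    return {
        r.name: rasterize(scale_region(r, cfg.region_scale), width, height)
        for r in cfg.regions
    }


def classify_pixel(
    rgb: Sequence[int],
    position: Tuple[int, int],
    cfg: ViewConfig,
    masks: Optional[Dict[str, np.ndarray]] = None,
) -> str:
    """Classify one pixel; ``position`` is ``(x, y)``.

    Reference scalar implementation of the MHT rule; ``segment_image``
    is the vectorized equivalent.  ``masks`` are precomputed
    rasterizations from :func:`region_masks` (without them, region-bound
    classes are skipped only if the region cannot be resolved).
    """
    x, y = position
    hsv = rgb_to_hsv(np.asarray(rgb, dtype=np.int64))
    for cls in cfg.classes:
        if cls.region_name is not None:
            if masks is None or cls.region_name not in masks:
                raise KeyError(f"no rasterized region {cls.region_name!r} supplied")
            m = masks[cls.region_name]
            if not (0 <= y < m.shape[0] and 0 <= x < m.shape[1]):
                raise ValueError("position outside the image")
            if not m[y, x]:
                continue
        if cls.matches(rgb, hsv):
            return cls.name
    return BACKGROUND


def segment_image(img: np.ndarray, cfg: ViewConfig) -> LabelImage:
    """Apply the per-pixel classifier to a whole 8-bit RGB image."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.integer) and img.min() >= 0 and img.max() <= 255:
            img = img.astype(np.uint8)
        else:
            raise ValueError("expected 8-bit RGB data")
    height, width = img.shape[:2]
    hsv = rgb_to_hsv(img)
    channels = {
        "R": img[..., 0].astype(np.float64),
        "G": img[..., 1].astype(np.float64),
        "B": img[..., 2].astype(np.float64),
        "H": hsv[..., 0],
        "S": hsv[..., 1],
        "V": hsv[..., 2],
    }
    masks = region_masks(cfg, width, height)
    labels = np.zeros((height, width), dtype=np.int16)
    unassigned = np.ones((height, width), dtype=bool)
    for idx, cls in enumerate(cfg.classes, start=1):
        match = np.zeros((height, width), dtype=bool)
        for profile in cls.profiles:
            box = np.ones((height, width), dtype=bool)
            for iv in profile.intervals:
                box &= iv.contains_array(channels[iv.channel])
                if not box.any():
                    break
            match |= box
        if cls.region_name is not None:
            match &= masks[cls.region_name]
        take = match & unassigned
        labels[take] = idx
        unassigned &= ~take
    return LabelImage(labels=labels, names=cfg.class_names)


def extract_plant(label_image: LabelImage) -> np.ndarray:
    """Binary plant mask: true exactly where the label is ``plant``."""
    if "plant" not in label_image.names:
        return np.zeros(label_image.shape, dtype=bool)
    return label_image.mask_for("plant")


def _structure(radius: int) -> np.ndarray:
    if radius < 0:
        raise ValueError("radius must be non-negative")
    return np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)


def erode(mask: np.ndarray, radius: int) -> np.ndarray:
    """Square-element erosion; pixels outside the frame count as false."""
    mask = np.asarray(mask, dtype=bool)
    if radius == 0:
        return mask.copy()
    return ndimage.binary_erosion(mask, structure=_structure(radius), border_value=0)


def dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """Square-element dilation (dual of erosion)."""
    mask = np.asarray(mask, dtype=bool)
    if radius == 0:
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=_structure(radius), border_value=0)


def opening(mask: np.ndarray, radius: int) -> np.ndarray:
    """Erosion followed by dilation with the same square element.

    Removes foreground features smaller than the ``(2r+1)``-pixel square
    while leaving larger shapes intact; idempotent and anti-extensive.
    """
    return dilate(erode(mask, radius), radius)


def render_label_image(label_image: LabelImage, cfg: ViewConfig) -> np.ndarray:
    """Colour-coded RGB rendering of a label image.

    Each class is painted in its configured display colour; background
    uses the view's background display colour (yellow by default).
    """
    palette = np.zeros((len(label_image.names), 3), dtype=np.uint8)
    palette[0] = cfg.background_display
    for idx, cls in enumerate(cfg.classes, start=1):
        palette[idx] = cls.display_colour
    return palette[label_image.labels]
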
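"""Independent brute-force oracles used by the test suite.

Deliberately slow, longhand re-implementations: per-pixel loops,
``colorsys`` for colour conversion, exhaustive neighbourhood scans and
all-pairs distances.  They share no code with the package modules they
check.
"""

from __future__ import annotations

import colorsys
import math

import numpy as np


def ref_rgb_to_hsv(r: int, g: int, b: int):
    """Stdlib colorsys conversion, hue rescaled to degrees."""
    h, s, v = colorsys.rgb_to_hsv(r / 255.0, g / 255.0, b / 255.0)
    return h * 360.0, s, v


def point_in_region(region, x: int, y: int) -> bool:
    if region.shape == "rectangle":
        x0, y0, x1, y1 = region.geometry
        return x0 <= x <= x1 and y0 <= y <= y1
    cx, cy, rad = region.geometry
    return (x - cx) ** 2 + (y - cy) ** 2 <= rad**2


def interval_contains(lo, hi, wraps, value) -> bool:
    if wraps:
        return value >= lo or value <= hi
    return lo <= value <= hi


def classify_longhand(rgb, x, y, cfg) -> str:
    """Re-evaluate every class's six intervals the slow way."""
    from phenopipe.regions import scale_region

    h, s, v = ref_rgb_to_hsv(*rgb)
    values = {"R": rgb[0], "G": rgb[1], "B": rgb[2], "H": h, "S": s, "V": v}
    for cls in cfg.classes:
        if cls.region_name is not None:
            reg = scale_region(cfg.region(cls.region_name), cfg.region_scale)
            if not point_in_region(reg, x, y):
                continue
        for profile in cls.profiles:
            if all(
                interval_contains(iv.lo, iv.hi, iv.wraps, values[iv.channel])
                for iv in profile.intervals
            ):
                return cls.name
    return "background"


def segment_longhand(img, cfg) -> np.ndarray:
    """Per-pixel longhand segmentation; returns an array of label names."""
    h, w = img.shape[:2]
    out = np.empty((h, w), dtype=object)
    for y in range(h):
        for x in range(w):
            out[y, x] = classify_longhand(tuple(int(c) for c in img[y, x]), x, y, cfg)
    return out


def erode_scan(mask, radius) -> np.ndarray:
    h, w = mask.shape
    out = np.zeros_like(mask)
    for y in range(h):
        for x in range(w):
            ok = True
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    yy, xx = y + dy, x + dx
                    if not (0 <= yy < h and 0 <= xx < w and mask[yy, xx]):
                        ok = False
                        break
                if not ok:
                    break
            out[y, x] = ok
    return out


def dilate_scan(mask, radius) -> np.ndarray:
    h, w = mask.shape
    out = np.zeros_like(mask)
    for y in range(h):
        for x in range(w):
            hit = False
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w and mask[yy, xx]:
                        hit = True
                        break
                if hit:
                    break
            out[y, x] = hit
    return out


def extents_scan(mask):
    h, w = mask.shape
    xs = [x for y in range(h) for x in range(w) if mask[y, x]]
    ys = [y for y in range(h) for x in range(w) if mask[y, x]]
    if not xs:
        return 0, 0
    return max(xs) - min(xs) + 1, max(ys) - min(ys) + 1

def diameter_pairwise(mask) -> float:
    pts = [(x, y) for y in range(mask.shape[0]) for x in range(mask.shape[1]) if mask[y, x]]
    best = 0.0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = math.dist(pts[i], pts[j])
            if d > best:
                best = d
    return best


def outline_scan(mask) -> np.ndarray:
    h, w = mask.shape
    out = np.zeros_like(mask)
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                yy, xx = y + dy, x + dx
                if not (0 <= yy < h and 0 <= xx < w) or not mask[yy, xx]:
                    out[y, x] = True
                    break
    return out
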
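"""RGB <-> HSV conversion for the combined-colour-space pixel classifier.

The segmentation thresholds each pixel in both colour spaces at once:
the raw camera channels R, G, B (integers in [0, 255]) and the hexcone
transform H (hue, degrees in [0, 360)), S (saturation, [0, 1]) and
V (value/brightness, [0, 1]).  HSV separates chromatic identity from
brightness, which makes green-plant thresholds far more robust to
illumination drift than RGB alone; RGB is kept because hue is
numerically unstable at low saturation.

Conventions fixed here (and relied on by every downstream module):

* hue is stored in degrees, ``0 <= h < 360``;
* achromatic pixels (``s == 0``) get ``h = 0``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rgb_to_hsv", "hsv_to_rgb"]


def _check_rgb(rgb: np.ndarray) -> np.ndarray:
    arr = np.asarray(rgb)
    if arr.shape[-1] != 3:
        raise ValueError("expected RGB data with a trailing axis of size 3")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValueError("RGB channels must be integers in [0, 255]")
    if arr.min(initial=0) < 0 or arr.max(initial=0) > 255:
        raise ValueError("RGB channels must lie in [0, 255]")
    return arr.astype(np.float64)


def rgb_to_hsv(rgb) -> np.ndarray:
    """Hexcone transform of 8-bit RGB values.

    Parameters
    ----------
    rgb
        Array-like of shape ``(..., 3)`` with integer channels in
        ``[0, 255]``; a single pixel ``(r, g, b)`` works too.

    Returns
    -------
    numpy.ndarray
        Float array of the same shape: hue in degrees ``[0, 360)``,
        saturation and value in ``[0, 1]``.
    """
    arr = _check_rgb(rgb) / 255.0
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    v = arr.max(axis=-1)
    delta = v - arr.min(axis=-1)
    # s = delta / v, with the achromatic / black conventions s = 0, h = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(v > 0, delta / np.where(v > 0, v, 1.0), 0.0)
        inv = np.where(delta > 0, 1.0 / np.where(delta > 0, delta, 1.0), 0.0)
    h = np.zeros_like(v)
    h = np.where((v == r) & (delta > 0), 60.0 * (g - b) * inv, h)
    h = np.where((v == g) & (v != r) & (delta > 0), 120.0 + 60.0 * (b - r) * inv, h)
    h = np.where((v == b) & (v != r) & (v != g) & (delta > 0), 240.0 + 60.0 * (r - g) * inv, h)
    h = np.mod(h, 360.0)
    out = np.stack([h, s, v], axis=-1)
    return out


def hsv_to_rgb(hsv) -> np.ndarray:
    """Inverse hexcone transform, rounded to integer 8-bit channels.

    Accepts hue in degrees ``[0, 360)`` and s, v in ``[0, 1]``; returns
    an integer array of the same shape with channels in ``[0, 255]``.
    """
    arr = np.asarray(hsv, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise ValueError("expected HSV data with a trailing axis of size 3")
    h, s, v = arr[..., 0], arr[..., 1], arr[..., 2]
    if np.any((h < 0) | (h >= 360)):
        raise ValueError("hue must lie in [0, 360)")
    if np.any((s < 0) | (s > 1)) or np.any((v < 0) | (v > 1)):
        raise ValueError("saturation and value must lie in [0, 1]")
    hp = h / 60.0
    i = np.floor(hp).astype(np.int64) % 6
    f = hp - np.floor(hp)
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))
    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    out = np.stack([r, g, b], axis=-1) * 255.0
    return np.rint(out).astype(np.int64)
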
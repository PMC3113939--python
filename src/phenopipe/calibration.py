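"""Calibration: colour-threshold profiles and per-view configuration.

The segmentation is multidimensional histogram thresholding (MHT): an
object class is a box in the six-channel space (R, G, B, H, S, V) — a
closed ``[lo, hi]`` interval per channel, all six tested conjunctively.
A class may carry several such boxes (a disjunction) to capture
disjoint colour modes, and may be bound to an image region outside of
which it never matches.  One :class:`ViewConfig` per camera view (top
or side) bundles the classes, the named regions, a region scaling
factor tracking camera zoom, the pixel -> millimetre factor and the
opening radius used for mask cleanup.

Profiles are calibrated from labelled sample pixels: per channel the
``trim``/``1 - trim`` quantiles of the sample (``trim = 0`` gives the
exact min/max).  Hue is treated circularly — the interval is placed on
the cut that minimises the circular span of the sample, and may wrap
through 0 degrees (``lo > hi`` with ``wraps=True`` meaning
``[lo, 360) U [0, hi]``).

Configurations persist as a small YAML document (one per view) with a
mandatory ``schema`` version field; see :func:`save_config` for the
layout and ``docs/methods.md`` for the full schema description.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .colorspace import rgb_to_hsv
from .regions import Region

__all__ = [
    "CHANNELS",
    "CHANNEL_RANGES",
    "ChannelInterval",
    "ThresholdProfile",
    "ObjectClassDef",
    "ViewConfig",
    "derive_profile",
    "validate_config",
    "load_config",
    "save_config",
    "read_labelled_samples",
]

CHANNELS: Tuple[str, ...] = ("R", "G", "B", "H", "S", "V")

#: Inclusive value range of each channel (hue upper bound exclusive).
CHANNEL_RANGES: Dict[str, Tuple[float, float]] = {
    "R": (0, 255),
    "G": (0, 255),
    "B": (0, 255),
    "H": (0, 360),
    "S": (0, 1),
    "V": (0, 1),
}

BACKGROUND = "background"
SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ChannelInterval:
    """Closed threshold interval on one channel.

    For hue, ``wraps=True`` with ``lo > hi`` denotes the circular
    interval ``[lo, 360) U [0, hi]``.
    """

    channel: str
    lo: float
    hi: float
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.wraps and self.channel != "H":
            raise ValueError("only the hue channel may wrap")
        rng = CHANNEL_RANGES[self.channel]
        for v in (self.lo, self.hi):
            if not (rng[0] <= v <= rng[1]) or (self.channel == "H" and v >= 360):
                raise ValueError(
                    f"{self.channel} threshold {v} outside range {rng}"
                )
        if not self.wraps and self.lo > self.hi:
            raise ValueError(f"{self.channel}: lo > hi without wraps")

    def contains(self, value: float) -> bool:
        if self.wraps:
            return value >= self.lo or value <= self.hi
        return self.lo <= value <= self.hi

    def contains_array(self, values: np.ndarray) -> np.ndarray:
        if self.wraps:
            return (values >= self.lo) | (values <= self.hi)
        return (values >= self.lo) & (values <= self.hi)

    def intersects(self, other: "ChannelInterval") -> bool:
        """Whether two intervals on the same channel share any value."""
        if self.channel != other.channel:
            raise ValueError("cannot intersect intervals on different channels")
        a = self._segments()
        b = other._segments()
        return any(lo1 <= hi2 and lo2 <= hi1 for lo1, hi1 in a for lo2, hi2 in b)

    def _segments(self) -> List[Tuple[float, float]]:
        if self.wraps and self.lo > self.hi:
            return [(self.lo, 360.0), (0.0, self.hi)]
        return [(self.lo, self.hi)]


@dataclass(frozen=True)
class ThresholdProfile:
    """One six-channel colour box: exactly one interval per channel."""

    intervals: Tuple[ChannelInterval, ...]

    def __post_init__(self) -> None:
        channels = tuple(iv.channel for iv in self.intervals)
        if sorted(channels) != sorted(CHANNELS):
            raise ValueError("a profile needs exactly one interval per channel")
        ordered = tuple(sorted(self.intervals, key=lambda iv: CHANNELS.index(iv.channel)))
        object.__setattr__(self, "intervals", ordered)

    @classmethod
    def from_bounds(cls, **bounds) -> "ThresholdProfile":
        """Build from keyword bounds, e.g. ``R=(10, 20), ..., H=(350, 10)``.

        A hue pair with ``lo > hi`` is taken as wrapping through 0.
        """
        ivs = []
        for ch in CHANNELS:
            lo, hi = bounds[ch]
            wraps = ch == "H" and lo > hi
            ivs.append(ChannelInterval(ch, float(lo), float(hi), wraps))
        return cls(tuple(ivs))

    def __getitem__(self, channel: str) -> ChannelInterval:
        for iv in self.intervals:
            if iv.channel == channel:
                return iv
        raise KeyError(channel)

    def contains(self, rgb: Sequence[float], hsv: Optional[Sequence[float]] = None) -> bool:
        """Whether a pixel lies inside the box (all six channels)."""
        if hsv is None:
            hsv = rgb_to_hsv(rgb)
        values = (rgb[0], rgb[1], rgb[2], hsv[0], hsv[1], hsv[2])
        return all(iv.contains(v) for iv, v in zip(self.intervals, values))

    def intersects(self, other: "ThresholdProfile") -> bool:
        return all(self[ch].intersects(other[ch]) for ch in CHANNELS)


@dataclass(frozen=True)
class ObjectClassDef:
    """A named object class: colour box(es), optional region, display colour."""

    name: str
    profiles: Tuple[ThresholdProfile, ...]
    region_name: Optional[str] = None
    display_colour: Tuple[int, int, int] = (128, 128, 128)

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError(f"class {self.name!r} needs at least one profile")
        if self.name == BACKGROUND:
            raise ValueError("'background' is reserved for unmatched pixels")
        if self.name == "plant" and self.region_name is not None:
            raise ValueError("the plant class carries no region: leaves may be anywhere")
        object.__setattr__(self, "profiles", tuple(self.profiles))
        object.__setattr__(self, "display_colour", tuple(int(c) for c in self.display_colour))

    def matches(self, rgb: Sequence[float], hsv: Optional[Sequence[float]] = None) -> bool:
        if hsv is None:
            hsv = rgb_to_hsv(rgb)
        return any(p.contains(rgb, hsv) for p in self.profiles)


@dataclass(frozen=True)
class ViewConfig:
    """Complete calibration for one camera view.

    ``classes`` are tried in declaration order (first match wins), with
    the plant conventionally declared last among colour classes.
    ``mm_per_px`` converts one pixel edge to millimetres;
    ``region_scale`` rescales every region about its centroid before
    rasterization; ``opening_radius`` is the half-width of the square
    structuring element used to clean the plant mask.
    """

    view: str
    classes: Tuple[ObjectClassDef, ...]
    regions: Tuple[Region, ...] = ()
    region_scale: float = 1.0
    mm_per_px: float = 1.0
    opening_radius: int = 1
    background_display: Tuple[int, int, int] = (255, 255, 0)

    def __post_init__(self) -> None:
        if self.view not in ("top", "side"):
            raise ValueError("view must be 'top' or 'side'")
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique within a view")
        if self.region_scale <= 0:
            raise ValueError("region_scale must be positive")
        if self.opening_radius < 0:
            raise ValueError("opening_radius must be non-negative")
        object.__setattr__(self, "classes", tuple(self.classes))
        object.__setattr__(self, "regions", tuple(self.regions))

    def region(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def class_names(self) -> Tuple[str, ...]:
        """Label names in priority order, index 0 reserved for background."""
        return (BACKGROUND,) + tuple(c.name for c in self.classes)

    @property
    def config_id(self) -> str:
        """Deterministic short identifier of the calibration contents."""
        import hashlib

        digest = hashlib.sha1(
            yaml.safe_dump(_config_to_dict(self), sort_keys=True).encode()
        ).hexdigest()
        return f"{self.view}-{digest[:10]}"


# ---------------------------------------------------------------------------
# Profile derivation (the calibration estimator)


def _circular_hue_bounds(hues: np.ndarray, trim: float) -> Tuple[float, float, bool]:
    """Trimmed quantile bounds of hue, placed on the cut that minimises
    the circular span of the sample; returns (lo, hi, wraps)."""
    h = np.sort(np.mod(hues, 360.0))
    if h.size == 1 or np.allclose(h, h[0]):
        return float(h[0]), float(h[0]), False
    gaps = np.diff(h)
    wrap_gap = 360.0 - h[-1] + h[0]
    k = int(np.argmax(gaps)) if gaps.size and gaps.max() > wrap_gap else -1
    # Reference cut: start of the sample arc = hue just after the largest gap.
    shift = h[0] if k == -1 else h[k + 1]
    unwrapped = np.mod(h - shift, 360.0)
    lo_u = float(np.quantile(unwrapped, trim))
    hi_u = float(np.quantile(unwrapped, 1.0 - trim))
    lo = (lo_u + shift) % 360.0
    hi = (hi_u + shift) % 360.0
    wraps = lo > hi
    return lo, hi, wraps


def derive_profile(samples, trim: float = 0.0) -> ThresholdProfile:
    """Estimate a six-channel threshold box from labelled sample pixels.

    Parameters
    ----------
    samples
        Array-like of shape ``(n, 3)``: RGB pixels labelled as one
        object class.
    trim
        Quantile trim fraction in ``[0, 0.5)``.  ``0`` reproduces the
        strict per-channel min/max; a small positive value discards
        colour outliers (mislabelled pixels).
    """
    arr = np.asarray(samples, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot derive a profile from an empty sample")
    arr = arr.reshape(-1, 3)
    if not (0 <= trim < 0.5):
        raise ValueError("trim must lie in [0, 0.5)")
    hsv = rgb_to_hsv(arr.astype(np.int64))
    bounds = {}
    for i, ch in enumerate(("R", "G", "B")):
        bounds[ch] = (float(np.quantile(arr[:, i], trim)), float(np.quantile(arr[:, i], 1 - trim)))
    for i, ch in enumerate(("S", "V"), start=1):
        bounds[ch] = (float(np.quantile(hsv[:, i], trim)), float(np.quantile(hsv[:, i], 1 - trim)))
    lo, hi, wraps = _circular_hue_bounds(hsv[:, 0], trim)
    ivs = [ChannelInterval(ch, *bounds[ch]) for ch in ("R", "G", "B")]
    ivs.append(ChannelInterval("H", lo, hi, wraps))
    ivs.append(ChannelInterval("S", *bounds["S"]))
    ivs.append(ChannelInterval("V", *bounds["V"]))
    return ThresholdProfile(tuple(ivs))


def read_labelled_samples(path) -> Dict[str, np.ndarray]:
    """Read a labelled-pixel file: one ``r,g,b,label`` line per pixel.

    Blank lines and lines starting with ``#`` are ignored.  Returns a
    mapping label -> ``(n, 3)`` integer array.
    """
    groups: Dict[str, List[Tuple[int, int, int]]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 'r,g,b,label'")
            r, g, b = (int(p) for p in parts[:3])
            groups.setdefault(parts[3], []).append((r, g, b))
    return {label: np.asarray(px, dtype=np.int64) for label, px in groups.items()}


# ---------------------------------------------------------------------------
# Validation


def validate_config(cfg: ViewConfig) -> List[str]:
    """Sanity-check a view configuration; returns human-readable diagnostics.

    Reported problems: region references that do not resolve,
    overlapping colour boxes between classes bound to the same region,
    (near-)zero-area regions, and a non-positive millimetre factor.
    An empty list means the configuration is sound.
    """
    diags: List[str] = []
    region_names = {r.name for r in cfg.regions}
    for cls in cfg.classes:
        if cls.region_name is not None and cls.region_name not in region_names:
            diags.append(
                f"class {cls.name!r} references unknown region {cls.region_name!r}"
            )
    for reg in cfg.regions:
        if reg.shape == "rectangle":
            x0, y0, x1, y1 = reg.geometry
            if x0 == x1 or y0 == y1:
                diags.append(f"region {reg.name!r} has zero area")
        elif reg.geometry[2] < 0.5:
            diags.append(f"region {reg.name!r} rasterizes to at most one pixel")
    if cfg.mm_per_px <= 0:
        diags.append(f"mm_per_px must be positive, got {cfg.mm_per_px}")
    for a, b in itertools.combinations(cfg.classes, 2):
        if a.region_name != b.region_name:
            continue
        for pa, pb in itertools.product(a.profiles, b.profiles):
            if pa.intersects(pb):
                where = (
                    f"region {a.region_name!r}" if a.region_name else "the unrestricted image"
                )
                diags.append(
                    f"classes {a.name!r} and {b.name!r} share overlapping "
                    f"colour volumes in {where}"
                )
                break
    return diags


# ---------------------------------------------------------------------------
# YAML persistence


def _interval_to_list(iv: ChannelInterval) -> list:
    return [float(iv.lo), float(iv.hi)]


def _profile_to_dict(p: ThresholdProfile) -> dict:
    d = {"hue_unit": "degrees"}
    for ch in CHANNELS:
        d[ch] = _interval_to_list(p[ch])
    return d


def _config_to_dict(cfg: ViewConfig) -> dict:
    return {
        "schema": SCHEMA_VERSION,
        "view": cfg.view,
        "mm_per_px": float(cfg.mm_per_px),
        "region_scale": float(cfg.region_scale),
        "opening_radius": int(cfg.opening_radius),
        "background_display": list(cfg.background_display),
        "regions": [
            {"name": r.name, "shape": r.shape, "geometry": list(r.geometry)}
            for r in cfg.regions
        ],
        "classes": [
            {
                "name": c.name,
                "display_colour": list(c.display_colour),
                **({"region": c.region_name} if c.region_name else {}),
                "profiles": [_profile_to_dict(p) for p in c.profiles],
            }
            for c in cfg.classes
        ],
    }


def _profile_from_dict(d: Mapping) -> ThresholdProfile:
    unit = d.get("hue_unit", "degrees")
    if unit not in ("degrees", "byte"):
        raise ValueError(f"unknown hue unit {unit!r}")
    bounds = {}
    for ch in CHANNELS:
        if ch not in d:
            raise ValueError(f"profile missing channel {ch}")
        lo, hi = (float(v) for v in d[ch])
        if ch == "H" and unit == "byte":
            lo, hi = lo * 360.0 / 256.0, hi * 360.0 / 256.0
        bounds[ch] = (lo, hi)
    return ThresholdProfile.from_bounds(**bounds)


def save_config(cfg: ViewConfig, path) -> None:
    """Write a view configuration as a YAML document."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_config_to_dict(cfg), fh, sort_keys=False)


def load_config(path) -> ViewConfig:
    """Read a view configuration; the document must declare ``schema: 1``."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ValueError(f"{path}: not a mapping")
    if doc.get("schema") != SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported or missing schema version")
    regions = tuple(
        Region(r["name"], r["shape"], tuple(r["geometry"])) for r in doc.get("regions", [])
    )
    classes = tuple(
        ObjectClassDef(
            name=c["name"],
            profiles=tuple(_profile_from_dict(p) for p in c["profiles"]),
            region_name=c.get("region"),
            display_colour=tuple(c.get("display_colour", (128, 128, 128))),
        )
        for c in doc.get("classes", [])
    )
    return ViewConfig(
        view=doc["view"],
        classes=classes,
        regions=regions,
        region_scale=float(doc.get("region_scale", 1.0)),
        mm_per_px=float(doc.get("mm_per_px", 1.0)),
        opening_radius=int(doc.get("opening_radius", 1)),
        background_display=tuple(doc.get("background_display", (255, 255, 0))),
    )
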
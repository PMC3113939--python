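"""Synthetic greenhouse scenes with exact ground truth.

No public image set accompanies the original screening experiments, so
every stage of the pipeline is exercised on generated scenes that mimic
the structure of an automated-greenhouse photograph: a light-blue
backdrop, a pot carrier, support cages and sticks (and, in top view,
the soil surface and a conveyor-belt strip), each confined to its fixed
image region, with a plant of known geometry drawn on top.  Each object
class is painted in an interior colour of its threshold volume in the
companion configuration, optional uniform per-channel noise stresses
the threshold margins, and optional plant-coloured distractor blobs
("clutter") inside the cages region exercise the region restriction.

Ground-truth measurements (bounding box, pixel count, maximum Feret
diameter) are computed here by independent brute-force code — an
exhaustive scan and a chunked all-pairs distance — never by the
measurement module the tests are checking.

A scene is *safe* when the noise amplitude does not exceed the
amplitude the companion profiles were derived for: every perturbed
colour then still lies inside its class's colour box and the
segmentation reproduces the true label map exactly.  Scenes with
clutter are *adversarial* and require the adversarial companion
configuration, in which the cages class also claims plant-green inside
its region.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .calibration import ObjectClassDef, ThresholdProfile, ViewConfig, derive_profile
from .regions import Region

__all__ = [
    "PALETTE",
    "DISPLAY",
    "SceneSpec",
    "GroundTruth",
    "build_view_config",
    "companion_config",
    "generate_scene",
    "iter_timeseries",
    "generate_timeseries",
    "generate_validation_batch",
    "default_experiment",
]

#: Scene colours: one interior colour per object class (and the backdrop,
#: which matches no class).  Any two entries differ by >= 58 in at least
#: one RGB channel, so the noise cubes stay disjoint for amplitudes < 29.
PALETTE: Dict[str, Tuple[int, int, int]] = {
    "background": (168, 205, 235),  # light-blue backdrop wall
    "soil": (110, 75, 40),
    "carrier": (200, 120, 40),
    "cages": (185, 60, 165),
    "sticks": (90, 95, 110),
    "conveyor_belt": (35, 35, 35),
    "plant": (60, 160, 50),
}

#: Display colours for the colour-coded label rendering.
DISPLAY: Dict[str, Tuple[int, int, int]] = {
    "soil": (139, 69, 19),
    "carrier": (0, 0, 255),
    "cages": (255, 0, 255),
    "sticks": (60, 60, 255),
    "conveyor_belt": (0, 0, 0),
    "plant": (0, 200, 0),
}

#: Class priority order per view; the plant is declared last.
CLASS_ORDER: Dict[str, Tuple[str, ...]] = {
    "top": ("soil", "carrier", "cages", "sticks", "conveyor_belt", "plant"),
    "side": ("carrier", "cages", "sticks", "plant"),
}

DEFAULT_PROFILE_AMPLITUDE = 6  # noise amplitude the companion profiles cover
DEFAULT_SIZES = {"side": (192, 240), "top": (192, 192)}


# ---------------------------------------------------------------------------
# Companion configuration


@lru_cache(maxsize=64)
def _cube_profile(colour: Tuple[int, int, int], amplitude: int) -> ThresholdProfile:
    """Threshold box covering every 8-bit colour within ``amplitude`` of
    ``colour`` per channel (clipped to [0, 255]), derived by enumerating
    the whole cube so the HSV bounds are exact, not corner estimates."""
    axes = [
        np.arange(max(0, c - amplitude), min(255, c + amplitude) + 1) for c in colour
    ]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    if len(grid) > 1_000_000:  # very large amplitudes: stride, keep extremes
        keep = np.unique(np.r_[0, len(grid) - 1, np.arange(0, len(grid), len(grid) // 500_000)])
        grid = grid[keep]
    return derive_profile(grid, trim=0.0)


def _side_regions(width: int, height: int) -> List[Region]:
    w, h = width, height
    return [
        Region("carrier", "rectangle", (0.19 * w, 0.79 * h, 0.81 * w, 0.94 * h)),
        Region("cages", "rectangle", (0.02 * w, 0.19 * h, 0.17 * w, 0.91 * h)),
        Region("sticks", "rectangle", (0.83 * w, 0.19 * h, 0.98 * w, 0.91 * h)),
    ]


def _top_regions(width: int, height: int) -> List[Region]:
    w, h = width, height
    r = 0.31 * min(w, h)
    return [
        Region("soil", "circle", (w / 2, h / 2, r)),
        Region("carrier", "rectangle", (0.09 * w, 0.09 * h, 0.91 * w, 0.91 * h)),
        Region("cages", "rectangle", (0, 0, w - 1, 0.08 * h)),
        Region("sticks", "rectangle", (0, 0.92 * h, w - 1, h - 1)),
        Region("conveyor_belt", "rectangle", (0, 0.09 * h, 0.07 * w, 0.91 * h)),
    ]


def build_view_config(
    view: str,
    width: int,
    height: int,
    mm_per_px: float = 1.0,
    profile_amplitude: int = DEFAULT_PROFILE_AMPLITUDE,
    region_scale: float = 1.0,
    opening_radius: int = 1,
    adversarial: bool = False,
) -> ViewConfig:
    """Companion calibration matched to the palette and scene layout.

    ``adversarial=True`` gives the cages class a second colour box equal
    to the plant's, so plant-coloured clutter inside the cages region is
    claimed by the (earlier-declared, region-bound) cages class rather
    than the plant.
    """
    regions = _side_regions(width, height) if view == "side" else _top_regions(width, height)
    plant_profile = _cube_profile(PALETTE["plant"], profile_amplitude)
    classes = []
    for name in CLASS_ORDER[view]:
        profiles = [
            plant_profile if name == "plant" else _cube_profile(PALETTE[name], profile_amplitude)
        ]
        if adversarial and name == "cages":
            profiles.append(plant_profile)
        classes.append(
            ObjectClassDef(
                name=name,
                profiles=tuple(profiles),
                region_name=None if name == "plant" else name,
                display_colour=DISPLAY[name],
            )
        )
    return ViewConfig(
        view=view,
        classes=tuple(classes),
        regions=tuple(regions),
        region_scale=region_scale,
        mm_per_px=mm_per_px,
        opening_radius=opening_radius,
    )


# ---------------------------------------------------------------------------
# Scene specification and ground truth


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Side-view plants are a canopy rectangle (``canopy_w`` x ``canopy_h``
    pixels) optionally on a stem; top-view plants are a rosette ellipse
    (semi-axes ``rosette_rx``/``rosette_ry``) with ``arm_count`` radial
    leaf arms.  ``noise_amplitude`` is the maximum uniform per-channel
    perturbation; ``clutter_blobs`` plant-coloured distractors are
    placed inside the cages region (making the spec adversarial).
    """

    view: str
    width: int = 0  # 0 -> view default
    height: int = 0
    canopy_w: int = 60
    canopy_h: int = 48
    stem_w: int = 6
    stem_h: int = 18
    rosette_rx: int = 40
    rosette_ry: int = 32
    arm_count: int = 0
    arm_length: int = 0
    noise_amplitude: int = 4
    clutter_blobs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.view not in ("top", "side"):
            raise ValueError("view must be 'top' or 'side'")
        w, h = DEFAULT_SIZES[self.view]
        if self.width == 0:
            object.__setattr__(self, "width", w)
        if self.height == 0:
            object.__setattr__(self, "height", h)
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")

    @property
    def adversarial(self) -> bool:
        return self.clutter_blobs > 0

    def is_safe(self, profile_amplitude: int = DEFAULT_PROFILE_AMPLITUDE) -> bool:
        """Whether every perturbed colour stays inside its class volume."""
        return self.noise_amplitude <= profile_amplitude


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-scene truth, computed by generation-side oracle code."""

    labels: np.ndarray  # int labels, 0 = background
    names: Tuple[str, ...]
    plant_mask: np.ndarray
    pixel_count: int
    x_extent_px: int
    y_extent_px: int
    bbox: Optional[Tuple[int, int, int, int]]  # (x0, y0, x1, y1)
    diameter_px: Optional[float]

    @property
    def width_px(self) -> int:
        return self.x_extent_px

    @property
    def height_px(self) -> int:
        return self.y_extent_px


def _oracle_bbox(mask: np.ndarray) -> Optional[Tuple[int, int, int, int]]:
    """Exhaustive row/column scan for the plant bounding box."""
    h, w = mask.shape
    x0 = y0 = None
    x1 = y1 = -1
    for y in range(h):
        row = mask[y]
        if row.any():
            if y0 is None:
                y0 = y
            y1 = y
    for x in range(w):
        col = mask[:, x]
        if col.any():
            if x0 is None:
                x0 = x
            x1 = x
    if y0 is None or x0 is None:
        return None
    return (x0, y0, x1, y1)


def _oracle_diameter(mask: np.ndarray, chunk: int = 2048) -> float:
    """Chunked all-pairs maximum distance between true-pixel centres."""
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(np.float64)
    n = len(pts)
    if n < 2:
        return 0.0
    best = 0.0
    for i in range(0, n, chunk):
        block = pts[i : i + chunk]
        d2 = ((block[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        best = max(best, float(d2.max()))
    return float(np.sqrt(best))


# ---------------------------------------------------------------------------
# Rendering


def _fill_rect(img, labels, idx, colour, x0, y0, x1, y1) -> None:
    x0, y0, x1, y1 = int(x0), int(y0), int(x1), int(y1)
    img[y0 : y1 + 1, x0 : x1 + 1] = colour
    labels[y0 : y1 + 1, x0 : x1 + 1] = idx


def _fill_disk(img, labels, idx, colour, cx, cy, rx, ry) -> None:
    h, w = labels.shape
    yy, xx = np.ogrid[:h, :w]
    inside = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    img[inside] = colour
    labels[inside] = idx


def _draw_plant(spec: SceneSpec, img, labels, idx, opening_radius: int) -> np.ndarray:
    """Draw the plant; returns its final (opening-stable) mask.

    The drawn silhouette is regularised by one morphological opening at
    the pipeline's radius so that the true plant shape is invariant
    under the pipeline's own cleanup step — the scene's plant simply
    has no features thinner than the structuring element.
    """
    h, w = labels.shape
    mask = np.zeros((h, w), dtype=bool)
    if spec.view == "side":
        base_y = int(0.79 * h) - 1  # sits on the carrier
        cx = w // 2
        if spec.stem_h > 0 and spec.stem_w > 0:
            x0 = cx - spec.stem_w // 2
            mask[base_y - spec.stem_h + 1 : base_y + 1, x0 : x0 + spec.stem_w] = True
        top = base_y - spec.stem_h
        x0 = cx - spec.canopy_w // 2
        mask[top - spec.canopy_h + 1 : top + 1, x0 : x0 + spec.canopy_w] = True
    else:
        cx, cy = w / 2, h / 2
        yy, xx = np.ogrid[:h, :w]
        mask |= ((xx - cx) / spec.rosette_rx) ** 2 + ((yy - cy) / spec.rosette_ry) ** 2 <= 1.0
        if spec.arm_count > 0 and spec.arm_length > 0:
            from skimage.draw import line

            for k in range(spec.arm_count):
                ang = 2 * np.pi * k / spec.arm_count
                ex = int(cx + (spec.rosette_rx + spec.arm_length) * np.cos(ang))
                ey = int(cy + (spec.rosette_ry + spec.arm_length) * np.sin(ang))
                rr, cc = line(int(cy), int(cx), ey, ex)
                keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                arm = np.zeros_like(mask)
                arm[rr[keep], cc[keep]] = True
                mask |= ndimage.binary_dilation(arm, np.ones((5, 5), bool))
    if opening_radius > 0:
        se = np.ones((2 * opening_radius + 1,) * 2, bool)
        mask = ndimage.binary_dilation(
            ndimage.binary_erosion(mask, se, border_value=0), se, border_value=0
        )
    img[mask] = PALETTE["plant"]
    labels[mask] = idx
    return mask


def generate_scene(
    spec: SceneSpec,
    opening_radius: int = 1,
    compute_diameter: bool = True,
) -> Tuple[np.ndarray, GroundTruth]:
    """Render one scene; deterministic for a given spec (seed included).

    Returns the 8-bit RGB image and the exact :class:`GroundTruth`.
    ``opening_radius`` must match the companion configuration so the
    plant silhouette is stable under the pipeline's cleanup.
    """
    w, h = spec.width, spec.height
    if spec.view == "side":
        max_cw = int(0.60 * w)
        if spec.canopy_w > max_cw or spec.canopy_h + spec.stem_h > int(0.75 * h):
            raise ValueError("plant does not fit the side-view scene layout")
    else:
        if 2 * spec.rosette_rx + 2 * spec.arm_length >= int(0.62 * min(w, h)) + 12:
            raise ValueError("rosette does not fit inside the soil region")
    rng = np.random.default_rng(spec.seed)
    names = ("background",) + CLASS_ORDER[spec.view]
    idx = {n: i for i, n in enumerate(names)}
    img = np.empty((h, w, 3), dtype=np.int16)
    img[...] = PALETTE["background"]
    labels = np.zeros((h, w), dtype=np.int16)

    if spec.view == "side":
        _fill_rect(img, labels, idx["carrier"], PALETTE["carrier"], 0.22 * w, 0.81 * h, 0.78 * w, 0.92 * h)
        for x0, x1 in ((0.04, 0.07), (0.11, 0.14)):
            _fill_rect(img, labels, idx["cages"], PALETTE["cages"], x0 * w, 0.22 * h, x1 * w, 0.89 * h)
        for x0, x1 in ((0.86, 0.89), (0.93, 0.96)):
            _fill_rect(img, labels, idx["sticks"], PALETTE["sticks"], x0 * w, 0.22 * h, x1 * w, 0.89 * h)
    else:
        _fill_rect(img, labels, idx["carrier"], PALETTE["carrier"], 0.125 * w, 0.125 * h, 0.875 * w, 0.875 * h)
        _fill_disk(img, labels, idx["soil"], PALETTE["soil"], w / 2, h / 2, 0.28 * min(w, h), 0.28 * min(w, h))
        _fill_rect(img, labels, idx["cages"], PALETTE["cages"], 0.02 * w, 0.01 * h, 0.98 * w, 0.06 * h)
        _fill_rect(img, labels, idx["sticks"], PALETTE["sticks"], 0.02 * w, 0.94 * h, 0.98 * w, 0.99 * h)
        _fill_rect(img, labels, idx["conveyor_belt"], PALETTE["conveyor_belt"], 0.008 * w, 0.12 * h, 0.05 * w, 0.88 * h)

    plant_mask = _draw_plant(spec, img, labels, idx["plant"], opening_radius)

    # Plant-coloured distractors inside the cages region (adversarial).
    for _ in range(spec.clutter_blobs):
        if spec.view == "side":
            bx0 = rng.integers(int(0.03 * w), int(0.13 * w))
            by0 = rng.integers(int(0.22 * h), int(0.85 * h))
        else:
            bx0 = rng.integers(int(0.05 * w), int(0.90 * w))
            by0 = rng.integers(int(0.01 * h), max(int(0.04 * h), int(0.01 * h) + 1))
        size = int(rng.integers(4, 7))
        _fill_rect(
            img,
            labels,
            idx["cages"],
            PALETTE["plant"],
            bx0,
            by0,
            min(bx0 + size, w - 1),
            min(by0 + size, h - 1),
        )
    if spec.noise_amplitude > 0:
        noise = rng.integers(
            -spec.noise_amplitude, spec.noise_amplitude + 1, size=img.shape, dtype=np.int16
        )
        img = img + noise
    img = np.clip(img, 0, 255).astype(np.uint8)

    bbox = _oracle_bbox(plant_mask)
    if bbox is None:
        xe = ye = 0
    else:
        xe = bbox[2] - bbox[0] + 1
        ye = bbox[3] - bbox[1] + 1
    truth = GroundTruth(
        labels=labels,
        names=names,
        plant_mask=plant_mask,
        pixel_count=int(plant_mask.sum()),
        x_extent_px=xe,
        y_extent_px=ye,
        bbox=bbox,
        diameter_px=_oracle_diameter(plant_mask) if compute_diameter else None,
    )
    return img, truth


def companion_config(spec: SceneSpec, mm_per_px: float = 1.0, opening_radius: int = 1) -> ViewConfig:
    """The calibration matching a scene spec's view, size and clutter mode."""
    return build_view_config(
        spec.view,
        spec.width,
        spec.height,
        mm_per_px=mm_per_px,
        opening_radius=opening_radius,
        adversarial=spec.adversarial,
    )


# ---------------------------------------------------------------------------
# Time series (growth experiment) and validation batch


def default_experiment(days: Sequence[int] = (29, 35, 41, 47, 53)) -> Dict[str, List[float]]:
    """Mean canopy-area curves (px^2 at 1 mm/px) for a two-cultivar,
    two-condition growth experiment: a taller, broader-leaved cultivar
    versus a tillering semi-dwarf, each well watered or drought
    stressed (stress reduces area, with partial late recovery)."""
    base = {"Barke": 1400.0, "Morex": 2000.0}
    stress = [1.0, 0.85, 0.72, 0.72, 0.85]
    out: Dict[str, List[float]] = {}
    for cultivar, a0 in base.items():
        growth = [a0 * 1.32**i for i in range(len(days))]
        out[f"{cultivar}/well-watered"] = growth
        out[f"{cultivar}/drought"] = [a * s for a, s in zip(growth, stress)]
    return out


def _canopy_from_area(area: float, aspect: float, max_w: int, max_h: int) -> Tuple[int, int]:
    cw = int(np.clip(round(np.sqrt(area / aspect)), 3, max_w))
    ch = int(np.clip(round(area / cw), 3, max_h))
    return cw, ch


def iter_timeseries(
    group_means: Mapping[str, Sequence[float]],
    days: Sequence,
    n_plants: int,
    cv: float = 0.2,
    seed: int = 0,
    width: int = 192,
    height: int = 240,
    noise_amplitude: int = 4,
    aspect: float = 0.75,
):
    """Yield side-view growth scenes, one per plant per day.

    Per plant and day the canopy area is drawn log-normally with the
    group/day mean and coefficient of variation ``cv``, then realised
    as a canopy rectangle of that pixel count (up to rounding).  Yields
    ``(plant_id, group, day, image, truth, spec)`` tuples; determinism
    follows from the seed.
    """
    if n_plants < 1 or not days:
        raise ValueError("need at least one plant and one day")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    max_w = int(0.58 * width)
    max_h = int(0.70 * height)
    for group in group_means:
        if len(group_means[group]) != len(days):
            raise ValueError(f"group {group!r}: need one mean per day")
    for group, means in group_means.items():
        gslug = group.replace("/", "-")
        for j in range(n_plants):
            plant_id = f"{gslug}-p{j:02d}"
            for day, mu in zip(days, means):
                if mu <= 0:
                    raise ValueError("mean areas must be positive")
                area = float(rng.lognormal(np.log(mu) - sigma**2 / 2, sigma))
                cw, ch = _canopy_from_area(area, aspect, max_w, max_h)
                spec = SceneSpec(
                    view="side",
                    width=width,
                    height=height,
                    canopy_w=cw,
                    canopy_h=ch,
                    stem_w=0,
                    stem_h=0,
                    noise_amplitude=noise_amplitude,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                img, truth = generate_scene(spec, compute_diameter=False)
                yield plant_id, group, day, img, truth, spec


def generate_timeseries(
    out_dir,
    group_means: Optional[Mapping[str, Sequence[float]]] = None,
    days: Optional[Sequence] = None,
    n_plants: int = 8,
    cv: float = 0.2,
    seed: int = 0,
    width: int = 192,
    height: int = 240,
    noise_amplitude: int = 4,
) -> pd.DataFrame:
    """Write a growth-experiment image set: PNGs, manifest.csv and the
    matching side-view configuration.  Returns the manifest."""
    import imageio.v3 as iio

    from .calibration import save_config

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if group_means is None:
        group_means = default_experiment()
    if days is None:
        days = (29, 35, 41, 47, 53)
    rows = []
    cfg = build_view_config("side", width, height)
    for plant_id, group, day, img, truth, spec in iter_timeseries(
        group_means, days, n_plants, cv, seed, width, height, noise_amplitude
    ):
        fname = f"{plant_id}_side_d{day}.png"
        iio.imwrite(out / fname, img)
        rows.append(
            {
                "filename": fname,
                "plant_id": plant_id,
                "group": group,
                "view": "side",
                "timepoint": day,
                "true_area_px": truth.pixel_count,
                "true_width_px": truth.x_extent_px,
                "true_height_px": truth.y_extent_px,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    save_config(cfg, out / "config_side.yaml")
    return manifest


def generate_validation_batch(
    out_dir,
    n_plants: int = 8,
    days: Sequence[int] = (28, 33, 38, 43, 48, 54),
    seed: int = 0,
    noise_amplitude: int = 4,
) -> pd.DataFrame:
    """Write a two-view validation batch: ``n_plants`` x ``len(days)``
    x {top, side} images named ``{plant_id}_{view}_d{day}.png``, the
    manifest and both view configurations.  The default 8 plants at 6
    time points give the 96-image batch used for end-to-end checks."""
    import imageio.v3 as iio

    from .calibration import save_config

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    sizes = DEFAULT_SIZES
    for view in ("top", "side"):
        w, h = sizes[view]
        save_config(build_view_config(view, w, h), out / f"config_{view}.yaml")
    for j in range(n_plants):
        plant_id = f"plant{j:02d}"
        for i, day in enumerate(days):
            growth = 1.0 + 0.45 * i
            for view in ("top", "side"):
                w, h = sizes[view]
                if view == "side":
                    cw = int(min(0.58 * w, 24 * growth + rng.integers(0, 8)))
                    ch = int(min(0.55 * h, 20 * growth + rng.integers(0, 8)))
                    spec = SceneSpec(
                        view="side",
                        width=w,
                        height=h,
                        canopy_w=cw,
                        canopy_h=ch,
                        stem_w=6,
                        stem_h=14,
                        noise_amplitude=noise_amplitude,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                else:
                    rx = int(min(0.27 * min(w, h), 13 * growth + rng.integers(0, 5)))
                    ry = max(6, int(rx * 0.8))
                    spec = SceneSpec(
                        view="top",
                        width=w,
                        height=h,
                        rosette_rx=rx,
                        rosette_ry=ry,
                        noise_amplitude=noise_amplitude,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                img, truth = generate_scene(spec, compute_diameter=False)
                fname = f"{plant_id}_{view}_d{day}.png"
                iio.imwrite(out / fname, img)
                rows.append(
                    {
                        "filename": fname,
                        "plant_id": plant_id,
                        "group": "validation",
                        "view": view,
                        "timepoint": day,
                        "true_area_px": truth.pixel_count,
                        "true_width_px": truth.x_extent_px,
                        "true_height_px": truth.y_extent_px,
                    }
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
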
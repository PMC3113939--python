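import numpy as np
import pytest

from phenopipe.calibration import ObjectClassDef, ThresholdProfile, ViewConfig
from phenopipe.regions import Region
from phenopipe.segmentation import (
    classify_pixel,
    dilate,
    erode,
    extract_plant,
    opening,
    region_masks,
    render_label_image,
    segment_image,
)
from phenopipe.synthetic import SceneSpec, companion_config, generate_scene

from _oracles import dilate_scan, erode_scan, segment_longhand
from conftest import random_mask


def profile(**overrides):
    bounds = {"R": (0, 255), "G": (0, 255), "B": (0, 255), "H": (0, 359.9), "S": (0, 1), "V": (0, 1)}
    bounds.update(overrides)
    return ThresholdProfile.from_bounds(**bounds)


@pytest.fixture()
def toy_cfg():
    """Two colour classes, one of them region-bound."""
    return ViewConfig(
        view="side",
        classes=(
            ObjectClassDef("carrier", (profile(R=(150, 255), G=(0, 140)),), region_name="carrier"),
            ObjectClassDef("plant", (profile(G=(150, 255), R=(0, 140)),)),
        ),
        regions=(Region("carrier", "rectangle", (0, 10, 15, 15)),),
    )


class TestClassifyPixel:
    def test_pixel_at_lower_bounds_matches(self):
        p = ThresholdProfile.from_bounds(
            R=(10, 20), G=(200, 220), B=(10, 30), H=(100, 130), S=(0.85, 1.0), V=(0.7, 0.9)
        )
        cfg = ViewConfig(view="side", classes=(ObjectClassDef("plant", (p,)),))
        # (26, 204, 26): hue 120, s ~0.87, v 0.8 -- inside; exact-lo RGB channels
        from phenopipe.colorspace import rgb_to_hsv

        rgb = (10, 204, 30)
        h, s, v = rgb_to_hsv(rgb)
        assert p.contains(rgb)
        assert classify_pixel(rgb, (0, 0), cfg, {}) == "plant"

    def test_region_restriction_forces_background(self, toy_cfg):
        masks = region_masks(toy_cfg, 20, 20)
        carrier_colour = (200, 50, 50)
        assert classify_pixel(carrier_colour, (5, 12), toy_cfg, masks) == "carrier"
        assert classify_pixel(carrier_colour, (5, 2), toy_cfg, masks) == "background"

    def test_matches_longhand_oracle_on_random_pixels(self, rng, toy_cfg):
        masks = region_masks(toy_cfg, 20, 20)
        from _oracles import classify_longhand

        for _ in range(500):
            rgb = tuple(int(c) for c in rng.integers(0, 256, 3))
            x, y = int(rng.integers(0, 20)), int(rng.integers(0, 20))
            assert classify_pixel(rgb, (x, y), toy_cfg, masks) == classify_longhand(
                rgb, x, y, toy_cfg
            )


class TestSegmentImage:
    def test_uniform_plant_image(self, toy_cfg):
        img = np.full((8, 8, 3), (30, 200, 30), dtype=np.uint8)
        li = segment_image(img, toy_cfg)
        assert (li.labels == li.names.index("plant")).all()

    def test_uniform_unmatched_image(self, toy_cfg):
        img = np.full((8, 8, 3), (145, 145, 145), dtype=np.uint8)
        li = segment_image(img, toy_cfg)
        assert (li.labels == 0).all()

    def test_noise_free_scene_reproduces_ground_truth_labels(self):
        spec = SceneSpec(view="top", noise_amplitude=0, seed=7)
        img, truth = generate_scene(spec)
        li = segment_image(img, companion_config(spec))
        assert li.names == truth.names
        assert np.array_equal(li.labels, truth.labels)

    def test_matches_longhand_segmentation(self, rng, toy_cfg):
        img = rng.integers(0, 256, size=(24, 24, 3)).astype(np.uint8)
        li = segment_image(img, toy_cfg)
        ref = segment_longhand(img, toy_cfg)
        got = np.array([[li.names[v] for v in row] for row in li.labels], dtype=object)
        assert (got == ref).all()

    def test_rejects_non_rgb_input(self, toy_cfg):
        with pytest.raises(ValueError):
            segment_image(np.zeros((5, 5)), toy_cfg)
        with pytest.raises(ValueError):
            segment_image(np.zeros((5, 5, 3), dtype=np.float64) + 0.5, toy_cfg)

    def test_region_soundness(self, rng):
        spec = SceneSpec(view="top", noise_amplitude=4, seed=2)
        img, _ = generate_scene(spec)
        cfg = companion_config(spec)
        li = segment_image(img, cfg)
        masks = region_masks(cfg, spec.width, spec.height)
        for cls in cfg.classes:
            if cls.region_name is None:
                continue
            assert not (li.mask_for(cls.name) & ~masks[cls.region_name]).any()

    def test_priority_permutation_with_disjoint_volumes(self, rng):
        spec = SceneSpec(view="side", noise_amplitude=4, seed=9)
        img, _ = generate_scene(spec)
        cfg = companion_config(spec)
        perm_cfg = ViewConfig(
            view=cfg.view,
            classes=tuple(reversed(cfg.classes)),
            regions=cfg.regions,
            region_scale=cfg.region_scale,
            mm_per_px=cfg.mm_per_px,
            opening_radius=cfg.opening_radius,
        )
        a = segment_image(img, cfg)
        b = segment_image(img, perm_cfg)
        names_a = np.array(a.names, dtype=object)[a.labels]
        names_b = np.array(b.names, dtype=object)[b.labels]
        assert (names_a == names_b).all()


class TestExtractPlant:
    def test_all_background_and_all_plant(self, toy_cfg):
        img = np.full((6, 6, 3), (145, 145, 145), dtype=np.uint8)
        assert extract_plant(segment_image(img, toy_cfg)).sum() == 0
        img[:] = (30, 200, 30)
        assert extract_plant(segment_image(img, toy_cfg)).all()

    def test_mixed_counts_match_label_counts(self, rng, toy_cfg):
        img = rng.integers(0, 256, size=(32, 32, 3)).astype(np.uint8)
        li = segment_image(img, toy_cfg)
        assert extract_plant(li).sum() == (li.labels == li.names.index("plant")).sum()


class TestMorphology:
    def test_radius_zero_is_identity(self, rng):
        m = random_mask(rng)
        for op in (erode, dilate, opening):
            assert np.array_equal(op(m, 0), m)

    def test_isolated_pixel(self):
        m = np.zeros((9, 9), dtype=bool)
        m[4, 4] = True
        assert erode(m, 1).sum() == 0
        d = dilate(m, 1)
        assert d.sum() == 9 and d[3:6, 3:6].all()
        assert opening(m, 1).sum() == 0

    def test_matches_scan_oracle(self, rng):
        for radius in (1, 2):
            for _ in range(10):
                m = random_mask(rng, (16, 16))
                assert np.array_equal(erode(m, radius), erode_scan(m, radius))
                assert np.array_equal(dilate(m, radius), dilate_scan(m, radius))

    def test_erosion_dilation_duality(self, rng):
        # dilation = complement of erosion of the complement (padded true)
        m = random_mask(rng, (20, 20))
        padded = np.pad(~m, 2, constant_values=True)
        dual = ~erode(padded, 1)[2:-2, 2:-2]
        assert np.array_equal(dilate(m, 1), dual)

    def test_opening_preserves_large_block(self):
        m = np.zeros((14, 14), dtype=bool)
        m[2:12, 2:12] = True
        assert np.array_equal(opening(m, 1), m)
        assert erode(m, 1).sum() == 8 * 8

    def test_opening_idempotent_and_antiextensive(self, rng):
        for _ in range(20):
            m = random_mask(rng)
            for r in (1, 2):
                once = opening(m, r)
                assert np.array_equal(opening(once, r), once)
                assert not (once & ~m).any()
                assert once.sum() <= m.sum()

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            erode(np.zeros((3, 3), bool), -1)


def test_render_label_image_uses_display_colours(toy_cfg):
    img = np.full((4, 4, 3), (30, 200, 30), dtype=np.uint8)
    li = segment_image(img, toy_cfg)
    rendered = render_label_image(li, toy_cfg)
    assert (rendered == toy_cfg.classes[1].display_colour).all()
    img[:] = (145, 145, 145)
    rendered = render_label_image(segment_image(img, toy_cfg), toy_cfg)
    assert (rendered == (255, 255, 0)).all()  # background is yellow-coded
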
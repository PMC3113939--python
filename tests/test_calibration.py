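import numpy as np
import pytest

from phenopipe.calibration import (
    CHANNELS,
    ChannelInterval,
    ObjectClassDef,
    ThresholdProfile,
    ViewConfig,
    derive_profile,
    load_config,
    read_labelled_samples,
    save_config,
    validate_config,
)
from phenopipe.colorspace import rgb_to_hsv
from phenopipe.regions import Region

from _oracles import interval_contains


def full_profile(**overrides):
    bounds = {"R": (0, 255), "G": (0, 255), "B": (0, 255), "H": (0, 359.9), "S": (0, 1), "V": (0, 1)}
    bounds.update(overrides)
    return ThresholdProfile.from_bounds(**bounds)


class TestChannelInterval:
    def test_closed_endpoints(self):
        iv = ChannelInterval("R", 10, 20)
        assert iv.contains(10) and iv.contains(20) and not iv.contains(21)

    def test_wrapping_hue(self):
        iv = ChannelInterval("H", 350, 10, wraps=True)
        assert iv.contains(355) and iv.contains(5) and not iv.contains(180)

    def test_wraps_only_valid_for_hue(self):
        with pytest.raises(ValueError):
            ChannelInterval("R", 200, 10, wraps=True)

    def test_wrapping_interval_intersection(self):
        a = ChannelInterval("H", 350, 10, wraps=True)
        assert a.intersects(ChannelInterval("H", 5, 20))
        assert not a.intersects(ChannelInterval("H", 100, 200))


class TestDeriveProfile:
    def test_two_pixel_min_max(self):
        samples = np.array([(10, 200, 10), (20, 220, 30)])
        p = derive_profile(samples, trim=0)
        assert (p["R"].lo, p["R"].hi) == (10, 20)
        assert (p["G"].lo, p["G"].hi) == (200, 220)
        assert (p["B"].lo, p["B"].hi) == (10, 30)
        hsv = rgb_to_hsv(samples)
        for i, ch in enumerate(("H", "S", "V")):
            assert p[ch].lo == pytest.approx(hsv[:, i].min())
            assert p[ch].hi == pytest.approx(hsv[:, i].max())

    def test_single_sample_degenerate_and_self_contained(self):
        p = derive_profile([(37, 90, 140)], trim=0)
        for ch in CHANNELS:
            assert p[ch].lo == p[ch].hi
        assert p.contains((37, 90, 140))

    def test_wraparound_hue_covers_all_samples(self, rng):
        # reds with hue scattered across the 0-degree seam
        hues = rng.uniform(-10, 10, size=1000) % 360
        hsv = np.column_stack([hues, np.full(1000, 0.9), np.full(1000, 0.9)])
        from phenopipe.colorspace import hsv_to_rgb

        samples = hsv_to_rgb(hsv)
        p = derive_profile(samples, trim=0)
        iv = p["H"]
        assert iv.wraps
        sample_hues = rgb_to_hsv(samples)[:, 0]
        assert all(interval_contains(iv.lo, iv.hi, iv.wraps, h) for h in sample_hues)
        # and the circular span stays tight: nothing near 180 degrees
        assert not interval_contains(iv.lo, iv.hi, iv.wraps, 180.0)

    def test_coverage_at_zero_trim(self, rng):
        samples = rng.integers(0, 256, size=(300, 3))
        p = derive_profile(samples, trim=0)
        hsv = rgb_to_hsv(samples)
        for px, hx in zip(samples, hsv):
            assert p.contains(px, hx)

    def test_trim_never_widens_intervals(self, rng):
        samples = rng.integers(40, 200, size=(500, 3))
        trims = [0.0, 0.05, 0.1, 0.2]
        profiles = [derive_profile(samples, t) for t in trims]
        for narrow, wide in zip(profiles[1:], profiles[:-1]):
            for ch in ("R", "G", "B", "S", "V"):
                assert narrow[ch].lo >= wide[ch].lo - 1e-12
                assert narrow[ch].hi <= wide[ch].hi + 1e-12

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            derive_profile(np.empty((0, 3)))


class TestValidateConfig:
    def test_packaged_default_configs_are_sound(self, side_cfg, top_cfg):
        assert validate_config(side_cfg) == []
        assert validate_config(top_cfg) == []

    def test_missing_region_reference(self):
        cfg = ViewConfig(
            view="side",
            classes=(ObjectClassDef("carrier", (full_profile(),), region_name="karrier"),),
            regions=(Region("carrier", "rectangle", (0, 0, 10, 10)),),
        )
        diags = validate_config(cfg)
        assert len(diags) == 1 and "karrier" in diags[0]

    def test_overlapping_volumes_in_shared_region(self):
        p = full_profile(R=(10, 50))
        cfg = ViewConfig(
            view="side",
            classes=(
                ObjectClassDef("a", (p,), region_name="r"),
                ObjectClassDef("b", (p,), region_name="r"),
            ),
            regions=(Region("r", "rectangle", (0, 0, 10, 10)),),
        )
        assert any("overlap" in d for d in validate_config(cfg))

    def test_disjoint_volumes_no_overlap_diagnostic(self):
        cfg = ViewConfig(
            view="side",
            classes=(
                ObjectClassDef("a", (full_profile(R=(0, 50)),), region_name="r"),
                ObjectClassDef("b", (full_profile(R=(100, 200)),), region_name="r"),
            ),
            regions=(Region("r", "rectangle", (0, 0, 10, 10)),),
        )
        assert validate_config(cfg) == []

    def test_nonpositive_mm_factor_flagged(self, side_cfg):
        from dataclasses import replace

        bad = replace(side_cfg, mm_per_px=0.0)
        assert any("mm_per_px" in d for d in validate_config(bad))

    def test_zero_area_region_flagged(self):
        cfg = ViewConfig(
            view="side",
            classes=(ObjectClassDef("a", (full_profile(),), region_name="line"),),
            regions=(Region("line", "rectangle", (5, 0, 5, 10)),),
        )
        assert any("zero area" in d for d in validate_config(cfg))


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path, side_cfg):
        path = tmp_path / "side.yaml"
        save_config(side_cfg, path)
        assert load_config(path) == side_cfg

    def test_schema_field_required(self, tmp_path, side_cfg):
        path = tmp_path / "side.yaml"
        save_config(side_cfg, path)
        text = path.read_text().replace("schema: 1", "schema: 99")
        path.write_text(text)
        with pytest.raises(ValueError, match="schema"):
            load_config(path)

    def test_byte_hue_unit_is_rescaled(self, tmp_path):
        doc = """
schema: 1
view: side
classes:
  - name: plant
    display_colour: [0, 200, 0]
    profiles:
      - hue_unit: byte
        R: [0, 255]
        G: [0, 255]
        B: [0, 255]
        H: [64, 128]
        S: [0, 1]
        V: [0, 1]
"""
        path = tmp_path / "cfg.yaml"
        path.write_text(doc)
        cfg = load_config(path)
        iv = cfg.classes[0].profiles[0]["H"]
        assert iv.lo == pytest.approx(64 * 360 / 256)
        assert iv.hi == pytest.approx(128 * 360 / 256)

    def test_labelled_sample_file(self, tmp_path):
        path = tmp_path / "samples.txt"
        path.write_text("# comment\n10,20,30,plant\n11,21,31,plant\n200,10,10,carrier\n")
        groups = read_labelled_samples(path)
        assert sorted(groups) == ["carrier", "plant"]
        assert groups["plant"].shape == (2, 3)
        assert groups["carrier"].tolist() == [[200, 10, 10]]


def test_plant_class_may_not_carry_a_region():
    with pytest.raises(ValueError, match="plant"):
        ObjectClassDef("plant", (full_profile(),), region_name="soil")
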
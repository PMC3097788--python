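"""Fan geometry, phantom chords and blocker-shadow projection."""

import math

import numpy as np
import pytest

from ctscatter.geometry import (BlockerArray, ConfigurationError, Phantom,
                                ScannerGeometry, SHADOW_CORE, OPEN,
                                channel_fan_angle, chord_lengths, project_shadow,
                                water_cylinder_215)

GEOM = ScannerGeometry()


class TestChannelAngles:
    def test_uniform_pitch_and_edges(self):
        pitch = 56.0 / 912
        assert GEOM.channel_pitch_deg == pytest.approx(pitch)
        assert channel_fan_angle(GEOM, 0) == pytest.approx(-28.0 + pitch / 2)
        assert channel_fan_angle(GEOM, 911) == pytest.approx(28.0 - pitch / 2)

    def test_fan_centre_between_middle_channels(self):
        # the centre falls midway between channels 455 and 456 (0-based)
        assert channel_fan_angle(GEOM, 455.5) == pytest.approx(0.0, abs=1e-12)
        assert channel_fan_angle(GEOM, 455) == pytest.approx(-channel_fan_angle(GEOM, 456))

    def test_antisymmetry(self):
        for i in (0, 17, 300, 455):
            assert channel_fan_angle(GEOM, i) == pytest.approx(
                -channel_fan_angle(GEOM, 911 - i))

    def test_out_of_range_raises(self):
        with pytest.raises(ConfigurationError):
            channel_fan_angle(GEOM, 912)
        with pytest.raises(ConfigurationError):
            channel_fan_angle(GEOM, -1)


class TestGeometryInvariants:
    def test_distance_ordering_enforced(self):
        with pytest.raises(ConfigurationError):
            ScannerGeometry(blocker_plane=600.0)
        with pytest.raises(ConfigurationError):
            ScannerGeometry(source_to_iso=1000.0)

    def test_channel_count_consistency(self):
        with pytest.raises(ConfigurationError):
            ScannerGeometry(n_channels_active=900)

    def test_element_count(self):
        assert GEOM.n_elements == 64 * 912


class TestChordLengths:
    def test_central_ray_water_cylinder(self):
        ph = water_cylinder_215()
        # channel 455 is a hair off centre; use the exact fan centre instead
        c = chord_lengths(GEOM, ph, 455.5)
        assert c["water"] == pytest.approx(21.5)
        assert c["plexiglas"] == pytest.approx(2 * 113.5 / 10 - 21.5)

    def test_miss_returns_zero(self):
        ph = Phantom(fill_diameter=20.0, fill_material="water")
        c = chord_lengths(GEOM, ph, 0)
        assert c["water"] == 0.0

    def test_half_radius_offset_chord(self):
        # d = R/2  =>  chord = R * sqrt(3)
        R = 107.5
        ph = Phantom(fill_diameter=2 * R, fill_material="water")
        theta = math.degrees(math.asin((R / 2) / GEOM.source_to_iso))
        idx = theta / GEOM.channel_pitch_deg + 911 / 2
        c = chord_lengths(GEOM, ph, idx)
        assert c["water"] == pytest.approx(R * math.sqrt(3) / 10, rel=1e-9)

    def test_against_brute_force_ray_marcher(self):
        """Analytic chords agree with a 1 um ray march on random rays."""
        rng = np.random.default_rng(5)
        ph = water_cylinder_215()
        xc, r_fill, r_out = 540.0, ph.fill_radius, ph.outer_radius
        step = 1e-3  # mm
        t = np.arange(300.0, 800.0, step)
        for idx in rng.uniform(0, 911, size=100):
            theta = math.radians(channel_fan_angle(GEOM, idx))
            x, y = t * math.cos(theta), t * math.sin(theta)
            r2 = (x - xc) ** 2 + y ** 2
            fill_bf = np.count_nonzero(r2 < r_fill ** 2) * step / 10
            wall_bf = np.count_nonzero((r2 >= r_fill ** 2) & (r2 < r_out ** 2)) * step / 10
            c = chord_lengths(GEOM, ph, idx)
            assert c["water"] == pytest.approx(fill_bf, abs=2e-4, rel=1e-3)
            assert c["plexiglas"] == pytest.approx(wall_bf, abs=4e-4, rel=1e-3)

    def test_phantom_clearance_invariant(self):
        ph = Phantom(fill_diameter=215.0, fill_material="water", axial_offset=350.0)
        with pytest.raises(ConfigurationError):
            ph.validate_against(GEOM)


class TestShadowProjection:
    def test_magnification_value(self):
        assert GEOM.shadow_magnification == pytest.approx(950.0 / 160.0)

    def test_central_bar_shadow_is_centred(self):
        blocker = BlockerArray(bar_centers=(0.0,), bar_width=2.0)
        mask = project_shadow(GEOM, blocker)
        bar = mask.bars[0]
        assert bar.center_channel == pytest.approx(455.5, abs=1e-9)
        assert bar.core_lo + bar.core_hi == 911  # symmetric around the centre pair
        # a 2 mm bar magnified by 5.9375 covers ~11.7 channels of arc
        width = bar.core_hi - bar.core_lo + 1
        assert width in (10, 11, 12)

    def test_mirror_symmetry_of_intervals(self):
        blocker = BlockerArray(bar_centers=(-40.0, 40.0), bar_width=2.0)
        mask = project_shadow(GEOM, blocker, penumbra_margin=0)
        a, b = mask.bars
        assert a.core_lo == 911 - b.core_hi
        assert a.core_hi == 911 - b.core_lo

    def test_shadow_width_monotone_in_bar_width(self):
        widths = []
        for w in (1.0, 2.0, 4.0, 8.0):
            mask = project_shadow(GEOM, BlockerArray(bar_centers=(0.0,), bar_width=w))
            bar = mask.bars[0]
            widths.append(bar.core_hi - bar.core_lo + 1)
        assert all(b >= a for a, b in zip(widths, widths[1:]))

    def test_core_intervals_contiguous_and_disjoint_from_open(self):
        blocker = BlockerArray.default_layout(GEOM)
        mask = project_shadow(GEOM, blocker)
        assert len(mask.bars) == 20
        for bar in mask.bars:
            assert np.all(mask.labels[bar.core_lo:bar.core_hi + 1] == SHADOW_CORE)
        # every channel has exactly one label; shadow and open are disjoint
        assert set(np.unique(mask.labels)) <= {0, 1, 2}
        assert not np.any((mask.labels == SHADOW_CORE) & (mask.labels == OPEN))

    def test_bar_outside_fan_raises_naming_the_bar(self):
        blocker = BlockerArray(bar_centers=(0.0, 120.0), bar_width=2.0)
        with pytest.raises(ConfigurationError, match="bar 1"):
            project_shadow(GEOM, blocker)

    def test_overlapping_bars_rejected(self):
        with pytest.raises(ConfigurationError):
            BlockerArray(bar_centers=(0.0, 1.0), bar_width=2.0)
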
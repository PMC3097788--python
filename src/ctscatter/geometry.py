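"""Fan/cone-beam scanner geometry, phantom placement and blocker-shadow projection.

The scanner is modelled third-generation style: a point x-ray source, a detector
arc of constant radius centred on the source, equal-angle channel sampling across
the fan, and detector rows stacked along the rotation (z) axis.  The beam-stop
array sits in a plane between the source and the isocentre; each lead bar casts a
magnified shadow onto the detector arc, which is what the measurement method
exploits: channels inside a shadow see (almost) only scattered radiation, open
channels see total radiation.

Coordinates: the source is at the origin, the central ray points along +x, the
fan opens in the x-y plane, rows run along z.  Channel/row indices are 0-based
internally; user-facing reports label rows 1-64 so that "row 32" is the central
row of a 64-row scanner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScannerGeometry",
    "Phantom",
    "BlockerArray",
    "ShadowMask",
    "ConfigurationError",
    "channel_fan_angle",
    "chord_lengths",
    "project_shadow",
    "water_cylinder_215",
    "polypropylene_cylinder_300",
]


class ConfigurationError(ValueError):
    """An experiment configuration is internally inconsistent."""


@dataclass(frozen=True)
class ScannerGeometry:
    """Distances, counts and angular sampling of a multi-slice CT scanner.

    Defaults describe a 64-slice scanner with a 540 mm source-isocentre
    distance, 950 mm source-detector distance, a 56 degree fan sampled by
    912 channels per row (888 active patient elements plus 24 reference
    elements), 0.625 mm row pitch at isocentre, and a blocker plane 160 mm
    below the source.  All lengths are millimetres, angles degrees.
    """

    source_to_iso: float = 540.0
    source_to_detector: float = 950.0
    blocker_plane: float = 160.0
    n_rows: int = 64
    n_channels_total: int = 912
    n_channels_active: int = 888
    n_channels_reference: int = 24
    fan_angle: float = 56.0
    row_pitch_at_iso: float = 0.625

    def __post_init__(self) -> None:
        if not (0.0 < self.blocker_plane < self.source_to_iso < self.source_to_detector):
            raise ConfigurationError(
                "require 0 < blocker_plane < source_to_iso < source_to_detector, got "
                f"{self.blocker_plane}, {self.source_to_iso}, {self.source_to_detector}"
            )
        if self.n_channels_total != self.n_channels_active + self.n_channels_reference:
            raise ConfigurationError(
                "n_channels_total must equal n_channels_active + n_channels_reference"
            )
        if self.fan_angle <= 0:
            raise ConfigurationError("fan_angle must be positive")
        for name in ("n_rows", "n_channels_total", "n_channels_active", "n_channels_reference"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")

    # -- derived quantities -------------------------------------------------

    @property
    def channel_pitch_deg(self) -> float:
        """Angular pitch of one channel: fan_angle / n_channels_total."""
        return self.fan_angle / self.n_channels_total

    @property
    def shadow_magnification(self) -> float:
        """Geometric magnification of the blocker plane onto the detector."""
        return self.source_to_detector / self.blocker_plane

    @property
    def row_pitch_at_detector(self) -> float:
        return self.row_pitch_at_iso * self.source_to_detector / self.source_to_iso

    @property
    def detector_half_height(self) -> float:
        """Half the detector z-extent (mm at the detector)."""
        return 0.5 * self.n_rows * self.row_pitch_at_detector

    @property
    def n_elements(self) -> int:
        """Total number of individual detector elements."""
        return self.n_rows * self.n_channels_total

    def channel_angles_deg(self) -> np.ndarray:
        """Fan angles of every channel centre (degrees, antisymmetric)."""
        idx = np.arange(self.n_channels_total, dtype=float)
        return (idx - (self.n_channels_total - 1) / 2.0) * self.channel_pitch_deg

    def row_z_edges(self) -> np.ndarray:
        """z coordinates (mm, at the detector) of the n_rows+1 row boundaries."""
        j = np.arange(self.n_rows + 1, dtype=float)
        return (j - self.n_rows / 2.0) * self.row_pitch_at_detector

    def reference_channel_indices(self) -> np.ndarray:
        """The reference elements, modelled as the outermost channels at each fan edge."""
        half = self.n_channels_reference // 2
        return np.concatenate(
            [np.arange(half), np.arange(self.n_channels_total - (self.n_channels_reference - half),
                                        self.n_channels_total)]
        )


def channel_fan_angle(geom: ScannerGeometry, channel_index: float) -> float:
    """Fan angle (degrees) of a channel centre; fractional indices allowed.

    The fan centre lies midway between the two central channels (between
    channels 455 and 456 for 912 channels, 0-based), so the angular grid is
    antisymmetric about index (n-1)/2.
    """
    if channel_index < 0 or channel_index > geom.n_channels_total - 1:
        raise ConfigurationError(
            f"channel index {channel_index} outside [0, {geom.n_channels_total - 1}]"
        )
    return (channel_index - (geom.n_channels_total - 1) / 2.0) * geom.channel_pitch_deg


@dataclass(frozen=True)
class Phantom:
    """A cylindrical phantom, axis along z, centred laterally on the beam axis.

    ``axial_offset`` shifts the cylinder along the source->detector axis
    (positive toward the detector), which is the off-centring studied for the
    air-gap effect.  ``wall_thickness`` of 0 means a solid uniform cylinder.
    """

    fill_diameter: float
    fill_material: str
    wall_thickness: float = 0.0
    wall_material: str | None = None
    axial_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.fill_diameter <= 0:
            raise ConfigurationError("fill_diameter must be positive")
        if self.wall_thickness < 0:
            raise ConfigurationError("wall_thickness must be >= 0")
        if self.wall_thickness > 0 and not self.wall_material:
            raise ConfigurationError("wall_material required when wall_thickness > 0")

    @property
    def fill_radius(self) -> float:
        return self.fill_diameter / 2.0

    @property
    def outer_radius(self) -> float:
        return self.fill_radius + self.wall_thickness

    def centre_x(self, geom: ScannerGeometry) -> float:
        """x position of the cylinder axis (mm from the source)."""
        return geom.source_to_iso + self.axial_offset

    def validate_against(self, geom: ScannerGeometry) -> None:
        clearance = min(geom.source_to_iso, geom.source_to_detector - geom.source_to_iso)
        if abs(self.axial_offset) + self.outer_radius >= clearance:
            raise ConfigurationError(
                "phantom intersects source or detector: "
                f"|offset| + radius = {abs(self.axial_offset) + self.outer_radius:.1f} mm "
                f">= clearance {clearance:.1f} mm"
            )


def water_cylinder_215() -> Phantom:
    """The 215 mm internal-diameter water cylinder with a 6 mm Plexiglas wall."""
    return Phantom(fill_diameter=215.0, fill_material="water",
                   wall_thickness=6.0, wall_material="plexiglas")


def polypropylene_cylinder_300() -> Phantom:
    """The uniform 300 mm polypropylene cylinder (obese-subject surrogate)."""
    return Phantom(fill_diameter=300.0, fill_material="polypropylene")


def chord_lengths(geom: ScannerGeometry, phantom: Phantom, channel_index: float) -> dict[str, float]:
    """Intersection lengths (cm) of a source->channel ray with the phantom.

    Returns a mapping material name -> path length in cm.  A ray at
    perpendicular distance d from the cylinder axis crosses a chord
    2*sqrt(R^2 - d^2) of the radius-R cylinder when d < R, else nothing;
    the wall contribution is the outer-cylinder chord minus the fill chord.
    Misses return zeros rather than raising.
    """
    theta = math.radians(channel_fan_angle(geom, channel_index))
    xc = phantom.centre_x(geom)
    d = abs(xc * math.sin(theta))

    def chord(radius_mm: float) -> float:
        if d >= radius_mm:
            return 0.0
        return 2.0 * math.sqrt(radius_mm * radius_mm - d * d)

    fill_mm = chord(phantom.fill_radius)
    out = {phantom.fill_material: fill_mm / 10.0}
    if phantom.wall_thickness > 0 and phantom.wall_material:
        wall_mm = chord(phantom.outer_radius) - fill_mm
        out[phantom.wall_material] = max(wall_mm, 0.0) / 10.0
    return out


@dataclass(frozen=True)
class BlockerArray:
    """The 1-D beam-stop array: parallel lead bars in the blocker plane.

    Bars run parallel to the row (z) axis, so a single shadow mask applies to
    every detector row.  ``bar_centers`` are signed lateral positions (mm) in
    the blocker plane; ``bar_width`` is lateral, ``bar_thickness`` along the
    beam (3 mm of lead in the reference setup).
    """

    bar_centers: tuple[float, ...]
    bar_width: float = 2.0
    bar_thickness: float = 3.0
    material: str = "lead"

    def __post_init__(self) -> None:
        centers = sorted(self.bar_centers)
        for a, b in zip(centers, centers[1:]):
            if b - a < self.bar_width:
                raise ConfigurationError(
                    f"bars at {a} mm and {b} mm overlap (width {self.bar_width} mm)"
                )
        if self.bar_width <= 0 or self.bar_thickness <= 0:
            raise ConfigurationError("bar dimensions must be positive")

    @property
    def n_bars(self) -> int:
        return len(self.bar_centers)

    @classmethod
    def default_layout(cls, geom: ScannerGeometry, n_bars: int = 20,
                       bar_width: float = 2.0, bar_thickness: float = 3.0,
                       coverage: float = 0.9) -> "BlockerArray":
        """Evenly space ``n_bars`` across the central ``coverage`` fraction of
        the fan width at the blocker plane, leaving open channels between
        shadows for total-profile sampling."""
        half = geom.blocker_plane * math.tan(math.radians(geom.fan_angle / 2.0)) * coverage
        centers = tuple(np.linspace(-half, half, n_bars))
        return cls(bar_centers=centers, bar_width=bar_width, bar_thickness=bar_thickness)


# channel labels in a ShadowMask
OPEN = 0
PENUMBRA = 1
SHADOW_CORE = 2


@dataclass(frozen=True)
class BarShadow:
    """One bar's footprint on the detector, in channel coordinates."""

    bar_index: int
    core_lo: int            # first fully shadowed channel
    core_hi: int            # last fully shadowed channel (inclusive)
    center_channel: float   # continuous channel coordinate of the shadow centre


@dataclass(frozen=True)
class ShadowMask:
    """Per-channel shadow labelling plus per-bar interval records.

    ``labels`` assigns each channel exactly one of OPEN / PENUMBRA /
    SHADOW_CORE; ``coverage`` is the geometric fraction of each channel
    covered by a bar shadow (used for the partial edge channels of the
    primary model); ``bars`` lists one contiguous core interval per bar.
    """

    labels: np.ndarray
    coverage: np.ndarray
    bars: tuple[BarShadow, ...]
    penumbra_margin: int = 2

    @property
    def shadow_core_channels(self) -> np.ndarray:
        return np.flatnonzero(self.labels == SHADOW_CORE)

    @property
    def open_channels(self) -> np.ndarray:
        return np.flatnonzero(self.labels == OPEN)


def project_shadow(geom: ScannerGeometry, blocker: BlockerArray,
                   penumbra_margin: int = 2) -> ShadowMask:
    """Project the blocker bars from the point source onto the detector arc.

    Each bar's lateral extent in the blocker plane maps through the source to
    an angular interval, magnified by source_to_detector / blocker_plane on
    the detector arc.  Channels fully inside an interval are SHADOW_CORE;
    partially covered edge channels and ``penumbra_margin`` additional
    channels on each side are PENUMBRA (excluded from both scatter and total
    sampling); the rest stay OPEN.  The source is a point, so the penumbra
    margin is purely an interpolation guard.
    """
    if penumbra_margin < 0:
        raise ConfigurationError("penumbra_margin must be >= 0")
    n = geom.n_channels_total
    pitch = geom.channel_pitch_deg
    half_fan = geom.fan_angle / 2.0
    labels = np.zeros(n, dtype=np.int8)
    coverage = np.zeros(n, dtype=float)
    bars: list[BarShadow] = []

    for b, c in enumerate(blocker.bar_centers):
        lo_mm, hi_mm = c - blocker.bar_width / 2.0, c + blocker.bar_width / 2.0
        ang_lo = math.degrees(math.atan2(lo_mm, geom.blocker_plane))
        ang_hi = math.degrees(math.atan2(hi_mm, geom.blocker_plane))
        if ang_lo < -half_fan or ang_hi > half_fan:
            raise ConfigurationError(
                f"bar {b} at {c:+.1f} mm falls outside the {geom.fan_angle} deg fan"
            )
        # continuous channel coordinates of the shadow edges
        u_lo = ang_lo / pitch + (n - 1) / 2.0
        u_hi = ang_hi / pitch + (n - 1) / 2.0
        # channel i covers [i - 0.5, i + 0.5]
        i = np.arange(max(0, math.floor(u_lo - 0.5)), min(n, math.ceil(u_hi + 1.5)))
        frac = np.clip(np.minimum(i + 0.5, u_hi) - np.maximum(i - 0.5, u_lo), 0.0, 1.0)
        coverage[i] = np.maximum(coverage[i], frac)

        core_lo = math.ceil(u_lo + 0.5 - 1e-9)
        core_hi = math.floor(u_hi - 0.5 + 1e-9)
        if core_hi < core_lo:
            raise ConfigurationError(
                f"bar {b} at {c:+.1f} mm shadows no full channel "
                f"(width {blocker.bar_width} mm too small for this geometry)"
            )
        labels[core_lo:core_hi + 1] = SHADOW_CORE
        pen_lo = max(0, core_lo - penumbra_margin - 1)
        pen_hi = min(n - 1, core_hi + penumbra_margin + 1)
        for span in (slice(pen_lo, core_lo), slice(core_hi + 1, pen_hi + 1)):
            seg = labels[span]
            seg[seg == OPEN] = PENUMBRA
        bars.append(BarShadow(bar_index=b, core_lo=core_lo, core_hi=core_hi,
                              center_channel=(u_lo + u_hi) / 2.0))

    return ShadowMask(labels=labels, coverage=coverage, bars=tuple(bars),
                      penumbra_margin=penumbra_margin)
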
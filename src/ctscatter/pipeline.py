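"""The blocker-array measurement algorithm: from a decalibrated two-exposure
acquisition to scatter, primary and SPR profiles.

The method: detector channels inside the lead-bar shadows record (essentially)
scatter alone; open channels record total radiation.  Per detector row, the
shadow samples are interpolated across all channels to give the scatter
profile, the open-channel readings are interpolated across the shadow gaps to
give the total profile, primary is total minus scatter, and the
scatter-to-primary ratio (SPR) follows per channel.  The integrated SPR of a
row is the sum of its per-channel SPR.  Blocker self-scatter is compensated by
subtracting the phantom-free exposure on the shadowed channels.

The module follows the estimator-object convention: build a
:class:`BlockerScatterModel` from the two frames, call :meth:`fit`, read the
profiles and diagnostics off the returned :class:`BlockerScatterResults`.
The underlying steps are exposed as plain functions as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .geometry import (OPEN, PENUMBRA, SHADOW_CORE, BlockerArray, ConfigurationError,
                       ScannerGeometry, ShadowMask, project_shadow)
from .raw_io import CalibrationTable, DetectorFrame, decalibrate, read_frame

__all__ = [
    "ScatterProfile", "BlockerScatterModel", "BlockerScatterResults",
    "compensate_blocker_scatter", "sample_shadow_scatter", "interpolate_scatter",
    "total_profile", "primary_profile", "spr_profile", "integrated_spr",
    "run_study",
]


@dataclass(frozen=True)
class ScatterProfile:
    """Interpolated scatter over all channels of one row, with provenance."""

    values: np.ndarray
    sample_positions: np.ndarray
    sample_values: np.ndarray
    interpolation: str = "pchip"

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("scatter profile must be finite and non-negative")


def compensate_blocker_scatter(with_phantom: DetectorFrame,
                               without_phantom: DetectorFrame,
                               mask: ShadowMask) -> DetectorFrame:
    """Remove the blocker's own scatter from the shadowed channels.

    Subtracts the phantom-free exposure element-wise on shadowed channels only
    (shadow core and penumbra); open channels of the phantom-free frame carry
    the full primary flux and must not be subtracted.  Clamped at zero.
    """
    for f, want_ph in ((with_phantom, True), (without_phantom, False)):
        if f.meta.calibrated:
            raise ValueError("frames must be decalibrated before compensation")
        if not f.meta.blocker_present:
            raise ValueError("both frames must carry the blocker")
        if f.meta.phantom_present != want_ph:
            raise ValueError("phantom flags must be (True, False) for the frame pair")
    if with_phantom.shape != without_phantom.shape:
        raise ValueError("frame shapes differ")
    shadowed = mask.labels != OPEN
    readings = with_phantom.readings.copy()
    readings[:, shadowed] = np.clip(
        readings[:, shadowed] - without_phantom.readings[:, shadowed], 0.0, None)
    return DetectorFrame(readings=readings,
                         meta=replace(with_phantom.meta, compensated=True))


def sample_shadow_scatter(frame: DetectorFrame, mask: ShadowMask):
    """One scatter sample per bar per row: the mean reading over the bar's
    shadow-core channels (penumbra excluded), positioned at the shadow centre.

    Returns ``(positions, samples)`` with positions shape (n_bars,) in
    continuous channel coordinates and samples shape (n_rows, n_bars).
    """
    if not frame.meta.compensated:
        raise ValueError("frame must be blocker-compensated before shadow sampling")
    positions = []
    cols = []
    for bar in mask.bars:
        core = np.arange(bar.core_lo, bar.core_hi + 1)
        if core.size == 0:
            raise ConfigurationError(f"bar {bar.bar_index} has no shadow-core channels")
        positions.append(bar.center_channel)
        cols.append(frame.readings[:, core].mean(axis=1))
    return np.asarray(positions), np.column_stack(cols)


def interpolate_scatter(positions: np.ndarray, samples: np.ndarray,
                        n_channels: int) -> ScatterProfile:
    """Monotone-preserving piecewise-cubic interpolation of one row's shadow
    samples over every channel; constant extrapolation beyond the outermost
    samples; negative values clamped to zero."""
    positions = np.asarray(positions, dtype=float)
    samples = np.asarray(samples, dtype=float)
    if positions.size < 2:
        raise ValueError("need at least 2 shadow samples to interpolate")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("sample positions must be strictly increasing")
    x = np.arange(n_channels, dtype=float)
    interp = PchipInterpolator(positions, samples, extrapolate=False)
    vals = interp(x)
    vals[x <= positions[0]] = samples[0]
    vals[x >= positions[-1]] = samples[-1]
    return ScatterProfile(values=np.clip(vals, 0.0, None),
                          sample_positions=positions, sample_values=samples)


def total_profile(row_readings: np.ndarray, mask: ShadowMask) -> np.ndarray:
    """Total radiation over all channels of one row: open channels taken
    directly, shadow and penumbra channels filled by the same
    monotone-cubic interpolation applied to the open-channel readings."""
    row = np.asarray(row_readings, dtype=float)
    open_idx = mask.open_channels
    if open_idx.size == row.size:
        return row.copy()
    x = np.arange(row.size, dtype=float)
    interp = PchipInterpolator(open_idx.astype(float), row[open_idx], extrapolate=False)
    filled = row.copy()
    gaps = mask.labels != OPEN
    vals = interp(x[gaps])
    # constant fill beyond the outermost open channels
    vals = np.where(x[gaps] < open_idx[0], row[open_idx[0]], vals)
    vals = np.where(x[gaps] > open_idx[-1], row[open_idx[-1]], vals)
    filled[gaps] = np.clip(vals, 0.0, None)
    return filled


def primary_profile(total: np.ndarray, scatter: np.ndarray) -> np.ndarray:
    """Primary radiation: total minus scatter, clamped at zero."""
    total = np.asarray(total, dtype=float)
    scatter = np.asarray(scatter, dtype=float)
    if total.shape != scatter.shape:
        raise ValueError("total and scatter lengths differ")
    return np.clip(total - scatter, 0.0, None)


def spr_profile(scatter: np.ndarray, primary: np.ndarray,
                primary_floor: float = 1e-3):
    """Per-channel SPR = scatter / primary, masked where primary falls below
    ``primary_floor`` times the row's maximum primary.

    Returns ``(spr, defined)``; ``spr`` is NaN where not defined.
    """
    scatter = np.asarray(scatter, dtype=float)
    primary = np.asarray(primary, dtype=float)
    if scatter.shape != primary.shape:
        raise ValueError("scatter and primary lengths differ")
    if not 0.0 < primary_floor < 1.0:
        raise ValueError("primary_floor must be in (0, 1)")
    defined = primary > primary_floor * primary.max()
    if not defined.any():
        raise ValueError("degenerate input: primary below floor at every channel")
    spr = np.full_like(scatter, np.nan)
    spr[defined] = scatter[defined] / primary[defined]
    return spr, defined


def integrated_spr(spr: np.ndarray, defined: np.ndarray) -> float:
    """Sum of the SPR over all channels of a row, masked channels contributing 0."""
    return float(np.where(defined, spr, 0.0).sum())


@dataclass(frozen=True)
class BlockerScatterResults:
    """Estimates from one acquisition pair.

    All matrices are rows x channels in decalibrated detector units; ``spr``
    is NaN where the primary fell below the validity floor.  Rows are 0-based
    internally; :meth:`summary` and the exported tables label them 1-based.
    """

    model: "BlockerScatterModel"
    scatter: np.ndarray
    total: np.ndarray
    primary: np.ndarray
    spr: np.ndarray
    spr_defined: np.ndarray
    integrated_spr: np.ndarray          # per row
    shadow_positions: np.ndarray
    shadow_samples: np.ndarray          # rows x bars
    rows: tuple[int, ...] = ()          # 0-based rows actually fitted

    def row_table(self, row: int) -> pd.DataFrame:
        """Per-channel profiles for one 0-based row."""
        n = self.scatter.shape[1]
        return pd.DataFrame({
            "channel": np.arange(n),
            "scatter": self.scatter[row],
            "total": self.total[row],
            "primary": self.primary[row],
            "spr": self.spr[row],
        })

    def integrated_table(self) -> pd.DataFrame:
        return pd.DataFrame({"row": np.arange(1, self.integrated_spr.size + 1),
                             "integrated_spr": self.integrated_spr})

    def summary(self, row: int = 31) -> str:
        m = self.model
        meta = m.with_phantom.meta
        n_rows, n_ch = self.scatter.shape
        lines = [
            "Blocker-array scatter measurement",
            "=" * 49,
            f"frames:            {n_rows} rows x {n_ch} channels",
            f"tube:              {meta.kvp:.0f} kVp, {meta.tube_current_ma:.0f} mA, "
            f"{meta.exposure_s:.1f} s",
            f"bars sampled:      {self.shadow_positions.size}",
            f"interpolation:     {m.interpolation} over shadow centres",
            f"primary floor:     {m.primary_floor:g} x row max",
            "-" * 49,
            f"row {row + 1:d} (1-based):",
            f"  scatter at fan centre:   {self.scatter[row, n_ch // 2]:.6g}",
            f"  primary at fan centre:   {self.primary[row, n_ch // 2]:.6g}",
            f"  SPR at fan centre:       {self.spr[row, n_ch // 2]:.4f}",
            f"  integrated SPR:          {self.integrated_spr[row]:.2f}",
            f"  channels masked:         {int((~self.spr_defined[row]).sum())}",
            "-" * 49,
        ]
        fitted = self.integrated_spr[list(self.rows)] if self.rows else self.integrated_spr
        lines.append(f"integrated SPR over {len(fitted)} fitted row(s): "
                     f"min {fitted.min():.2f}, max {fitted.max():.2f}")
        return "\n".join(lines)

    def plot_profiles(self, row: int = 31, ax=None):
        """Scatter/total/primary profiles and SPR for one row."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 5))
        t = self.row_table(row)
        ax.plot(t.channel, t.total, label="total", lw=1)
        ax.plot(t.channel, t.primary, label="primary", lw=1)
        ax.plot(t.channel, t.scatter, label="scatter", lw=1)
        ax.plot(self.shadow_positions, self.shadow_samples[row], "k.", ms=4,
                label="shadow samples")
        ax.set_xlabel("channel")
        ax.set_ylabel("detector units")
        ax.set_title(f"row {row + 1}")
        ax.legend()
        return ax


class BlockerScatterModel:
    """Scatter/SPR estimator for one two-exposure blocker acquisition.

    Parameters
    ----------
    with_phantom, without_phantom
        Decalibrated frames: blocker present in both, phantom in the first
        only.
    geometry, blocker
        The scanner geometry and bar layout used to project the shadow mask
        (alternatively pass a precomputed ``mask``).
    penumbra_margin
        Channels excluded on each side of every shadow core (interpolation
        guard; the point source casts no physical penumbra).
    primary_floor
        Validity floor for the SPR denominator, as a fraction of the row's
        maximum primary.
    """

    def __init__(self, with_phantom: DetectorFrame, without_phantom: DetectorFrame,
                 geometry: ScannerGeometry, blocker: BlockerArray | None = None,
                 mask: ShadowMask | None = None, penumbra_margin: int = 2,
                 primary_floor: float = 1e-3, interpolation: str = "pchip"):
        if mask is None:
            if blocker is None:
                raise ValueError("provide either a blocker layout or a shadow mask")
            mask = project_shadow(geometry, blocker, penumbra_margin=penumbra_margin)
        if interpolation != "pchip":
            raise ValueError("only monotone piecewise-cubic ('pchip') is implemented")
        self.with_phantom = with_phantom
        self.without_phantom = without_phantom
        self.geometry = geometry
        self.mask = mask
        self.primary_floor = primary_floor
        self.interpolation = interpolation

    @classmethod
    def from_files(cls, with_path: str | Path, without_path: str | Path,
                   calibration: CalibrationTable, geometry: ScannerGeometry,
                   blocker: BlockerArray | None = None, **kwargs) -> "BlockerScatterModel":
        """Read two raw frames, apply the calibration inversely, build the model."""
        frames = []
        for p in (with_path, without_path):
            f = read_frame(p)
            frames.append(decalibrate(f, calibration) if f.meta.calibrated else f)
        return cls(frames[0], frames[1], geometry, blocker=blocker, **kwargs)

    def fit(self, rows: list[int] | None = None) -> BlockerScatterResults:
        """Run the measurement chain; per-row processing is independent."""
        comp = compensate_blocker_scatter(self.with_phantom, self.without_phantom,
                                          self.mask)
        positions, samples = sample_shadow_scatter(comp, self.mask)
        n_rows, n_ch = comp.shape
        sel = range(n_rows) if rows is None else rows
        scatter = np.zeros((n_rows, n_ch))
        total = np.zeros_like(scatter)
        primary = np.zeros_like(scatter)
        spr = np.full_like(scatter, np.nan)
        defined = np.zeros_like(scatter, dtype=bool)
        ispr = np.zeros(n_rows)
        for r in sel:
            prof = interpolate_scatter(positions, samples[r], n_ch)
            scatter[r] = prof.values
            total[r] = total_profile(comp.readings[r], self.mask)
            primary[r] = primary_profile(total[r], scatter[r])
            spr[r], defined[r] = spr_profile(scatter[r], primary[r],
                                             self.primary_floor)
            ispr[r] = integrated_spr(spr[r], defined[r])
        return BlockerScatterResults(
            model=self, scatter=scatter, total=total, primary=primary,
            spr=spr, spr_defined=defined, integrated_spr=ispr,
            shadow_positions=positions, shadow_samples=samples,
            rows=tuple(sel))


def run_study(manifest_path: str | Path, out_dir: str | Path,
              geometry: ScannerGeometry | None = None,
              blocker: BlockerArray | None = None,
              calibration: CalibrationTable | None = None,
              row: int = 32) -> dict[str, Path]:
    """Analyse every acquisition pair in a simulator manifest.

    Writes per-channel profile tables for the chosen (1-based) row, an
    integrated-SPR table (all rows x all acquisitions), an off-centring trend
    table, and a run log.  Deterministic given the manifest.
    """
    geometry = geometry or ScannerGeometry()
    blocker = blocker or BlockerArray.default_layout(geometry)
    calibration = calibration or CalibrationTable.identity(
        geometry.n_rows, geometry.n_channels_total)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(manifest_path, sep="\t")
    r0 = row - 1

    integrated = {}
    trend_rows = []
    log = [f"blocker-array study: {len(manifest)} acquisition pairs, row {row}"]
    outputs: dict[str, Path] = {}
    for _, entry in manifest.iterrows():
        missing = [p for p in (entry.phantom_frame, entry.blocker_frame)
                   if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"manifest entry {entry.tag}: missing {missing}")
        model = BlockerScatterModel.from_files(entry.phantom_frame, entry.blocker_frame,
                                               calibration, geometry, blocker=blocker)
        res = model.fit()
        tag = str(entry.tag)
        prof_path = out_dir / f"profiles_{tag}.tsv"
        res.row_table(r0).to_csv(prof_path, sep="\t", index=False, float_format="%.8e")
        outputs[f"profiles_{tag}"] = prof_path
        integrated[tag] = res.integrated_spr
        trend_rows.append({"tag": tag, "kvp": entry.kvp,
                           "fill_material": entry.fill_material,
                           "fill_diameter_mm": entry.fill_diameter_mm,
                           "axial_offset_mm": entry.axial_offset_mm,
                           "integrated_spr_row": res.integrated_spr[r0]})
        log.append(f"  {tag}: integrated SPR(row {row}) = {res.integrated_spr[r0]:.3f}")

    ispr = pd.DataFrame(integrated)
    ispr.insert(0, "row", np.arange(1, geometry.n_rows + 1))
    ispr_path = out_dir / "integrated_spr.tsv"
    ispr.to_csv(ispr_path, sep="\t", index=False, float_format="%.6e")
    outputs["integrated_spr"] = ispr_path

    trend = pd.DataFrame(trend_rows)
    offc = trend[trend.axial_offset_mm != 0.0]
    if len(offc):
        sweep = trend[(trend.kvp == 120.0) & (trend.fill_material == "water")] \
            .sort_values("axial_offset_mm")
        sweep_path = out_dir / "offcenter_trend.tsv"
        sweep.to_csv(sweep_path, sep="\t", index=False, float_format="%.6e")
        outputs["offcenter_trend"] = sweep_path
    trend_path = out_dir / "acquisition_trend.tsv"
    trend.to_csv(trend_path, sep="\t", index=False, float_format="%.6e")
    outputs["acquisition_trend"] = trend_path

    (out_dir / "run.log").write_text("\n".join(log) + "\n")
    outputs["log"] = out_dir / "run.log"
    return outputs
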
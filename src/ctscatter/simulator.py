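"""Synthetic two-exposure acquisitions: Beer-Lambert primary plus single-scatter
Compton transport, written as raw frames with a ground-truth sidecar.

The simulator generates exactly the data the blocker method consumes: one
exposure with the beam-stop array alone and one with the phantom added, both
as raw detector frames, together with the uncalibrated primary and scatter
matrices for parameter-recovery testing.

Two scatter engines share one physics model (see :mod:`ctscatter._kernels`):

* ``simulate_scatter_mc`` -- analog Monte Carlo: photons sampled per channel
  ray, one forced interaction in the fill, Klein-Nishina direction sampling,
  deposit at the element the exit ray hits.  Returns per-element standard
  errors alongside the estimate.
* ``simulate_scatter_deterministic`` -- quadrature over the identical chain
  (steps along each chord, all exit channels, per-row out-of-plane slices).
  This is the expected value of the Monte Carlo estimator and serves both as
  its convergence oracle and as the noise-free ground truth for rendered
  acquisitions.

Tube output follows the standard heuristic photons ∝ mA · s · kVp²; absolute
units are arbitrary and cancel in every scatter-to-primary ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import _kernels
from .geometry import (BlockerArray, ConfigurationError, Phantom, ScannerGeometry,
                       project_shadow, water_cylinder_215, polypropylene_cylinder_300)
from .physics import (KN_THETA_GRID, Spectrum, blocker_transmission, compton_fraction,
                      generate_spectrum, get_material, klein_nishina, kn_total_angular)
from .raw_io import CalibrationTable, DetectorFrame, FrameMeta, calibrate, write_frame

__all__ = [
    "AcquisitionSetup", "GroundTruth",
    "simulate_primary", "simulate_scatter_mc", "simulate_scatter_deterministic",
    "render_acquisition_pair", "make_study_fixtures",
]


@dataclass(frozen=True)
class AcquisitionSetup:
    """Everything needed to simulate one exposure."""

    geometry: ScannerGeometry
    spectrum: Spectrum
    phantom: Phantom | None = None
    blocker: BlockerArray | None = None
    tube_current: float = 100.0    # mA
    exposure_time: float = 3.0     # s
    n_photons: int = 1_000_000
    seed: int = 0
    noise: str = "off"             # off | poisson
    multiple_scatter_factor: float = 1.0  # uniform surrogate for unmodelled rescatter

    def __post_init__(self) -> None:
        if self.tube_current <= 0 or self.exposure_time <= 0:
            raise ConfigurationError("tube_current and exposure_time must be positive")
        if self.n_photons < 0:
            raise ConfigurationError("n_photons must be >= 0")
        if self.noise not in ("off", "poisson"):
            raise ConfigurationError(f"unknown noise mode {self.noise!r}")
        if self.multiple_scatter_factor < 0:
            raise ConfigurationError("multiple_scatter_factor must be >= 0")
        if self.phantom is not None:
            self.phantom.validate_against(self.geometry)

    @property
    def tube_output(self) -> float:
        """Photon-fluence scale per incident ray (arbitrary units)."""
        return self.tube_current * self.exposure_time * self.spectrum.kvp ** 2


@dataclass(frozen=True)
class GroundTruth:
    """Simulator-only truth for parameter-recovery tests.

    Pre-noise, pre-calibration: total frame = primary + scatter exactly.
    ``primary_unblocked`` is the same Beer-Lambert primary without the
    beam-stop shadow factor -- the field the pipeline reconstructs when it
    interpolates the total profile across the bar shadows.  ``scatter_se``
    holds per-element Monte Carlo standard errors (zeros for the quadrature
    engine, whose result is an expectation, not an estimate).
    """

    primary: np.ndarray
    scatter: np.ndarray
    scatter_se: np.ndarray
    primary_unblocked: np.ndarray | None = None
    rows: tuple[int, ...] | None = None

    @property
    def total(self) -> np.ndarray:
        return self.primary + self.scatter

    def save(self, path: str | Path, meta: dict | None = None) -> Path:
        path = Path(path)
        n_rows, n_ch = self.primary.shape
        lines = ["# ctscatter ground-truth sidecar",
                 f"shape: {n_rows} {n_ch}",
                 f"rows: {'all' if self.rows is None else ' '.join(map(str, self.rows))}"]
        for k, v in (meta or {}).items():
            lines.append(f"{k}: {v}")
        blocks = []
        named = [("PRIMARY", self.primary), ("SCATTER", self.scatter),
                 ("SCATTER_SE", self.scatter_se)]
        if self.primary_unblocked is not None:
            named.append(("PRIMARY_UNBLOCKED", self.primary_unblocked))
        for name, arr in named:
            blocks.append(f"## {name}")
            blocks.extend(" ".join(f"{x:.9e}" for x in row) for row in arr)
        path.write_text("\n".join(lines + blocks) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        lines = Path(path).read_text().splitlines()
        shape = rows = None
        arrays: dict[str, list[list[float]]] = {}
        current = None
        for line in lines:
            if line.startswith("#") and not line.startswith("##"):
                continue
            if line.startswith("## "):
                current = line[3:].strip()
                arrays[current] = []
            elif current is not None:
                arrays[current].append([float(x) for x in line.split()])
            elif line.startswith("shape:"):
                shape = tuple(int(x) for x in line.split(":")[1].split())
            elif line.startswith("rows:"):
                val = line.split(":", 1)[1].strip()
                rows = None if val == "all" else tuple(int(x) for x in val.split())
        if shape is None or "PRIMARY" not in arrays:
            raise IOError(f"{path}: not a ground-truth sidecar")
        unb = arrays.get("PRIMARY_UNBLOCKED")
        return cls(primary=np.array(arrays["PRIMARY"]),
                   scatter=np.array(arrays["SCATTER"]),
                   scatter_se=np.array(arrays["SCATTER_SE"]),
                   primary_unblocked=None if unb is None else np.array(unb),
                   rows=rows)


# ---------------------------------------------------------------------------
# shared precomputation

def _incident_blocker_factor(setup: AcquisitionSetup) -> np.ndarray:
    """Per-channel transmission factor of the beam-stop array for the incident
    beam: 1 for open channels, exp(-mu_Pb t) in a shadow core, a linear mix for
    partially covered edge channels."""
    n = setup.geometry.n_channels_total
    if setup.blocker is None:
        return np.ones(n)
    mask = project_shadow(setup.geometry, setup.blocker, penumbra_margin=0)
    t_bar = blocker_transmission(setup.blocker.bar_thickness / 10.0)
    return 1.0 - mask.coverage + mask.coverage * t_bar


def _arc_coords(geom: ScannerGeometry):
    alpha = np.radians(geom.channel_angles_deg())
    edges = np.radians((np.arange(geom.n_channels_total + 1) - geom.n_channels_total / 2.0)
                       * geom.channel_pitch_deg)
    r = geom.source_to_detector
    return (alpha, r * np.cos(alpha), r * np.sin(alpha),
            r * np.cos(edges), r * np.sin(edges))


_FINE_E0, _FINE_STEP = 4.0, 0.25


def _fine_mu(material_name: str | None) -> np.ndarray:
    """Attenuation (mm^-1) on a fine energy grid for scattered-photon lookup."""
    e = np.arange(_FINE_E0, 150.0 + _FINE_STEP, _FINE_STEP)
    if material_name is None:
        return np.zeros_like(e)
    mat = get_material(material_name)
    return mat.linear_attenuation(e, extrapolate=True) / 10.0


def _spectral_tables(setup: AcquisitionSetup):
    ph = setup.phantom
    e = setup.spectrum.energies
    w = setup.spectrum.fluence
    fill = get_material(ph.fill_material)
    mu_f = fill.linear_attenuation(e) / 10.0
    if ph.wall_thickness > 0 and ph.wall_material:
        mu_w = get_material(ph.wall_material).linear_attenuation(e) / 10.0
        wall_fine = _fine_mu(ph.wall_material)
    else:
        mu_w = np.zeros_like(mu_f)
        wall_fine = _fine_mu(None)
    fc = np.atleast_1d(compton_fraction(fill, e))
    sigma = np.atleast_1d(kn_total_angular(e))
    return e, w, mu_f, mu_w, fc, sigma, _fine_mu(ph.fill_material), wall_fine


# ---------------------------------------------------------------------------
# primary

def simulate_primary(setup: AcquisitionSetup) -> np.ndarray:
    """Beer-Lambert primary signal, rows x channels (energy-integrating detector).

    Per channel: tube_output * sum_E fluence(E) * E * exp(-sum_m mu_m(E) l_m) * B,
    with l_m the per-material chord lengths and B the blocker shadow factor.
    Rows are identical (the cone obliquity of at most ~2 deg is neglected).
    """
    geom = setup.geometry
    e = setup.spectrum.energies
    w = setup.spectrum.fluence
    att = np.ones((geom.n_channels_total, e.size))
    if setup.phantom is not None:
        setup.phantom.validate_against(geom)
        ph = setup.phantom
        alpha = np.radians(geom.channel_angles_deg())
        d = np.abs(ph.centre_x(geom) * np.sin(alpha))
        def chord_cm(radius_mm):
            return 2.0 * np.sqrt(np.clip(radius_mm ** 2 - d ** 2, 0.0, None)) / 10.0
        l_fill = chord_cm(ph.fill_radius)
        mu = get_material(ph.fill_material).linear_attenuation(e)
        att = np.exp(-np.outer(l_fill, mu))
        if ph.wall_thickness > 0 and ph.wall_material:
            l_wall = chord_cm(ph.outer_radius) - l_fill
            mu_w = get_material(ph.wall_material).linear_attenuation(e)
            att *= np.exp(-np.outer(l_wall, mu_w))
    profile = setup.tube_output * (att * (w * e)).sum(axis=1)
    profile *= _incident_blocker_factor(setup)
    return np.tile(profile, (geom.n_rows, 1))


# ---------------------------------------------------------------------------
# scatter engines

def _require_phantom(setup: AcquisitionSetup) -> Phantom:
    if setup.phantom is None:
        raise ConfigurationError("scatter simulation requires a phantom in the beam")
    return setup.phantom


def _cone_half_width(setup: AcquisitionSetup) -> float:
    """Half z-extent of the illuminated cone at the phantom centre (mm).

    The collimated beam spans the full detector z-aperture; its width at any
    depth scales with distance from the source.  The illumination is frozen
    laterally at the phantom-centre depth (the cone half-angle is ~2 deg, so
    the variation across the phantom is a few mm).
    """
    geom = setup.geometry
    xc = setup.phantom.centre_x(geom) if setup.phantom else geom.source_to_iso
    return geom.detector_half_height * xc / geom.source_to_detector


def _plane_spread_matrix(geom: ScannerGeometry, z_w: float,
                         virt_edges: np.ndarray) -> np.ndarray:
    """Map deposits binned in exit-z offset (virtual bins, relative to the
    incident plane) onto physical detector rows, averaging over incident
    planes distributed uniformly across the cone half-width ``z_w``.

    Returns W with shape (n_virtual, n_rows):  S_rows = W.T @ S_virtual.
    """
    row_edges = geom.row_z_edges()
    du = np.diff(virt_edges)
    w = np.zeros((virt_edges.size - 1, geom.n_rows))
    for r in range(geom.n_rows):
        z = np.linspace(row_edges[r], row_edges[r + 1], 9)
        # overlap of the box [z - z_w, z + z_w] with each virtual bin
        lo = np.maximum(z[:, None] - z_w, virt_edges[:-1][None, :])
        hi = np.minimum(z[:, None] + z_w, virt_edges[1:][None, :])
        frac = np.clip(hi - lo, 0.0, None) / (2.0 * z_w)
        w[:, r] = np.trapezoid(frac, z, axis=0) / du
    return w


def simulate_scatter_deterministic(setup: AcquisitionSetup,
                                   grid_resolution: float = 5.0,
                                   exploit_symmetry: bool = True) -> np.ndarray:
    """Single-scatter quadrature: the expected value of the MC estimator.

    ``grid_resolution`` is the integration step (mm) along each incident
    chord; halving it should change per-channel values by well under 1% at
    the 5 mm default.  ``exploit_symmetry`` halves the incident-channel loop
    for left-right symmetric configurations (the result is identical to
    rounding).  Returns the full rows x channels scatter matrix.
    """
    ph = _require_phantom(setup)
    if grid_resolution <= 0:
        raise ConfigurationError("grid_resolution must be positive")
    geom = setup.geometry
    n_ch = geom.n_channels_total
    alpha, ax, ay, ex_, ey_ = _arc_coords(geom)
    bfac = _incident_blocker_factor(setup)
    e, w, mu_f, mu_w, fc, sigma, fine_f, fine_w = _spectral_tables(setup)
    fcs = fc / sigma
    xc = ph.centre_x(geom)

    # exit-z offsets are resolved on a virtual grid wide enough that, after
    # averaging over incident planes, every physical row is covered
    z_w = _cone_half_width(setup)
    half_span = geom.detector_half_height + z_w
    du = 2.0 * geom.row_pitch_at_detector
    n_virtual = int(math.ceil(2.0 * half_span / du))
    virt_edges = np.linspace(-half_span, half_span, n_virtual + 1)
    row_sel = np.arange(n_virtual, dtype=np.int64)
    phi0 = setup.tube_output * geom.n_rows  # the cone carries n_rows fans

    def run(indices: np.ndarray, acc: np.ndarray) -> None:
        _kernels.quadrature_scatter(indices, alpha, ex_, ey_, ax, ay, bfac, e, w,
                                    mu_f, mu_w, fcs, _FINE_E0, 1.0 / _FINE_STEP,
                                    fine_f, fine_w, xc, ph.fill_radius, ph.outer_radius,
                                    grid_resolution, virt_edges, row_sel, phi0, acc)

    out = np.zeros((n_virtual, n_ch))
    symmetric = exploit_symmetry and np.allclose(bfac, bfac[::-1], rtol=0, atol=1e-12)
    if symmetric:
        run(np.arange(n_ch // 2, dtype=np.int64), out)
        out = out + out[:, ::-1]
        if n_ch % 2 == 1:
            extra = np.zeros_like(out)
            run(np.array([n_ch // 2], dtype=np.int64), extra)
            out += extra
    else:
        run(np.arange(n_ch, dtype=np.int64), out)

    spread = _plane_spread_matrix(geom, z_w, virt_edges)
    return setup.multiple_scatter_factor * (spread.T @ out)


def _kn_inverse_cdf_tables(energies: np.ndarray, n_q: int = 513):
    """Per-energy inverse CDF of cos(theta) under the Klein-Nishina law.

    Tabulated in cos(theta), where the density (proportional to the
    differential cross-section itself) is finite and smooth at both
    endpoints, so piecewise-linear inversion is uniformly accurate; an
    inverse CDF in theta would misrepresent the vanishing sin(theta) density
    at 0 and pi, which the narrow detector z-band samples preferentially.
    """
    x = np.cos(KN_THETA_GRID)[::-1]          # ascending in cos(theta)
    tables = np.empty((energies.size, n_q))
    q = np.linspace(0.0, 1.0, n_q)
    for k, e_kev in enumerate(energies):
        pdf = klein_nishina(e_kev, np.arccos(x))
        cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(x))])
        cdf /= cdf[-1]
        tables[k] = np.interp(q, cdf, x)
    return q, tables


def simulate_scatter_mc(setup: AcquisitionSetup,
                        n_splits: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Analog single-scatter Monte Carlo; returns (scatter, standard errors).

    ``setup.n_photons`` source photons are stratified equally over the channel
    rays (meaningful statistics require n_photons >= n_channels); energy is
    sampled from the spectrum bins, the interaction depth from the truncated
    exponential along the fill chord, and each interaction emits ``n_splits``
    exit rays sampled from the Klein-Nishina law at weight 1/n_splits
    (direction splitting -- plain variance reduction, the estimator stays
    analog and unbiased).  Bit-identical for a fixed seed.
    """
    ph = _require_phantom(setup)
    geom = setup.geometry
    n_ch = geom.n_channels_total
    n = setup.n_photons
    sums = np.zeros((geom.n_rows, n_ch))
    sumsq = np.zeros_like(sums)
    if n == 0:
        return sums, sumsq
    alpha, *_ = _arc_coords(geom)
    bfac = _incident_blocker_factor(setup)
    e, w, mu_f, mu_w, fc, sigma, fine_f, fine_w = _spectral_tables(setup)

    ss = np.random.SeedSequence(setup.seed)
    rng = np.random.default_rng(ss)
    u = rng.random((n, 3))
    cdf_e = np.cumsum(w)
    cdf_e[-1] = 1.0
    e_idx = np.searchsorted(cdf_e, u[:, 0]).astype(np.int64)
    q, theta_tab = _kn_inverse_cdf_tables(e)
    counts = np.bincount(np.arange(n) % n_ch, minlength=n_ch).astype(float)
    counts[counts == 0] = 1.0
    kernel_seed = int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))

    _kernels.mc_scatter(n, n_splits, kernel_seed, counts, alpha, bfac, e_idx,
                        u[:, 1], u[:, 2], _cone_half_width(setup),
                        q, theta_tab,
                        e, mu_f, mu_w, np.atleast_1d(fc),
                        _FINE_E0, 1.0 / _FINE_STEP, fine_f, fine_w,
                        ph.centre_x(geom), ph.fill_radius, ph.outer_radius,
                        geom.source_to_detector, math.radians(geom.channel_pitch_deg),
                        geom.row_pitch_at_detector, geom.n_rows,
                        setup.tube_output * geom.n_rows, sums, sumsq)
    var = np.clip(sumsq - sums ** 2 / (n * n_splits), 0.0, None)
    f = setup.multiple_scatter_factor
    return f * sums, f * np.sqrt(var)


# ---------------------------------------------------------------------------
# rendering acquisitions

def render_acquisition_pair(setup: AcquisitionSetup,
                            calibration: CalibrationTable,
                            out_dir: str | Path,
                            tag: str = "acq",
                            grid_resolution: float = 5.0,
                            engine: str = "deterministic") -> dict:
    """Write the two-exposure acquisition the blocker method requires.

    Exposure 1: blocker only (pure primary; the phantom, the only scatterer in
    the model, is out of the beam).  Exposure 2: blocker + phantom, primary
    plus single scatter.  Both frames pass through ``calibration`` before
    writing; a ground-truth sidecar stores the uncalibrated primary/scatter.
    Returns a manifest entry dict with the written paths.
    """
    if setup.blocker is None:
        raise ConfigurationError("render_acquisition_pair requires the blocker array")
    ph = _require_phantom(setup)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    open_setup = replace(setup, phantom=None)
    primary_open = simulate_primary(open_setup)
    primary_ph = simulate_primary(setup)
    primary_unblocked = simulate_primary(replace(setup, blocker=None))
    if engine == "deterministic":
        scatter = simulate_scatter_deterministic(setup, grid_resolution=grid_resolution)
        scatter_se = np.zeros_like(scatter)
    elif engine == "mc":
        scatter, scatter_se = simulate_scatter_mc(setup)
    else:
        raise ConfigurationError(f"unknown scatter engine {engine!r}")

    truth = GroundTruth(primary=primary_ph, scatter=scatter, scatter_se=scatter_se,
                        primary_unblocked=primary_unblocked)

    frames = {}
    for name, readings, phantom_flag in (("blocker", primary_open, False),
                                         ("phantom", primary_ph + scatter, True)):
        data = readings
        if setup.noise == "poisson":
            rng = np.random.default_rng(np.random.SeedSequence(setup.seed,
                                                               spawn_key=(hash(name) % 2**31,)))
            data = rng.poisson(np.clip(data, 0.0, None)).astype(float)
        meta = FrameMeta(kvp=setup.spectrum.kvp, tube_current_ma=setup.tube_current,
                         exposure_s=setup.exposure_time, phantom_present=phantom_flag,
                         blocker_present=True, calibrated=False, seed=setup.seed)
        frame = calibrate(DetectorFrame(readings=data, meta=meta), calibration)
        dtype = "uint16" if calibration.compression == "uint16" else "float32"
        frames[name] = write_frame(frame, out_dir / f"{tag}_{name}.ctraw", dtype=dtype)

    meta = {"tag": tag, "kvp": setup.spectrum.kvp, "tube_current_ma": setup.tube_current,
            "exposure_s": setup.exposure_time, "fill_material": ph.fill_material,
            "fill_diameter_mm": ph.fill_diameter, "axial_offset_mm": ph.axial_offset,
            "seed": setup.seed, "engine": engine, "grid_resolution_mm": grid_resolution}
    truth_path = truth.save(out_dir / f"{tag}_truth.txt", meta=meta)
    return {"tag": tag, "kvp": setup.spectrum.kvp, "tube_current_ma": setup.tube_current,
            "fill_material": ph.fill_material, "fill_diameter_mm": ph.fill_diameter,
            "axial_offset_mm": ph.axial_offset, "seed": setup.seed,
            "blocker_frame": str(frames["blocker"]), "phantom_frame": str(frames["phantom"]),
            "truth": str(truth_path)}


def make_study_fixtures(out_dir: str | Path,
                        geometry: ScannerGeometry | None = None,
                        blocker: BlockerArray | None = None,
                        seed: int = 0,
                        kvps: tuple = (80.0, 100.0, 120.0, 140.0),
                        offsets: tuple = (-100.0, -50.0, 0.0, 50.0, 100.0),
                        grid_resolution: float = 5.0,
                        spectrum_bin: float = 5.0,
                        noise: str = "off") -> Path:
    """Generate the full study: a kVp sweep for the 215 mm water cylinder
    (100 mA) and the 300 mm polypropylene cylinder (200 mA), 3 s exposures,
    plus an off-centring sweep at 120 kVp / 100 mA.  Writes one acquisition
    pair per setup and a manifest listing every file; returns the manifest path.
    """
    import pandas as pd

    geometry = geometry or ScannerGeometry()
    blocker = blocker or BlockerArray.default_layout(geometry)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    calibration = CalibrationTable.identity(geometry.n_rows, geometry.n_channels_total)

    setups: list[tuple[str, AcquisitionSetup]] = []
    for kvp in kvps:
        for phantom, ma in ((water_cylinder_215(), 100.0),
                            (polypropylene_cylinder_300(), 200.0)):
            tag = f"{phantom.fill_material}_{int(round(phantom.fill_diameter))}mm_{int(kvp)}kvp"
            setups.append((tag, AcquisitionSetup(
                geometry=geometry, phantom=phantom, blocker=blocker,
                spectrum=generate_spectrum(kvp, bin_width=spectrum_bin),
                tube_current=ma, noise=noise)))
    for off in offsets:
        phantom = replace(water_cylinder_215(), axial_offset=off)
        tag = f"water_215mm_120kvp_offset{int(off):+d}mm"
        setups.append((tag, AcquisitionSetup(
            geometry=geometry, phantom=phantom, blocker=blocker,
            spectrum=generate_spectrum(120.0, bin_width=spectrum_bin),
            tube_current=100.0, noise=noise)))

    entries = []
    for i, (tag, s) in enumerate(setups):
        s = replace(s, seed=(seed * 1009 + i) % 2 ** 31)
        entries.append(render_acquisition_pair(s, calibration, out_dir, tag=tag,
                                               grid_resolution=grid_resolution))
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(entries).to_csv(manifest, sep="\t", index=False)
    return manifest
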
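"""Scripted, seeded study designs binding the simulator to the pipeline.

A design enumerates acquisition setups (kVp sweeps, phantom sizes,
off-centring) and a list of named property assertions on the pipeline output
(monotonic trends, symmetry, recovery tolerances).  ``run_design`` generates
the fixtures, runs the measurement chain, evaluates every assertion and
writes a pass/fail report with measured margins.  The shipped designs under
``ctscatter/designs/`` cover the standard measurement campaign: the 215 mm
water cylinder and the 300 mm polypropylene cylinder at 80-140 kVp, and an
axial off-centring sweep at 120 kVp.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .geometry import (BlockerArray, ConfigurationError, Phantom, ScannerGeometry,
                       polypropylene_cylinder_300, water_cylinder_215)
from .physics import generate_spectrum
from .pipeline import BlockerScatterModel
from .raw_io import CalibrationTable
from .simulator import AcquisitionSetup, GroundTruth, render_acquisition_pair

__all__ = ["StudyDesign", "Verdict", "load_design", "run_design", "shipped_design_path"]

_PRESETS = {"water215": water_cylinder_215, "polypropylene300": polypropylene_cylinder_300}


@dataclass(frozen=True)
class StudyDesign:
    name: str
    geometry: ScannerGeometry
    blocker: BlockerArray
    setups: dict[str, AcquisitionSetup]      # tag -> setup
    assertions: tuple[tuple[str, dict], ...] # (kind, params)
    seed: int = 0
    row: int = 32                            # 1-based reporting row
    grid_resolution: float = 5.0

    def __post_init__(self) -> None:
        for kind, params in self.assertions:
            for tag in _assertion_tags(kind, params):
                if tag not in self.setups:
                    raise ConfigurationError(
                        f"assertion {kind} names unknown setup {tag!r}")


def _assertion_tags(kind: str, params: dict) -> list[str]:
    if kind in ("decreasing", "increasing"):
        return list(params["series"])
    if kind in ("mirror_symmetry", "two_peak", "recovery"):
        return [params["setup"]]
    if kind == "greater":
        return [params["a"], params["b"]]
    raise ConfigurationError(f"unknown assertion kind {kind!r}")


@dataclass(frozen=True)
class Verdict:
    design: str
    passed: bool
    checks: tuple[dict, ...]

    def report(self) -> str:
        lines = [f"design: {self.design}",
                 f"result: {'PASS' if self.passed else 'FAIL'}"]
        for c in self.checks:
            lines.append(f"  [{'ok' if c['passed'] else 'FAIL'}] {c['name']}: {c['detail']}")
        return "\n".join(lines)


def shipped_design_path(name: str) -> Path:
    """Path of a packaged design (e.g. 'kvp_sweep_water')."""
    p = resources.files("ctscatter.designs").joinpath(f"{name}.cfg")
    if not p.is_file():
        raise KeyError(f"no shipped design named {name!r}")
    return Path(str(p))


def load_design(path: str | Path) -> StudyDesign:
    cp = configparser.ConfigParser()
    if not cp.read(path):
        raise ConfigurationError(f"cannot read design file {path}")
    if "design" not in cp:
        raise ConfigurationError(f"{path}: missing [design] section")
    d = cp["design"]
    geom_kw = {}
    if "geometry" in cp:
        for k, v in cp["geometry"].items():
            geom_kw[k] = int(v) if k.startswith("n_") else float(v)
    geometry = ScannerGeometry(**geom_kw)
    if "blocker" in cp:
        b = cp["blocker"]
        blocker = BlockerArray.default_layout(
            geometry, n_bars=int(b.get("n_bars", 20)),
            bar_width=float(b.get("bar_width", 2.0)),
            bar_thickness=float(b.get("bar_thickness", 3.0)),
            coverage=float(b.get("coverage", 0.9)))
    else:
        blocker = BlockerArray.default_layout(geometry)
    seed = int(d.get("seed", 0))
    spectrum_bin = float(d.get("spectrum_bin", 5.0))
    setups = {}
    assertions = []
    for sec in cp.sections():
        if sec.startswith("setup:"):
            tag = sec.split(":", 1)[1]
            s = cp[sec]
            if "preset" in s:
                phantom = _PRESETS[s["preset"]]()
            else:
                phantom = Phantom(fill_diameter=float(s["fill_diameter"]),
                                  fill_material=s["fill_material"],
                                  wall_thickness=float(s.get("wall_thickness", 0.0)),
                                  wall_material=s.get("wall_material") or None)
            if "axial_offset" in s:
                phantom = replace(phantom, axial_offset=float(s["axial_offset"]))
            setups[tag] = AcquisitionSetup(
                geometry=geometry, phantom=phantom, blocker=blocker,
                spectrum=generate_spectrum(float(s.get("kvp", 120.0)),
                                           bin_width=spectrum_bin),
                tube_current=float(s.get("tube_current", 100.0)),
                exposure_time=float(s.get("exposure_time", 3.0)),
                n_photons=int(float(s.get("n_photons", 1e6))), seed=seed)
        elif sec.startswith("assert:"):
            a = dict(cp[sec])
            a.setdefault("name", sec.split(":", 1)[1])
            kind = a.pop("kind")
            if "series" in a:
                a["series"] = [t.strip() for t in a["series"].split(",")]
            assertions.append((kind, a))
    return StudyDesign(name=d.get("name", Path(path).stem), geometry=geometry,
                       blocker=blocker, setups=setups,
                       assertions=tuple(assertions), seed=seed,
                       row=int(d.get("row", 32)),
                       grid_resolution=float(d.get("grid_resolution", 5.0)))


def _evaluate(kind: str, params: dict, results: dict, truths: dict, row0: int):
    name = params.get("name", kind)
    if kind in ("decreasing", "increasing"):
        vals = [results[t].integrated_spr[row0] for t in params["series"]]
        diffs = np.diff(vals)
        ok = bool(np.all(diffs < 0) if kind == "decreasing" else np.all(diffs > 0))
        detail = "integrated SPR " + " -> ".join(f"{v:.3f}" for v in vals)
    elif kind == "greater":
        va = results[params["a"]].integrated_spr[row0]
        vb = results[params["b"]].integrated_spr[row0]
        ok = bool(va > vb)
        detail = f"{params['a']}={va:.3f} > {params['b']}={vb:.3f}"
    elif kind == "mirror_symmetry":
        prof = results[params["setup"]].scatter[row0]
        tol = float(params.get("tol", 0.01))
        rel = np.abs(prof - prof[::-1]) / prof.max()
        ok = bool(rel.max() <= tol)
        detail = f"max mirror asymmetry {rel.max():.2e} (tol {tol:g})"
    elif kind == "two_peak":
        prof = results[params["setup"]].scatter[row0]
        centre = prof[prof.size // 2]
        ok = bool(centre < prof.max())
        detail = f"centre {centre:.4g} < max {prof.max():.4g}"
    elif kind == "recovery":
        res = results[params["setup"]]
        truth = truths[params["setup"]]
        sc = res.scatter[row0]
        tr = truth.scatter[row0]
        rms_s = float(np.sqrt(np.mean(((sc - tr) / tr) ** 2)))
        pu = truth.primary_unblocked[row0]
        rms_p = float(np.sqrt(np.mean(((res.primary[row0] - pu) / pu) ** 2)))
        lim_s = float(params.get("scatter_rms_max", 0.05))
        lim_p = float(params.get("primary_rms_max", 0.02))
        ok = rms_s <= lim_s and rms_p <= lim_p
        detail = f"scatter RMS {rms_s:.3%} (<= {lim_s:.0%}), primary RMS {rms_p:.3%} (<= {lim_p:.0%})"
    else:  # unreachable: validated at load
        raise ConfigurationError(kind)
    return {"name": name, "passed": ok, "detail": detail}


def run_design(design: StudyDesign, out_dir: str | Path) -> Verdict:
    """Generate fixtures, run the pipeline, evaluate every assertion.

    Deterministic given the design's seed.  An empty design passes trivially.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geom = design.geometry
    cal = CalibrationTable.identity(geom.n_rows, geom.n_channels_total)
    results = {}
    truths = {}
    for i, (tag, setup) in enumerate(sorted(design.setups.items())):
        setup = replace(setup, seed=(design.seed * 1009 + i) % 2 ** 31)
        entry = render_acquisition_pair(setup, cal, out_dir / "fixtures", tag=tag,
                                        grid_resolution=design.grid_resolution)
        truths[tag] = GroundTruth.load(entry["truth"])
        model = BlockerScatterModel.from_files(entry["phantom_frame"],
                                               entry["blocker_frame"], cal, geom,
                                               blocker=design.blocker)
        results[tag] = model.fit()
    checks = tuple(_evaluate(kind, params, results, truths, design.row - 1)
                   for kind, params in design.assertions)
    verdict = Verdict(design=design.name,
                      passed=all(c["passed"] for c in checks) if checks else True,
                      checks=checks)
    (out_dir / "report.txt").write_text(verdict.report() + "\n")
    return verdict
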
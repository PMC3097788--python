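"""Plain-text experiment configuration (INI key-value, units mm / degrees / keV).

Sections: ``[geometry]`` (ScannerGeometry fields), ``[phantom]``, ``[blocker]``
(either an explicit ``bar_centers`` list or ``n_bars``/``coverage`` for the
evenly spaced default layout) and ``[acquisition]`` (kvp, tube_current,
exposure_time, n_photons, seed, noise, spectrum_bin, grid_resolution).
Unknown keys are an error -- silent typos in a measurement configuration are
worse than a crash.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, fields
from pathlib import Path

from .geometry import (BlockerArray, ConfigurationError, Phantom, ScannerGeometry,
                       polypropylene_cylinder_300, water_cylinder_215)
from .physics import generate_spectrum
from .simulator import AcquisitionSetup

__all__ = ["ExperimentConfig", "load_config"]

_ACQ_KEYS = {"kvp": 120.0, "tube_current": 100.0, "exposure_time": 3.0,
             "n_photons": 1_000_000, "seed": 0, "noise": "off",
             "spectrum_bin": 5.0, "grid_resolution": 5.0}
_BLOCKER_KEYS = {"n_bars", "bar_width", "bar_thickness", "coverage", "bar_centers"}
_PHANTOM_PRESETS = {"water215": water_cylinder_215,
                    "polypropylene300": polypropylene_cylinder_300}


@dataclass(frozen=True)
class ExperimentConfig:
    geometry: ScannerGeometry
    phantom: Phantom | None
    blocker: BlockerArray | None
    acquisition: dict

    def build_setup(self) -> AcquisitionSetup:
        a = self.acquisition
        return AcquisitionSetup(
            geometry=self.geometry, phantom=self.phantom, blocker=self.blocker,
            spectrum=generate_spectrum(a["kvp"], bin_width=a["spectrum_bin"]),
            tube_current=a["tube_current"], exposure_time=a["exposure_time"],
            n_photons=int(a["n_photons"]), seed=int(a["seed"]), noise=a["noise"])


def _check_keys(section: str, got, allowed) -> None:
    unknown = set(got) - set(allowed)
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in [{section}]: {', '.join(sorted(unknown))}")


def _parse_geometry(sec) -> ScannerGeometry:
    allowed = {f.name for f in fields(ScannerGeometry)}
    _check_keys("geometry", sec, allowed)
    kw = {}
    for k, v in sec.items():
        kw[k] = int(v) if k.startswith("n_") else float(v)
    return ScannerGeometry(**kw)


def _parse_phantom(sec) -> Phantom:
    if "preset" in sec:
        _check_keys("phantom", sec, {"preset", "axial_offset"})
        ph = _PHANTOM_PRESETS[sec["preset"]]()
        if "axial_offset" in sec:
            from dataclasses import replace
            ph = replace(ph, axial_offset=float(sec["axial_offset"]))
        return ph
    allowed = {f.name for f in fields(Phantom)}
    _check_keys("phantom", sec, allowed)
    kw = dict(sec)
    for k in ("fill_diameter", "wall_thickness", "axial_offset"):
        if k in kw:
            kw[k] = float(kw[k])
    return Phantom(**kw)


def _parse_blocker(sec, geom: ScannerGeometry) -> BlockerArray:
    _check_keys("blocker", sec, _BLOCKER_KEYS)
    if "bar_centers" in sec:
        centers = tuple(float(x) for x in sec["bar_centers"].split(","))
        return BlockerArray(bar_centers=centers,
                            bar_width=float(sec.get("bar_width", 2.0)),
                            bar_thickness=float(sec.get("bar_thickness", 3.0)))
    return BlockerArray.default_layout(
        geom, n_bars=int(sec.get("n_bars", 20)),
        bar_width=float(sec.get("bar_width", 2.0)),
        bar_thickness=float(sec.get("bar_thickness", 3.0)),
        coverage=float(sec.get("coverage", 0.9)))


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an experiment configuration file."""
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise ConfigurationError(f"cannot read configuration {path}")
    known = {"geometry", "phantom", "blocker", "acquisition"}
    _check_keys("<file>", cp.sections(), known)
    geom = _parse_geometry(cp["geometry"]) if "geometry" in cp else ScannerGeometry()
    phantom = _parse_phantom(cp["phantom"]) if "phantom" in cp else None
    blocker = _parse_blocker(cp["blocker"], geom) if "blocker" in cp else None
    acq = dict(_ACQ_KEYS)
    if "acquisition" in cp:
        _check_keys("acquisition", cp["acquisition"], _ACQ_KEYS)
        for k, v in cp["acquisition"].items():
            if k == "noise":
                acq[k] = v
            elif isinstance(_ACQ_KEYS[k], int):
                acq[k] = int(float(v))
            else:
                acq[k] = float(v)
    return ExperimentConfig(geometry=geom, phantom=phantom, blocker=blocker,
                            acquisition=acq)
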
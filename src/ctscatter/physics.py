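"""Materials, attenuation, polychromatic tube spectra and Compton kernels.

Mass-attenuation tables for the six materials the instrument model needs
(water, Plexiglas, polypropylene, lead, aluminium, copper) ship as plain-text
two-column files on a 10-150 keV grid and are interpolated log-log.  The tube
spectrum is a Kramers bremsstrahlung continuum hardened by the inherent
filtration stack (3.25 mm Al + 0.1 mm Cu by default); characteristic anode
lines are not modelled, because only kVp trends are asserted downstream.

The single-valued lead attenuation used for the blocker shadow factor follows
the beam-stop arithmetic convention (mu/rho = 3.32 cm^2/g at the effective
beam energy, rho = 11.3 g/cm^3, hence mu = 37.52 /cm), while everything else
uses the full energy-resolved tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "Material", "Spectrum", "get_material",
    "linear_attenuation", "transmission", "generate_spectrum",
    "compton_energy", "klein_nishina", "kn_total_angular", "compton_fraction",
    "blocker_linear_attenuation", "blocker_transmission",
]

# classical electron radius squared, cm^2
R_E2_CM2 = 7.940787e-26
# electron density of water, electrons per cm^3
N_E_WATER = 3.3428e23
# electron rest energy, keV
MEC2_KEV = 511.0

# blocker-arithmetic constants for lead (effective-energy values)
BLOCKER_LEAD_MU_RHO = 3.32    # cm^2/g
BLOCKER_LEAD_DENSITY = 11.3   # g/cm^3


def blocker_linear_attenuation() -> float:
    """Single-valued linear attenuation of the lead bars, cm^-1 (= 37.52)."""
    return BLOCKER_LEAD_MU_RHO * BLOCKER_LEAD_DENSITY


def blocker_transmission(thickness_cm: float = 0.3) -> float:
    """Transmission of the lead bars at their nominal thickness (3 mm)."""
    return math.exp(-blocker_linear_attenuation() * thickness_cm)


@dataclass(frozen=True)
class Material:
    """A material with density and a tabulated mass-attenuation curve."""

    name: str
    density: float                 # g/cm^3
    electron_density: float        # relative to water
    energies: np.ndarray           # keV, ascending
    mu_rho: np.ndarray             # cm^2/g

    def mass_attenuation(self, energy_kev, extrapolate: bool = False) -> np.ndarray:
        """mu/rho (cm^2/g) at ``energy_kev``, log-log interpolated."""
        e = np.asarray(energy_kev, dtype=float)
        lo, hi = self.energies[0], self.energies[-1]
        if not extrapolate and (np.any(e < lo) or np.any(e > hi)):
            raise ValueError(
                f"energy outside {self.name} table range [{lo}, {hi}] keV"
            )
        loge = np.log(np.clip(e, 1e-3, None))
        out = np.exp(np.interp(loge, np.log(self.energies), np.log(self.mu_rho)))
        return out if out.shape else float(out)

    def linear_attenuation(self, energy_kev, extrapolate: bool = False):
        """mu (cm^-1) at ``energy_kev``."""
        return self.mass_attenuation(energy_kev, extrapolate=extrapolate) * self.density


def _load_material(name: str) -> Material:
    text = resources.files("ctscatter.materials").joinpath(f"{name}.tsv").read_text()
    density = electron_density = None
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "density_g_cm3" in line:
                density = float(line.split("=")[1])
            elif "electron_density_rel_water" in line:
                electron_density = float(line.split("=")[1])
            continue
        e, mr = line.split()
        rows.append((float(e), float(mr)))
    if density is None or electron_density is None:
        raise ValueError(f"material table {name} missing density header")
    arr = np.array(rows)
    return Material(name=name, density=density, electron_density=electron_density,
                    energies=arr[:, 0], mu_rho=arr[:, 1])


_MATERIALS: dict[str, Material] = {}
_ALIASES = {"pmma": "plexiglas", "aluminum": "aluminium", "al": "aluminium",
            "cu": "copper", "pp": "polypropylene"}


def get_material(name: str) -> Material:
    """Look up a packaged material by name (case-insensitive, common aliases)."""
    key = _ALIASES.get(name.lower(), name.lower())
    if key not in _MATERIALS:
        try:
            _MATERIALS[key] = _load_material(key)
        except FileNotFoundError as exc:
            raise KeyError(f"unknown material {name!r}") from exc
    return _MATERIALS[key]


def linear_attenuation(material: Material | str, energy_kev) -> float:
    """Linear attenuation coefficient mu (cm^-1) at the given energy."""
    if isinstance(material, str):
        material = get_material(material)
    return material.linear_attenuation(energy_kev)


def transmission(material: Material | str, energy_kev, thickness_cm: float):
    """Narrow-beam transmission exp(-mu t) through ``thickness_cm`` of material."""
    if np.any(np.asarray(thickness_cm) < 0):
        raise ValueError("thickness must be >= 0")
    return np.exp(-linear_attenuation(material, energy_kev) * thickness_cm)


@dataclass(frozen=True)
class Spectrum:
    """Relative photon fluence per energy bin for one tube voltage."""

    kvp: float
    energies: np.ndarray   # bin centres, keV
    fluence: np.ndarray    # normalised to sum 1

    def __post_init__(self) -> None:
        if np.any(self.energies > self.kvp + 1e-9):
            raise ValueError("spectrum bins exceed kVp")
        if np.any(self.fluence < 0):
            raise ValueError("negative fluence")

    @property
    def mean_energy(self) -> float:
        return float(np.sum(self.energies * self.fluence))

    @classmethod
    def monoenergetic(cls, energy_kev: float) -> "Spectrum":
        return cls(kvp=float(energy_kev), energies=np.array([float(energy_kev)]),
                   fluence=np.array([1.0]))


DEFAULT_FILTRATION = (("aluminium", 0.325), ("copper", 0.01))


def generate_spectrum(kvp: float,
                      filtration=DEFAULT_FILTRATION,
                      bin_width: float = 1.0,
                      e_min: float = 10.0) -> Spectrum:
    """Kramers-shaped tube spectrum hardened by a filtration stack.

    Unfiltered fluence per bin is proportional to (kVp - E)/E; each
    (material, thickness_cm) element of ``filtration`` multiplies in its
    narrow-beam transmission; the result is normalised to unit sum.  Bins of
    ``bin_width`` keV start at ``e_min`` (10 keV default: the sub-10 keV tail
    is removed entirely by millimetres of aluminium).
    """
    if not 40.0 <= kvp <= 150.0:
        raise ValueError(f"kVp {kvp} outside supported range [40, 150]")
    edges = np.arange(e_min, kvp + 1e-9, bin_width)
    if edges[-1] < kvp - 1e-9:
        edges = np.append(edges, kvp)
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    fluence = np.clip(kvp - centers, 0.0, None) / centers * widths
    for mat, t_cm in filtration:
        fluence = fluence * transmission(mat, centers, t_cm)
    total = fluence.sum()
    if total <= 0:
        raise ValueError("filtration removed the entire spectrum")
    return Spectrum(kvp=float(kvp), energies=centers, fluence=fluence / total)


def compton_energy(energy_kev, theta_rad):
    """Energy (keV) of a Compton-scattered photon at polar angle theta."""
    e = np.asarray(energy_kev, dtype=float)
    return e / (1.0 + (e / MEC2_KEV) * (1.0 - np.cos(theta_rad)))


def klein_nishina(energy_kev, theta_rad):
    """Klein-Nishina differential cross-section dsigma/dOmega in units of r_e^2.

    Forward limit (theta=0) is 1; the low-energy limit is the Thomson form
    (1 + cos^2 theta)/2.
    """
    e = np.asarray(energy_kev, dtype=float)
    ratio = compton_energy(e, theta_rad) / e
    return 0.5 * ratio * ratio * (ratio + 1.0 / ratio - np.sin(theta_rad) ** 2)


# shared polar grid for angular sampling and normalisation, so the Monte Carlo
# sampler and the quadrature oracle use the identical discretisation
KN_THETA_GRID = np.linspace(0.0, math.pi, 1025)


def kn_total_angular(energy_kev) -> float:
    """Total Klein-Nishina cross-section in r_e^2 units, by quadrature.

    2*pi * integral of klein_nishina * sin(theta) over KN_THETA_GRID; the
    Thomson limit is 8*pi/3.
    """
    kn = klein_nishina(np.asarray(energy_kev, dtype=float)[..., None], KN_THETA_GRID)
    integ = np.trapezoid(kn * np.sin(KN_THETA_GRID), KN_THETA_GRID, axis=-1)
    out = 2.0 * math.pi * integ
    return out if out.shape else float(out)


def compton_fraction(material: Material | str, energy_kev):
    """Fraction of interactions that Compton-scatter, free-electron approximation.

    mu_incoherent ~= n_e * sigma_KN(E); the fraction is mu_inc / mu_total,
    clipped to [0, 1].  Adequate above ~20 keV where binding effects are small.
    """
    if isinstance(material, str):
        material = get_material(material)
    e = np.asarray(energy_kev, dtype=float)
    n_e = material.electron_density * N_E_WATER
    mu_inc = n_e * kn_total_angular(e) * R_E2_CM2
    mu_tot = material.linear_attenuation(e, extrapolate=True)
    return np.clip(mu_inc / mu_tot, 0.0, 1.0)
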
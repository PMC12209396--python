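"""Polychromatic beam models, transmission, and effective energy.

A mammography tube spectrum is modeled as Kramers bremsstrahlung photon
fluence, ``N(E) dE ~ (E_max/E - 1)``, hardened by an aluminum-equivalent
anode/inherent self-filtration term and the user-requested external filter
(Al or Ag).  A measured or vendor spectrum can be supplied instead as a
two-column (keV, relative weight) text file.

The effective energy of a beam for a given material path is the
monochromatic energy whose composition-averaged attenuation reproduces the
beam's equivalent attenuation ``mu_eq = -ln(T_poly)/t`` for that path; it is
found by linear interpolation of mu_mix(E) over the spectrum support, the
same convention used throughout the estimation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .materials import (
    AttenuationTable,
    PathComposition,
    load_table,
    load_tables,
    mu_at,
)

__all__ = [
    "EnergySpectrum",
    "EffectiveEnergyResult",
    "UnsupportedConfigurationError",
    "NoSolutionError",
    "build_spectrum",
    "poly_transmission",
    "effective_energy",
    "effective_energy_from_mu",
    "loss_percent_error",
    "read_spectrum",
    "write_spectrum",
]


class UnsupportedConfigurationError(ValueError):
    """Anode/filter combination the tube model does not cover."""


class NoSolutionError(ValueError):
    """mu_eq falls outside the range of mu_mix over the spectrum support."""


_FILTER_TABLES = {"Al": "aluminum", "Ag": "silver"}

# Tungsten mass attenuation (cm^2/g) used only for anode self-absorption in
# the tube model; coarse above the L edges, which filtration kills anyway.
_W_E = np.array([10.0, 12.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0])
_W_MU_RHO = np.array([230.0, 170.0, 139.0, 65.7, 36.6, 22.7, 15.1, 10.7, 8.0])
_W_RHO = 19.3


@dataclass(frozen=True)
class EnergySpectrum:
    """Binned photon-fluence spectrum (bin centers, relative weights)."""

    energies: np.ndarray     # keV bin centers, strictly increasing
    weights: np.ndarray      # relative fluence, >= 0, at least one > 0
    kvp: float
    anode: str = "W"
    filter_material: Optional[str] = None
    filter_thickness: float = 0.0  # mm

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w)
        if e.ndim != 1 or e.size == 0 or (e.size > 1 and np.any(np.diff(e) <= 0)):
            raise ValueError("energies must be 1-D and strictly increasing")
        if w.shape != e.shape or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be >= 0 with at least one positive")
        if e[-1] > self.kvp + 1e-9:
            raise ValueError("spectrum support exceeds the peak voltage")

    @property
    def normalized_weights(self) -> np.ndarray:
        return self.weights / self.weights.sum()

    def mean_energy(self) -> float:
        return float(np.sum(self.normalized_weights * self.energies))

    def sd_energy(self) -> float:
        """Fluence-weighted standard deviation of energy (spectral width)."""
        mu = self.mean_energy()
        return float(np.sqrt(np.sum(self.normalized_weights * (self.energies - mu) ** 2)))

    @classmethod
    def monochromatic(cls, e: float) -> "EnergySpectrum":
        return cls(energies=np.array([e]), weights=np.array([1.0]), kvp=e)


@dataclass(frozen=True)
class EffectiveEnergyResult:
    e_eff: float                 # keV
    mu_equivalent: float         # 1/cm
    reference_composition: PathComposition


def _filter_mu(material: str) -> AttenuationTable:
    if material not in _FILTER_TABLES:
        raise UnsupportedConfigurationError(
            f"unsupported filter material {material!r} (supported: Al, Ag)"
        )
    return load_table(_FILTER_TABLES[material])


def build_spectrum(
    kvp: float,
    anode: str = "W",
    filter_material: Optional[str] = "Al",
    filter_thickness: float = 0.7,
    bin_width: float = 1.0,
    e_min: float = 10.0,
    target_self_filtration_um: float = 9.0,
) -> EnergySpectrum:
    """Analytic W-anode spectrum at ``kvp`` with external filtration.

    Kramers bremsstrahlung photon fluence, ``N(E) ~ (kvp/E - 1)``, hardened
    by self-absorption along an effective tungsten path inside the target
    (the dominant low-energy suppression in a real tube) and by the external
    filter.

    Parameters
    ----------
    kvp : peak voltage in kV (20-40 supported).
    filter_material, filter_thickness : external filter element and mm.
    bin_width : keV spacing of the bin centers.
    e_min : low-energy cutoff; bin centers run from e_min to kvp inclusive.
    target_self_filtration_um : effective tungsten path in micrometres;
        the default is calibrated so the W/Al 28 kV beam's effective energy
        through 2-9 cm breasts spans the 20.6-22.3 keV range reported for
        clinical-style mammography beams.
    """
    if not 20.0 <= kvp <= 40.0:
        raise ValueError("kvp must lie in [20, 40]")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if anode.upper() != "W":
        raise UnsupportedConfigurationError(f"unsupported anode {anode!r} (only W)")

    centers = np.arange(e_min, kvp + 1e-9, bin_width)
    if centers.size == 0:
        raise ValueError("empty spectrum support: e_min above kvp")

    ext = _filter_mu(filter_material) if filter_material and filter_thickness > 0 else None

    # integrate the continuous model over each bin (5-point midpoint rule)
    sub = (np.arange(5) + 0.5) / 5.0 - 0.5
    e_fine = np.clip(centers[:, None] + sub[None, :] * bin_width, e_min, kvp)
    fluence = np.clip(kvp / e_fine - 1.0, 0.0, None)
    mu_w = np.interp(e_fine, _W_E, _W_MU_RHO) * _W_RHO
    atten = np.exp(-mu_w * (target_self_filtration_um * 1e-4))
    if ext is not None:
        atten = atten * np.exp(-mu_at(ext, e_fine) * (filter_thickness / 10.0))
    weights = (fluence * atten).mean(axis=1)
    weights = weights / weights.sum()
    return EnergySpectrum(
        energies=centers, weights=weights, kvp=kvp, anode=anode.upper(),
        filter_material=filter_material, filter_thickness=filter_thickness,
    )


def poly_transmission(
    spectrum: EnergySpectrum,
    comp: PathComposition,
    tables: Dict[str, AttenuationTable] | None = None,
) -> float:
    """Fluence-averaged Beer-Lambert transmission of the path, in (0, 1]."""
    tables = tables or load_tables()
    w = spectrum.normalized_weights
    optical = np.zeros_like(spectrum.energies)
    for name, t_i in comp.items():
        if t_i > 0:
            optical = optical + mu_at(tables[name], spectrum.energies) * t_i
    return float(np.sum(w * np.exp(-optical)))


def _mu_mix_grid(
    comp: PathComposition,
    e_lo: float,
    e_hi: float,
    tables: Dict[str, AttenuationTable],
) -> tuple[np.ndarray, np.ndarray]:
    """mu_mix(E) on the union of table nodes within [e_lo, e_hi] (+ endpoints)."""
    nodes = [np.array([e_lo, e_hi])]
    for name, t_i in comp.items():
        if t_i > 0:
            g = tables[name].energies
            nodes.append(g[(g > e_lo) & (g < e_hi)])
    grid = np.unique(np.concatenate(nodes))
    return grid, comp.mu_mix(grid, tables)


def effective_energy_from_mu(
    mu_eq: float,
    comp: PathComposition,
    e_lo: float,
    e_hi: float,
    tables: Dict[str, AttenuationTable] | None = None,
) -> EffectiveEnergyResult:
    """Solve mu_mix(E) = mu_eq for E on [e_lo, e_hi] by linear interpolation."""
    tables = tables or load_tables()
    grid, mu_mix = _mu_mix_grid(comp, e_lo, e_hi, tables)
    lo, hi = float(mu_mix.min()), float(mu_mix.max())
    span = max(hi - lo, abs(mu_eq), 1.0)
    if lo - 1e-12 * span <= mu_eq <= hi + 1e-12 * span:
        mu_eq = min(max(mu_eq, lo), hi)
    else:
        raise NoSolutionError(
            f"mu_eq={mu_eq:.5f} outside mu_mix range [{lo:.5f}, {hi:.5f}] "
            f"over [{e_lo}, {e_hi}] keV"
        )
    # mu_mix decreases with E for edge-free tissue mixes; interpolate inversely
    order = np.argsort(mu_mix)
    e_eff = float(np.interp(mu_eq, mu_mix[order], grid[order]))
    return EffectiveEnergyResult(e_eff=e_eff, mu_equivalent=mu_eq,
                                 reference_composition=comp)


def effective_energy(
    spectrum: EnergySpectrum,
    comp: PathComposition,
    tables: Dict[str, AttenuationTable] | None = None,
) -> EffectiveEnergyResult:
    """Model-side effective energy of ``spectrum`` for the path ``comp``."""
    if comp.t_total <= 0:
        raise ValueError("effective energy needs a path with t_total > 0")
    tables = tables or load_tables()
    trans = poly_transmission(spectrum, comp, tables)
    mu_eq = -np.log(trans) / comp.t_total
    return effective_energy_from_mu(
        mu_eq, comp, float(spectrum.energies[0]), float(spectrum.energies[-1]), tables
    )


def loss_percent_error(i0_total: float, im_poly: float, im_mono: float) -> float:
    """Percent error between polychromatic and monochromatic count losses.

    The count loss of an image is ``Iloss = 1 - Im/I0``; the error is
    ``(Iloss_poly - Iloss_mono)/Iloss_mono * 100``.
    """
    if i0_total <= 0:
        raise ValueError("i0_total must be positive")
    loss_poly = 1.0 - im_poly / i0_total
    loss_mono = 1.0 - im_mono / i0_total
    if loss_mono == 0.0:
        raise ZeroDivisionError("monochromatic loss is zero")
    return float((loss_poly - loss_mono) / loss_mono * 100.0)


def write_spectrum(path, spectrum: EnergySpectrum) -> None:
    data = np.column_stack([spectrum.energies, spectrum.weights])
    header = (f"energy_keV weight  # kvp={spectrum.kvp} anode={spectrum.anode} "
              f"filter={spectrum.filter_material}/{spectrum.filter_thickness}mm")
    np.savetxt(path, data, header=header, comments="")


def read_spectrum(path, kvp: Optional[float] = None) -> EnergySpectrum:
    """Read a two-column (keV, weight) spectrum file (one header line)."""
    data = np.loadtxt(path, skiprows=1)
    data = np.atleast_2d(data)
    e, w = data[:, 0], data[:, 1]
    return EnergySpectrum(energies=e, weights=w, kvp=kvp or float(e[-1]))
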
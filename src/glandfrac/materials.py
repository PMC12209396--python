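"""Linear attenuation tables and per-ray material path compositions.

The package works in fixed internal units: lengths in cm, photon energy in
keV, linear attenuation ``mu`` in 1/cm.  Tables are bundled as plain-text
files (one header line, columns ``energy_keV mu_over_rho_cm2_g mu_per_cm``)
covering 10-45 keV and are interpolated linearly in energy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Dict, Iterable

import numpy as np

__all__ = [
    "AttenuationTable",
    "PathComposition",
    "AttenuationError",
    "load_table",
    "load_tables",
    "mu_at",
    "MATERIAL_NAMES",
]

MATERIAL_NAMES = (
    "lexan", "skin", "adipose", "glandular",
    "hydroxyapatite", "water", "aluminum", "silver",
)


class AttenuationError(ValueError):
    """Raised for unknown materials or energies outside a table's grid."""


@dataclass(frozen=True)
class AttenuationTable:
    """Linear attenuation coefficient of one material on an energy grid."""

    material: str
    energies: np.ndarray  # keV, strictly increasing
    mu: np.ndarray        # 1/cm

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        m = np.asarray(self.mu, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "mu", m)
        if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
            raise AttenuationError("energy grid must be 1-D and strictly increasing")
        if m.shape != e.shape or np.any(m <= 0):
            raise AttenuationError("mu must be positive on the whole grid")
        if e[0] > 10.0 or e[-1] < 40.0:
            raise AttenuationError("grid must cover at least 10-40 keV")

    def __call__(self, e):
        return mu_at(self, e)


def mu_at(table: AttenuationTable, e):
    """Piecewise-linear interpolation of ``mu`` (1/cm) at energy ``e`` (keV).

    No extrapolation: energies outside the table grid raise
    :class:`AttenuationError`.
    """
    e_arr = np.asarray(e, dtype=float)
    if np.any(e_arr < table.energies[0]) or np.any(e_arr > table.energies[-1]):
        raise AttenuationError(
            f"energy out of range for {table.material}: "
            f"grid covers [{table.energies[0]}, {table.energies[-1]}] keV"
        )
    out = np.interp(e_arr, table.energies, table.mu)
    return float(out) if np.isscalar(e) or e_arr.ndim == 0 else out


def _read_table_file(name: str) -> AttenuationTable:
    ref = resources.files("glandfrac.data").joinpath(f"{name}.txt")
    with ref.open() as fh:
        header = fh.readline()
        if "energy_keV" not in header:
            raise AttenuationError(f"malformed table header for {name}")
        data = np.loadtxt(fh)
    return AttenuationTable(material=name, energies=data[:, 0], mu=data[:, 2])


_CACHE: Dict[str, AttenuationTable] = {}


def load_table(material: str) -> AttenuationTable:
    """Load a bundled material table by name (cached)."""
    if material not in MATERIAL_NAMES:
        raise AttenuationError(
            f"unknown material {material!r}; known: {', '.join(MATERIAL_NAMES)}"
        )
    if material not in _CACHE:
        _CACHE[material] = _read_table_file(material)
    return _CACHE[material]


def load_tables(materials: Iterable[str] = MATERIAL_NAMES) -> Dict[str, AttenuationTable]:
    return {m: load_table(m) for m in materials}


@dataclass(frozen=True)
class PathComposition:
    """Per-material intercept lengths (cm) along one ray.

    ``t_total`` is always the sum of the components; the breast-only length
    excludes the Lexan paddles.
    """

    lexan: float = 0.0
    skin: float = 0.0
    adipose: float = 0.0
    glandular: float = 0.0
    hydroxyapatite: float = 0.0

    def __post_init__(self) -> None:
        for name, value in self.items():
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"negative or non-finite length for {name}: {value}")

    def items(self):
        return (
            ("lexan", self.lexan),
            ("skin", self.skin),
            ("adipose", self.adipose),
            ("glandular", self.glandular),
            ("hydroxyapatite", self.hydroxyapatite),
        )

    @property
    def t_total(self) -> float:
        return sum(v for _, v in self.items())

    @property
    def t_breast(self) -> float:
        return self.t_total - self.lexan

    def mu_mix(self, e, tables: Dict[str, AttenuationTable] | None = None):
        """Composition-averaged mu(E) in 1/cm: sum_i mu_i(E) t_i / t_total."""
        if self.t_total <= 0:
            raise ValueError("mu_mix undefined for a zero-length composition")
        tables = tables or load_tables()
        e_arr = np.asarray(e, dtype=float)
        acc = np.zeros_like(e_arr)
        for name, t_i in self.items():
            if t_i > 0:
                acc = acc + mu_at(tables[name], e_arr) * (t_i / self.t_total)
        return float(acc) if np.isscalar(e) or e_arr.ndim == 0 else acc

    def scaled(self, factor: float) -> "PathComposition":
        return replace(
            self,
            lexan=self.lexan * factor, skin=self.skin * factor,
            adipose=self.adipose * factor, glandular=self.glandular * factor,
            hydroxyapatite=self.hydroxyapatite * factor,
        )


def reference_composition(
    breast_thickness: float,
    glandular_fraction: float = 0.5,
    skin_thickness: float = 0.145,
    n_skin_layers: int = 2,
    lexan_total: float = 0.5,
) -> PathComposition:
    """Nominal perpendicular-ray composition used when the true mix is unknown.

    The breast interior (thickness minus the skin layers) is split between
    adipose and glandular tissue at ``glandular_fraction``; paddles and skin
    enter at their nominal thicknesses.
    """
    t_skin = n_skin_layers * skin_thickness
    interior = breast_thickness - t_skin
    if interior <= 0:
        raise ValueError("breast thinner than its skin layers")
    if not 0.0 <= glandular_fraction <= 1.0:
        raise ValueError("glandular_fraction must lie in [0, 1]")
    return PathComposition(
        lexan=lexan_total,
        skin=t_skin,
        adipose=interior * (1.0 - glandular_fraction),
        glandular=interior * glandular_fraction,
    )
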
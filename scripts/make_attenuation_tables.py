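"""Regenerate the bundled linear-attenuation tables in src/glandfrac/data/.

Each material table is built from elemental mass attenuation coefficients
(cm^2/g, NIST XCOM-style values on the standard 10-50 keV grid) combined with
the elemental mass fractions of the material and its bulk density.  Elemental
values are interpolated log-log in energy (photoelectric absorption is close
to a power law in this range), then mixed:

    mu/rho (E) = sum_i w_i * (mu/rho)_i (E),      mu(E) = rho * mu/rho(E)

Silver carries its K edge at 25.514 keV, represented by a pair of grid points
bracketing the edge so that linear interpolation never crosses it.

Run from the repository root:  python scripts/make_attenuation_tables.py
"""

from __future__ import annotations

import pathlib

import numpy as np

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "glandfrac" / "data"

# cm^2/g at 10, 15, 20, 30, 40, 50 keV
_E_GRID = np.array([10.0, 15.0, 20.0, 30.0, 40.0, 50.0])
_ELEMENTS = {
    "H": [0.3854, 0.3764, 0.3695, 0.3570, 0.3458, 0.3355],
    "C": [2.373, 0.8071, 0.4420, 0.2562, 0.2076, 0.1871],
    "N": [3.879, 1.236, 0.6178, 0.3066, 0.2288, 0.1980],
    "O": [5.952, 1.836, 0.8651, 0.3779, 0.2585, 0.2132],
    "Na": [15.8, 4.80, 2.05, 0.74, 0.46, 0.36],
    "Al": [26.23, 7.955, 3.441, 1.128, 0.5685, 0.3681],
    "P": [40.1, 12.5, 5.35, 1.70, 0.81, 0.49],
    "S": [50.3, 15.3, 6.71, 2.11, 1.01, 0.61],
    "Cl": [59.0, 18.2, 8.00, 2.55, 1.19, 0.72],
    "K": [79.1, 24.6, 11.0, 3.41, 1.54, 0.88],
    "Ca": [93.4, 30.3, 13.06, 4.08, 1.83, 1.02],
}

# Silver: separate grid carrying the K edge (25.514 keV)
_AG_E = np.array([10.0, 15.0, 20.0, 25.513, 25.515, 30.0, 40.0, 50.0])
_AG_MU = np.array([118.7, 40.4, 18.36, 9.30, 55.2, 36.7, 16.8, 9.5])

# (mass fractions, density g/cm^3)
MATERIALS = {
    # ICRU-44 adipose tissue
    "adipose": (
        {"H": 0.114, "C": 0.598, "N": 0.007, "O": 0.278,
         "Na": 0.001, "S": 0.001, "Cl": 0.001},
        0.95,
    ),
    # Hammerstein et al. fibroglandular tissue
    "glandular": (
        {"H": 0.102, "C": 0.184, "N": 0.032, "O": 0.677, "P": 0.005},
        1.04,
    ),
    # ICRP soft-tissue skin
    "skin": (
        {"H": 0.100, "C": 0.204, "N": 0.042, "O": 0.645, "Na": 0.002,
         "P": 0.001, "S": 0.002, "Cl": 0.003, "K": 0.001},
        1.09,
    ),
    # polycarbonate C16H14O3 (compression paddles)
    "lexan": ({"H": 0.0555, "C": 0.7557, "O": 0.1888}, 1.20),
    "water": ({"H": 0.1119, "O": 0.8881}, 1.00),
    # Ca10(PO4)6(OH)2, type-II microcalcification mineral
    "hydroxyapatite": (
        {"Ca": 0.3989, "P": 0.1850, "O": 0.4141, "H": 0.0020},
        3.18,
    ),
    "aluminum": ({"Al": 1.0}, 2.699),
}
AG_DENSITY = 10.49


def _loglog_interp(e_out: np.ndarray, e_in: np.ndarray, mu_in: np.ndarray) -> np.ndarray:
    return np.exp(np.interp(np.log(e_out), np.log(e_in), np.log(mu_in)))


def build_fine_grid() -> np.ndarray:
    return np.round(np.arange(10.0, 45.0 + 1e-9, 0.5), 3)


def material_mu_over_rho(name: str, energies: np.ndarray) -> np.ndarray:
    fractions, _rho = MATERIALS[name]
    out = np.zeros_like(energies, dtype=float)
    for el, w in fractions.items():
        out += w * _loglog_interp(energies, _E_GRID, np.asarray(_ELEMENTS[el]))
    return out


def write_table(path: pathlib.Path, name: str, energies: np.ndarray,
                mu_over_rho: np.ndarray, rho: float) -> None:
    mu = mu_over_rho * rho
    with open(path, "w") as fh:
        fh.write(f"energy_keV mu_over_rho_cm2_g mu_per_cm  # material={name} density_g_cm3={rho}\n")
        for e, mr, m in zip(energies, mu_over_rho, mu):
            fh.write(f"{e:.3f} {mr:.6e} {m:.6e}\n")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    fine = build_fine_grid()
    for name, (_fracs, rho) in MATERIALS.items():
        write_table(OUT / f"{name}.txt", name, fine, material_mu_over_rho(name, fine), rho)
    # silver keeps its native edge-aware grid, densified between the nodes
    ag_fine = np.unique(np.concatenate([
        np.arange(10.0, 25.0 + 1e-9, 0.5), [25.513, 25.515],
        np.arange(26.0, 45.0 + 1e-9, 0.5),
    ]))
    lo = ag_fine <= 25.513
    mu_ag = np.empty_like(ag_fine)
    mu_ag[lo] = _loglog_interp(ag_fine[lo], _AG_E[:4], _AG_MU[:4])
    mu_ag[~lo] = _loglog_interp(ag_fine[~lo], _AG_E[4:], _AG_MU[4:])
    write_table(OUT / "silver.txt", "silver", ag_fine, mu_ag, AG_DENSITY)
    print(f"wrote {len(MATERIALS) + 1} tables to {OUT}")


if __name__ == "__main__":
    main()
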
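"""Forward projection simulator: expected counts, scatter and Poisson noise.

The simulator stands in for Monte Carlo photon transport with an analytic
model: per-pixel polychromatic Beer-Lambert primaries from the exact traced
path decomposition, a scatter expectation built multiplicatively from a
thickness-driven scatter-to-primary-ratio (SPR) table, an anti-scatter-grid
model that scales scatter down to a remnant fraction, and Poisson sampling
of the total.  Ground truth (primary, scatter, SPR map, paths) is retained
alongside the sampled image.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
from scipy import ndimage

from .materials import AttenuationTable, load_tables, mu_at
from .phantom import (
    BreastPhantom,
    InvalidPhantomError,
    PathDecomposition,
    ProjectionGeometry,
    trace_paths,
)
from .spectrum import EnergySpectrum

__all__ = [
    "SprModel",
    "CountImage",
    "DEFAULT_SPR",
    "spr_value",
    "simulate_projection",
    "apply_asg",
    "insert_microcalcs_phantom",
    "insert_microcalcs_counts",
]

_RASTER_MATERIALS = ("lexan", "skin", "adipose", "glandular", "hydroxyapatite")


@dataclass(frozen=True)
class SprModel:
    """Monotone scatter-to-primary ratio versus breast thickness (cm)."""

    thicknesses: np.ndarray
    spr: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.thicknesses, dtype=float)
        s = np.asarray(self.spr, dtype=float)
        object.__setattr__(self, "thicknesses", t)
        object.__setattr__(self, "spr", s)
        if np.any(np.diff(t) <= 0) or np.any(s < 0):
            raise ValueError("SPR table must have increasing thickness and SPR >= 0")

    def __call__(self, t_breast):
        return spr_value(t_breast, self)

    def scaled(self, factor: float) -> "SprModel":
        return replace(self, spr=self.spr * factor)


# Thickness-only SPR for gridless mammography at mammographic energies with a
# small air gap; values follow the published contact-geometry range (~0.3 at
# 2 cm rising toward ~1 at 9 cm), linearly interpolated.
DEFAULT_SPR = SprModel(
    thicknesses=np.array([0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 12.0]),
    spr=np.array([0.0, 0.08, 0.15, 0.30, 0.40, 0.48, 0.57, 0.67, 0.78, 0.89, 1.00, 1.25]),
)


def spr_value(t_breast, model: SprModel = DEFAULT_SPR):
    """Interpolated SPR at breast thickness ``t_breast`` (cm); SPR(0) = 0."""
    t = np.asarray(t_breast, dtype=float)
    if np.any(t < 0):
        raise ValueError("breast thickness must be >= 0")
    out = np.interp(t, model.thicknesses, model.spr)
    return float(out) if np.isscalar(t_breast) or t.ndim == 0 else out


@dataclass
class CountImage:
    """Aligned count rasters with the ground truth used to generate them."""

    i0: np.ndarray          # flat-field expectation
    primary: np.ndarray     # expected primary counts
    scatter: np.ndarray     # expected scatter counts
    measured: np.ndarray    # Poisson sample (or the expectation, see poisson)
    spr_map: np.ndarray
    paths: PathDecomposition
    spectrum: EnergySpectrum
    geometry: ProjectionGeometry
    phantom: Optional[BreastPhantom]
    seed: Optional[int]
    poisson: bool
    meta: dict = field(default_factory=dict)

    @property
    def expected(self) -> np.ndarray:
        return self.primary + self.scatter


def _per_pixel_transmission(
    paths: PathDecomposition,
    spectrum: EnergySpectrum,
    tables: Dict[str, AttenuationTable],
) -> np.ndarray:
    rasters = {
        "lexan": paths.t_lexan, "skin": paths.t_skin, "adipose": paths.t_adipose,
        "glandular": paths.t_glandular, "hydroxyapatite": paths.t_calc,
    }
    w = spectrum.normalized_weights
    out = np.zeros(paths.t_lexan.shape, dtype=float)
    for wb, e in zip(w, spectrum.energies):
        optical = np.zeros_like(out)
        for name in _RASTER_MATERIALS:
            t_r = rasters[name]
            if np.any(t_r > 0):
                optical += mu_at(tables[name], float(e)) * t_r
        out += wb * np.exp(-optical)
    return out


def simulate_projection(
    phantom: Optional[BreastPhantom],
    geom: ProjectionGeometry,
    spectrum: EnergySpectrum,
    counts_per_pixel_flatfield: float = 30000.0,
    spr_model: Optional[SprModel] = DEFAULT_SPR,
    seed: Optional[int] = None,
    poisson: bool = True,
    falloff: bool = True,
    spr_smooth_sigma_cm: float = 1.0,
    tables: Optional[Dict[str, AttenuationTable]] = None,
    paths: Optional[PathDecomposition] = None,
) -> CountImage:
    """Simulate a raw count image (and its flat field) for one phantom.

    ``falloff`` applies the inverse-square/obliquity (cos^3 theta) factor to
    the flat field; ``poisson=False`` returns expectation-mode images
    (``measured`` equals ``primary + scatter`` exactly).  ``spr_smooth_sigma_cm``
    low-pass filters the SPR map to mimic the spatial diffuseness of scatter.
    With a fixed seed the simulation is bit-reproducible.
    """
    if counts_per_pixel_flatfield <= 0:
        raise ValueError("counts_per_pixel_flatfield must be positive")
    tables = tables or load_tables()

    if phantom is None:
        ny, nx = geom.shape
        empty = BreastPhantom(thickness=1.0, glandular_height=0.0)
        paths = paths or trace_paths(empty, geom)
        zeros = np.zeros(geom.shape)
        transmission = np.ones(geom.shape)
        paths = replace(paths, t_lexan=zeros.copy(), t_skin=zeros.copy(),
                        t_adipose=zeros.copy(), t_glandular=zeros.copy(),
                        t_calc=zeros.copy(), mask=np.zeros(geom.shape, dtype=bool),
                        glandular_full=np.zeros(geom.shape, dtype=bool),
                        phantom=None)
    else:
        paths = paths or trace_paths(phantom, geom)
        transmission = _per_pixel_transmission(paths, spectrum, tables)

    i0 = np.full(geom.shape, float(counts_per_pixel_flatfield))
    if falloff:
        i0 *= paths.cos_theta**3
    primary = i0 * transmission

    if spr_model is None or phantom is None:
        spr_map = np.zeros(geom.shape)
    else:
        spr_map = spr_value(paths.t_breast, spr_model)
        if spr_smooth_sigma_cm and spr_smooth_sigma_cm > 0:
            spr_map = ndimage.gaussian_filter(
                spr_map, sigma=spr_smooth_sigma_cm / geom.pixel_pitch
            )
    scatter = spr_map * primary

    expected = primary + scatter
    if poisson:
        rng = np.random.default_rng(seed)
        measured = rng.poisson(expected).astype(np.int64)
    else:
        measured = expected.copy()

    return CountImage(
        i0=i0, primary=primary, scatter=scatter, measured=measured,
        spr_map=spr_map, paths=paths, spectrum=spectrum, geometry=geom,
        phantom=phantom, seed=seed, poisson=poisson,
        meta={"counts_per_pixel_flatfield": counts_per_pixel_flatfield,
              "falloff": falloff, "spr_smooth_sigma_cm": spr_smooth_sigma_cm},
    )


def apply_asg(
    img: CountImage,
    removal_fraction: float = 0.75,
    seed: Optional[int] = None,
) -> CountImage:
    """Anti-scatter-grid model: keep a remnant of the scatter expectation.

    Equivalent to scaling the scatter-only image by ``1 - removal_fraction``
    and adding it back to the primary-only image; the measured image is
    re-sampled as Poisson(primary + remnant scatter) unless the input was in
    expectation mode.
    """
    if not 0.0 <= removal_fraction <= 1.0:
        raise ValueError("removal_fraction must lie in [0, 1]")
    remnant = (1.0 - removal_fraction) * img.scatter
    expected = img.primary + remnant
    if img.poisson:
        rng = np.random.default_rng(seed)
        measured = rng.poisson(expected).astype(np.int64)
    else:
        measured = expected.copy()
    meta = dict(img.meta, asg_removal_fraction=removal_fraction)
    return replace(img, scatter=remnant, measured=measured, seed=seed, meta=meta)


def insert_microcalcs_phantom(phantom: BreastPhantom, calcs) -> BreastPhantom:
    """Return a phantom with the deposits added (full polychromatic treatment)."""
    calcs = tuple(calcs)
    out = replace(phantom, microcalcs=phantom.microcalcs + calcs)
    # validation of placement happens in trace_paths, but catch gross errors now
    for mc in calcs:
        if np.hypot(mc.x, mc.y) + mc.diameter / 2 > phantom.glandular_radius:
            raise InvalidPhantomError("microcalcification outside the glandular radius")
    return out


def insert_microcalcs_counts(
    image: np.ndarray,
    calcs,
    geom: ProjectionGeometry,
    mu_calc: float,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Attenuate raw counts under each deposit's projected footprint.

    Counts are multiplied by ``exp(-mu_calc * h)`` with ``h`` the per-pixel
    chord through the deposit cylinder and ``mu_calc`` the hydroxyapatite
    attenuation (1/cm) at the working effective energy.
    """
    sdd = geom.source_detector_distance
    xd, yd = geom.pixel_centers()
    lf = np.sqrt(xd**2 + yd**2 + sdd**2) / sdd
    out = np.asarray(image, dtype=float).copy()
    for mc in calcs:
        a = xd**2 + yd**2
        b = -2.0 * (xd * mc.x + yd * mc.y)
        c0 = mc.x**2 + mc.y**2 - (mc.diameter / 2) ** 2
        disc = b**2 - 4.0 * a * c0
        hit = disc > 0
        sq = np.sqrt(np.where(hit, disc, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            u1 = (-b - sq) / (2.0 * a)
            u2 = (-b + sq) / (2.0 * a)
        z1 = sdd * (1.0 - np.maximum(u1, u2))
        z2 = sdd * (1.0 - np.minimum(u1, u2))
        c_lo, c_hi = mc.z_center - mc.height / 2, mc.z_center + mc.height / 2
        chord = np.clip(np.minimum(c_hi, z2) - np.maximum(c_lo, z1), 0.0, None)
        h = np.where(hit, chord * lf, 0.0)
        if mask is not None and np.any((h > 0) & ~mask):
            raise ValueError("microcalcification footprint outside the mask")
        factor = np.exp(-mu_calc * h)
        if np.any(factor <= 0) or np.any(factor > 1.0 + 1e-12):
            raise ValueError("attenuation factors must lie in (0, 1]")
        out *= factor
    return out
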
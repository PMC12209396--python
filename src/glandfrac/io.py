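"""Readers/writers, acquisition metadata, flat-field estimation and masking.

Simulated images travel as a directory bundle: one ``arrays.npz`` with the
2-D rasters (C-order, little-endian float64/bool, shape recorded by numpy)
plus a ``meta.yaml`` sidecar with geometry, spectrum, phantom and seed
metadata.  Clinical-style raw ("for-processing") DICOM images are read with
pydicom; every header-derived quantity records its provenance (header tag
vs default vs manual override).
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import yaml
from scipy import ndimage, stats

from .materials import load_tables, mu_at
from .phantom import ProjectionGeometry
from .simulate import CountImage
from .spectrum import EnergySpectrum

__all__ = [
    "AcquisitionMeta",
    "BreastMask",
    "write_bundle",
    "read_bundle",
    "export_tiff",
    "read_raw_dicom",
    "estimate_i0_from_background",
    "make_breast_mask",
]


@dataclass
class AcquisitionMeta:
    compressed_thickness: float      # cm
    kvp: float
    anode: str = "W"
    filter_material: str = "Al"
    filter_thickness: float = 0.7    # mm
    paddle_thickness: float = 0.25   # cm, per paddle
    pixel_pitch: float = 0.1         # cm
    source: str = "manual"           # "dicom" | "simulation" | "manual"
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.compressed_thickness <= 0:
            raise ValueError("compressed thickness must be positive")
        if self.kvp <= 0:
            raise ValueError("kvp must be positive")


@dataclass
class BreastMask:
    mask: np.ndarray
    exclusions: Dict[str, int] = field(default_factory=dict)


_RASTERS = ("i0", "primary", "scatter", "measured", "spr_map",
            "t_lexan", "t_skin", "t_adipose", "t_glandular", "t_calc",
            "mask", "glandular_full", "cos_theta")


def write_bundle(path, img: CountImage) -> pathlib.Path:
    """Write a CountImage and its ground truth to a directory bundle."""
    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    p = img.paths
    arrays = {
        "i0": img.i0, "primary": img.primary, "scatter": img.scatter,
        "measured": img.measured, "spr_map": img.spr_map,
        "t_lexan": p.t_lexan, "t_skin": p.t_skin, "t_adipose": p.t_adipose,
        "t_glandular": p.t_glandular, "t_calc": p.t_calc,
        "mask": p.mask, "glandular_full": p.glandular_full,
        "cos_theta": p.cos_theta,
    }
    np.savez(path / "arrays.npz", **arrays)
    geom = img.geometry
    meta = {
        "format": "glandfrac-bundle-1",
        "array_order": "C (row-major), rows = detector y, cols = detector x",
        "byte_order": "little-endian (numpy .npz)",
        "shape": list(img.measured.shape),
        "seed": img.seed,
        "poisson": bool(img.poisson),
        "geometry": {
            "source_detector_distance": geom.source_detector_distance,
            "air_gap": geom.air_gap,
            "detector_size": list(geom.detector_size),
            "pixel_pitch": geom.pixel_pitch,
        },
        "spectrum": {
            "energies_keV": [float(e) for e in img.spectrum.energies],
            "weights": [float(w) for w in img.spectrum.weights],
            "kvp": img.spectrum.kvp,
            "anode": img.spectrum.anode,
            "filter_material": img.spectrum.filter_material,
            "filter_thickness_mm": img.spectrum.filter_thickness,
        },
        "phantom": None if img.phantom is None else {
            "thickness": img.phantom.thickness,
            "outer_radius": img.phantom.outer_radius,
            "glandular_radius": img.phantom.glandular_radius,
            "glandular_height": img.phantom.glandular_height,
            "glandular_offset": img.phantom.glandular_offset,
            "skin_thickness": img.phantom.skin_thickness,
            "n_skin_layers": img.phantom.n_skin_layers,
            "paddle_thickness_each": img.phantom.paddle_thickness_each,
            "n_paddles": img.phantom.n_paddles,
        },
        "extra": {k: v for k, v in img.meta.items()},
    }
    with open(path / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def read_bundle(path) -> Tuple[Dict[str, np.ndarray], dict]:
    """Read a bundle back as (arrays dict, metadata dict)."""
    path = pathlib.Path(path)
    with np.load(path / "arrays.npz") as z:
        arrays = {k: z[k] for k in z.files}
    with open(path / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    return arrays, meta


def bundle_spectrum(meta: dict) -> EnergySpectrum:
    s = meta["spectrum"]
    return EnergySpectrum(
        energies=np.array(s["energies_keV"]), weights=np.array(s["weights"]),
        kvp=s["kvp"], anode=s["anode"], filter_material=s["filter_material"],
        filter_thickness=s["filter_thickness_mm"],
    )


def bundle_geometry(meta: dict) -> ProjectionGeometry:
    g = meta["geometry"]
    return ProjectionGeometry(
        source_detector_distance=g["source_detector_distance"],
        air_gap=g["air_gap"], detector_size=tuple(g["detector_size"]),
        pixel_pitch=g["pixel_pitch"],
    )


def export_tiff(path, raster: np.ndarray) -> None:
    """16-bit TIFF export for viewing (values rescaled to the full range)."""
    import tifffile

    r = np.asarray(raster, dtype=float)
    finite = np.isfinite(r)
    lo, hi = r[finite].min(), r[finite].max()
    scale = (r - lo) / (hi - lo) if hi > lo else np.zeros_like(r)
    scale[~finite] = 0.0
    tifffile.imwrite(path, (scale * 65535).astype(np.uint16))


# DICOM attributes searched for the compressed breast thickness, in order
_THICKNESS_TAGS = ("BodyPartThickness",)
_FILTER_NAME = {"ALUMINUM": "Al", "AL": "Al", "SILVER": "Ag", "AG": "Ag",
                "RHODIUM": "Rh", "MOLYBDENUM": "Mo"}
_ANODE_NAME = {"TUNGSTEN": "W", "W": "W", "MOLYBDENUM": "Mo", "RHODIUM": "Rh"}


def read_raw_dicom(path, thickness_override: Optional[float] = None
                   ) -> Tuple[np.ndarray, AcquisitionMeta]:
    """Read a raw/"for-processing" monochrome DICOM mammogram.

    Pixel data are returned with the rescale slope/intercept applied.
    Metadata fall back to documented defaults (recorded in ``provenance``)
    when a header attribute is absent; a missing thickness with no manual
    override is an error naming the attributes searched.
    """
    import pydicom
    from pydicom.errors import InvalidDicomError

    try:
        ds = pydicom.dcmread(str(path))
    except InvalidDicomError as exc:
        raise ValueError(f"not a DICOM file: {path}") from exc

    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept

    prov: Dict[str, str] = {}
    thickness_mm = None
    for tag in _THICKNESS_TAGS:
        if getattr(ds, tag, None) is not None:
            thickness_mm = float(getattr(ds, tag))
            prov["compressed_thickness"] = f"header:{tag}"
            break
    if thickness_mm is None:
        if thickness_override is None:
            raise ValueError(
                "compressed breast thickness not found (searched: "
                f"{', '.join(_THICKNESS_TAGS)}) and no manual override given"
            )
        thickness_cm = float(thickness_override)
        prov["compressed_thickness"] = "manual"
    else:
        thickness_cm = thickness_mm / 10.0

    kvp = float(getattr(ds, "KVP", 28.0))
    prov["kvp"] = "header:KVP" if getattr(ds, "KVP", None) is not None else "default"

    anode_raw = str(getattr(ds, "AnodeTargetMaterial", "TUNGSTEN")).upper()
    anode = _ANODE_NAME.get(anode_raw, anode_raw)
    prov["anode"] = ("header:AnodeTargetMaterial"
                     if getattr(ds, "AnodeTargetMaterial", None) is not None else "default")

    filt_raw = str(getattr(ds, "FilterMaterial", "ALUMINUM")).upper()
    filt = _FILTER_NAME.get(filt_raw, filt_raw)
    prov["filter_material"] = ("header:FilterMaterial"
                               if getattr(ds, "FilterMaterial", None) is not None else "default")
    ft = getattr(ds, "FilterThicknessMinimum", None)
    filter_thickness = float(ft) if ft is not None else (0.05 if filt == "Ag" else 0.7)
    prov["filter_thickness"] = ("header:FilterThicknessMinimum" if ft is not None
                                else "default")

    # paddle thickness is rarely in the header; assume the standard 2.5 mm
    prov["paddle_thickness"] = "default"

    ps = getattr(ds, "PixelSpacing", None)
    pitch = float(ps[0]) / 10.0 if ps is not None else 0.1
    prov["pixel_pitch"] = "header:PixelSpacing" if ps is not None else "default"

    meta = AcquisitionMeta(
        compressed_thickness=thickness_cm, kvp=kvp, anode=anode,
        filter_material=filt, filter_thickness=filter_thickness,
        paddle_thickness=0.25, pixel_pitch=pitch, source="dicom",
        provenance=prov,
    )
    return arr, meta


def estimate_i0_from_background(
    image: np.ndarray,
    object_mask: Optional[np.ndarray] = None,
    trim: float = 0.1,
    column_fraction: float = 0.95,
) -> Tuple[float, np.ndarray]:
    """Flat-field estimate from unattenuated columns beside the object.

    Columns whose trimmed-mean counts reach ``column_fraction`` of the
    brightest column are treated as background; the value returned is their
    trimmed mean (robust to stray attenuated pixels at the object edge),
    together with the column indices used.
    """
    image = np.asarray(image, dtype=float)
    work = image.copy()
    if object_mask is not None:
        work = np.where(np.asarray(object_mask, dtype=bool), np.nan, work)
    col_ok = np.isfinite(work).all(axis=0)
    if not col_ok.any():
        raise ValueError("no background columns in the field of view; supply I0 manually")
    col_means = np.full(image.shape[1], -np.inf)
    for c in np.flatnonzero(col_ok):
        col_means[c] = stats.trim_mean(work[:, c], trim)
    best = col_means.max()
    cols = np.flatnonzero(col_means >= column_fraction * best)
    values = work[:, cols].ravel()
    return float(stats.trim_mean(values, trim)), cols


def make_breast_mask(
    image: np.ndarray,
    i0: np.ndarray | float,
    meta: AcquisitionMeta,
    e_eff: float = 20.0,
    safety: float = 0.85,
    erode_mm: float = 2.0,
    tables=None,
) -> BreastMask:
    """In-tissue mask by thresholding the log signal against the minimum
    full-thickness attenuation (pure adipose interior plus paddles at the
    working effective energy), eroded to drop marginal pixels.

    ``safety`` leaves headroom for scatter (which inflates Im and lowers the
    log signal) and for the difference between the adipose floor and the
    true composition.
    """
    tables = tables or load_tables()
    image = np.asarray(image, dtype=float)
    i0 = np.broadcast_to(np.asarray(i0, dtype=float), image.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        logsig = np.log(i0 / np.maximum(image, 1e-12))
    mu_a = mu_at(tables["adipose"], e_eff)
    mu_l = mu_at(tables["lexan"], e_eff)
    a_min = mu_a * meta.compressed_thickness + mu_l * 2 * meta.paddle_thickness
    raw = logsig >= safety * a_min
    n_background = int((~raw).sum())
    erode_px = max(int(round(erode_mm / 10.0 / meta.pixel_pitch)), 0)
    mask = ndimage.binary_erosion(raw, iterations=erode_px) if erode_px else raw
    if not mask.any():
        raise ValueError("empty breast mask")
    return BreastMask(
        mask=mask,
        exclusions={"background": n_background,
                    "margin": int(raw.sum() - mask.sum())},
    )
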
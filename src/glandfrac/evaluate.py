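"""Evaluation: error statistics, microcalcification CNR, display mapping,
and the experiment harness that replays the simulation study grids.

Error statistics are expressed in percentage points of glandular fraction.
CNR uses the standard (x_s - x_bg)/sigma_bg definition; improvements are
compared on absolute CNRs because the glandular-fraction image inverts the
contrast polarity of a calcification (a count deficit becomes a GF excess).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .gf import GFImage, estimate_gf_from_sim
from .materials import PathComposition, load_tables
from .phantom import MicroCalc, ProjectionGeometry, trace_paths, build_phantom
from .simulate import (
    DEFAULT_SPR,
    SprModel,
    apply_asg,
    insert_microcalcs_phantom,
    simulate_projection,
)
from .spectrum import EnergySpectrum, build_spectrum, loss_percent_error

__all__ = [
    "GfErrorStats",
    "CNRReport",
    "DisplayMapping",
    "gf_error_stats",
    "compute_cnr",
    "cnr_improvement",
    "fit_display_mapping",
    "apply_display_mapping",
    "GridConfig",
    "study_spectrum",
    "run_loss_error_table",
    "run_gf_grid",
    "run_location_study",
    "run_cnr_study",
    "run_experiment_grid",
]


@dataclass(frozen=True)
class GfErrorStats:
    """Per-configuration error summary, in percentage points of GF."""

    mean_estimate: float
    sd_estimate: float
    mae: float
    rmse: float
    bias: float
    n_pixels: int
    label: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CNRReport:
    xs: float
    xbg: float
    sigma_bg: float
    cnr: float
    n_signal: int
    n_background: int
    roi: dict = field(default_factory=dict)


@dataclass(frozen=True)
class DisplayMapping:
    """Monotone lookup from log-processed linear values to display values."""

    x_centers: np.ndarray
    y_values: np.ndarray   # non-decreasing
    domain: Tuple[float, float]
    max_abs_residual: float


def gf_error_stats(
    gf: GFImage | np.ndarray,
    truth: np.ndarray,
    mask: np.ndarray,
    label: Optional[dict] = None,
) -> GfErrorStats:
    """RMSE/MAE/bias of the estimate against per-pixel ground truth."""
    est = gf.m if isinstance(gf, GFImage) else np.asarray(gf, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if isinstance(gf, GFImage):
        mask = mask & gf.mask
    mask = mask & np.isfinite(est) & np.isfinite(truth)
    if not mask.any():
        raise ValueError("empty mask")
    err = (est[mask] - np.asarray(truth, dtype=float)[mask]) * 100.0
    return GfErrorStats(
        mean_estimate=float(np.mean(est[mask])),
        sd_estimate=float(np.std(est[mask])),
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err**2))),
        bias=float(np.mean(err)),
        n_pixels=int(mask.sum()),
        label=label or {},
    )


def pooled_error_stats(errors_pp: Sequence[np.ndarray], label: Optional[dict] = None) -> GfErrorStats:
    """Pool pixel-level errors (percentage points) across configurations."""
    err = np.concatenate([np.ravel(e) for e in errors_pp])
    return GfErrorStats(
        mean_estimate=float("nan"), sd_estimate=float(np.std(err)),
        mae=float(np.mean(np.abs(err))), rmse=float(np.sqrt(np.mean(err**2))),
        bias=float(np.mean(err)), n_pixels=int(err.size), label=label or {},
    )


def compute_cnr(image: np.ndarray, signal_roi: np.ndarray, bg_roi: np.ndarray) -> CNRReport:
    """CNR = (mean signal - mean background)/sd background on the two ROIs."""
    image = np.asarray(image, dtype=float)
    s = np.asarray(signal_roi, dtype=bool)
    b = np.asarray(bg_roi, dtype=bool)
    if np.any(s & b):
        raise ValueError("signal and background ROIs must be disjoint")
    if s.sum() < 1 or b.sum() < 2:
        raise ValueError("signal ROI needs >= 1 pixel and background >= 2")
    xs = float(np.mean(image[s]))
    xbg = float(np.mean(image[b]))
    sigma = float(np.std(image[b], ddof=1))
    if sigma == 0.0:
        raise ValueError("zero background standard deviation")
    return CNRReport(xs=xs, xbg=xbg, sigma_bg=sigma, cnr=(xs - xbg) / sigma,
                     n_signal=int(s.sum()), n_background=int(b.sum()))


def cnr_improvement(cnr_gf: CNRReport | float, cnr_ref: CNRReport | float) -> float:
    """Percent improvement on absolute CNRs: (|gf| - |ref|)/|ref| x 100."""
    g = cnr_gf.cnr if isinstance(cnr_gf, CNRReport) else float(cnr_gf)
    r = cnr_ref.cnr if isinstance(cnr_ref, CNRReport) else float(cnr_ref)
    if r == 0.0:
        raise ZeroDivisionError("reference CNR is zero")
    return (abs(g) - abs(r)) / abs(r) * 100.0


def calc_rois(
    paths,
    calc: MicroCalc,
    geom: ProjectionGeometry,
    annulus_cm: Tuple[float, float] = (0.2, 0.5),
    restrict: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Signal ROI = projected calcification footprint; background ROI = an
    annulus around it restricted to the glandular-shadow interior and clear
    of every calcification footprint."""
    signal = paths.t_calc > 0
    xd, yd = geom.pixel_centers()
    # project the deposit center to the detector along the cone beam
    scale = geom.source_detector_distance / (geom.source_detector_distance - calc.z_center)
    cx, cy = calc.x * scale, calc.y * scale
    dist = np.hypot(xd - cx, yd - cy)
    this_calc = signal & (dist <= max(calc.diameter * scale, 2 * geom.pixel_pitch))
    bg = (dist >= annulus_cm[0]) & (dist <= annulus_cm[1]) & ~signal
    if restrict is not None:
        bg &= restrict
    return this_calc, bg


def fit_display_mapping(
    log_linear: np.ndarray,
    display: np.ndarray,
    mask: Optional[np.ndarray] = None,
    n_bins: int = 256,
) -> DisplayMapping:
    """Monotone binned-median fit of the vendor display transform.

    The fit domain is binned uniformly; each bin's display value is the
    median of its samples, made non-decreasing by a running maximum, and
    applied with linear interpolation between bin centers.
    """
    x = np.asarray(log_linear, dtype=float)
    y = np.asarray(display, dtype=float)
    m = np.ones(x.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    xv, yv = x[m], y[m]
    lo, hi = float(xv.min()), float(xv.max())
    if hi <= lo:
        raise ValueError("degenerate (constant) log-linear input")
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(xv, edges) - 1, 0, n_bins - 1)
    med = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            med[b] = np.median(yv[sel])
    good = np.isfinite(med)
    med = np.interp(centers, centers[good], med[good])
    med = np.maximum.accumulate(med)
    fitted = np.interp(xv, centers, med)
    return DisplayMapping(
        x_centers=centers, y_values=med, domain=(lo, hi),
        max_abs_residual=float(np.max(np.abs(fitted - yv))),
    )


def apply_display_mapping(mapping: DisplayMapping, log_linear: np.ndarray) -> np.ndarray:
    return np.interp(np.asarray(log_linear, dtype=float),
                     mapping.x_centers, mapping.y_values)


# ---------------------------------------------------------------------------
# experiment harness
# ---------------------------------------------------------------------------

def study_spectrum(name: str = "W/Al") -> EnergySpectrum:
    """The two study beams: broad W/Al 28 kV (14-28 keV in 2 keV bins) and
    the narrower W/Ag 34 kV clinical beam."""
    if name == "W/Al":
        return build_spectrum(28.0, "W", "Al", 0.7, bin_width=2.0, e_min=14.0)
    if name == "W/Ag":
        return build_spectrum(34.0, "W", "Ag", 0.05, bin_width=1.0, e_min=10.0)
    raise ValueError(f"unknown study spectrum {name!r}")


@dataclass
class GridConfig:
    thicknesses: Sequence[float] = tuple(range(2, 10))
    gfs: Sequence[float] = (0.2, 0.3, 0.5)
    spectrum: str = "W/Al"
    counts_per_pixel: float = 30000.0
    seeds: Sequence[int] = (0, 1, 2)
    asg_removal_fraction: float = 0.75
    spr_model: SprModel = field(default_factory=lambda: DEFAULT_SPR)
    scatter_mode: str = "model"
    erode_px: int = 2
    geometry: ProjectionGeometry = field(default_factory=ProjectionGeometry)


def _simulate_cell(
    T: float,
    gf: float,
    cfg: GridConfig,
    seed,
    poisson: bool = True,
    asg: bool = False,
    offset: float = 0.0,
    calcs: Tuple[MicroCalc, ...] = (),
    spectrum: Optional[EnergySpectrum] = None,
    paths=None,
):
    spec = spectrum or study_spectrum(cfg.spectrum)
    ph = build_phantom(T, gf, glandular_offset=offset)
    if calcs:
        ph = insert_microcalcs_phantom(ph, calcs)
    seed = None if seed is None else int(seed)
    sub = None if seed is None else [seed, seed + 1]
    img = simulate_projection(
        ph, cfg.geometry, spec, cfg.counts_per_pixel, cfg.spr_model,
        seed=None if sub is None else sub[0], poisson=poisson, paths=paths,
    )
    if asg:
        img = apply_asg(img, cfg.asg_removal_fraction,
                        seed=None if sub is None else sub[1])
    return img


def run_loss_error_table(cfg: Optional[GridConfig] = None) -> pd.DataFrame:
    """Polychromatic vs effective-energy count-loss percent error, per cell.

    Expectation-mode, absorption-only images: the monochromatic counterpart
    is built at the effective energy matched to the acquisition's total
    equivalent attenuation, and the loss error follows the
    (loss_poly - loss_mono)/loss_mono definition.
    """
    cfg = cfg or GridConfig()
    spec = study_spectrum(cfg.spectrum)
    tables = load_tables()
    rows = []
    for T in cfg.thicknesses:
        for gf in cfg.gfs:
            ph = build_phantom(T, gf)
            paths = trace_paths(ph, cfg.geometry)
            img = simulate_projection(ph, cfg.geometry, spec, cfg.counts_per_pixel,
                                      spr_model=None, poisson=False, paths=paths)
            msk = paths.mask
            i0_tot = float(img.i0[msk].sum())
            im_poly = float(img.primary[msk].sum())
            # matched effective energy: the acquisition's total equivalent
            # attenuation, solved against the mask-average composition
            t_bar = float(np.mean(paths.t_total[msk]))
            mu_eq = -np.log(im_poly / i0_tot) / t_bar
            ref = PathComposition(
                lexan=float(paths.t_lexan[msk].mean()),
                skin=float(paths.t_skin[msk].mean()),
                adipose=float(paths.t_adipose[msk].mean()),
                glandular=float(paths.t_glandular[msk].mean()),
            )
            from .spectrum import effective_energy_from_mu
            ee = effective_energy_from_mu(
                mu_eq, ref, float(spec.energies[0]), float(spec.energies[-1]), tables
            )
            mono = EnergySpectrum.monochromatic(ee.e_eff)
            img_m = simulate_projection(ph, cfg.geometry, mono, cfg.counts_per_pixel,
                                        spr_model=None, poisson=False, paths=paths)
            im_mono = float(img_m.primary[msk].sum())
            err = loss_percent_error(i0_tot, im_poly, im_mono)
            rows.append({"T_cm": T, "gf": gf, "e_eff_keV": ee.e_eff,
                         "loss_error_pct": err})
    return pd.DataFrame(rows)


def run_gf_grid(
    cfg: Optional[GridConfig] = None,
    asg: bool = True,
    poisson: bool = True,
) -> Tuple[pd.DataFrame, GfErrorStats]:
    """Full (T, GF) grid for one branch; returns per-configuration stats and
    the pixel-pooled summary across all configurations and seeds."""
    cfg = cfg or GridConfig()
    spec = study_spectrum(cfg.spectrum)
    rows: List[dict] = []
    pooled: List[np.ndarray] = []
    seeds = cfg.seeds if poisson else (None,)
    for T in cfg.thicknesses:
        for gf in cfg.gfs:
            ph = build_phantom(T, gf)
            paths = trace_paths(ph, cfg.geometry)
            interior = paths.glandular_interior(cfg.erode_px)
            truth = paths.m_true
            for seed in seeds:
                img = _simulate_cell(T, gf, cfg, seed, poisson=poisson, asg=asg,
                                     spectrum=spec, paths=paths)
                est = estimate_gf_from_sim(
                    img, spr_model=cfg.spr_model, scatter_mode=cfg.scatter_mode,
                    ref_glandular_fraction=gf,
                )
                st = gf_error_stats(est, truth, interior,
                                    label={"T_cm": T, "gf": gf, "seed": seed,
                                           "branch": "asg" if asg else "gridless"})
                rows.append({**st.label, "mean": st.mean_estimate, "sd": st.sd_estimate,
                             "mae_pp": st.mae, "rmse_pp": st.rmse, "bias_pp": st.bias,
                             "n": st.n_pixels, "e_eff_keV": est.meta["e_eff"]})
                msk = interior & est.mask
                pooled.append((est.m[msk] - truth[msk]) * 100.0)
    summary = pooled_error_stats(pooled, label={"branch": "asg" if asg else "gridless",
                                                "spectrum": cfg.spectrum})
    return pd.DataFrame(rows), summary


def run_location_study(
    cfg: Optional[GridConfig] = None,
    T: float = 4.0,
    gf: float = 0.2,
    offsets: Sequence[float] = (-1.0, 0.0, 1.0),
    asg: bool = True,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Mean estimated GF for different axial placements of the glandular slab."""
    cfg = cfg or GridConfig()
    spec = study_spectrum(cfg.spectrum)
    rows = []
    for i, off in enumerate(offsets):
        img = _simulate_cell(T, gf, cfg, base_seed + 101 * i, asg=asg,
                             offset=off, spectrum=spec)
        est = estimate_gf_from_sim(img, spr_model=cfg.spr_model,
                                   scatter_mode=cfg.scatter_mode,
                                   ref_glandular_fraction=gf)
        interior = img.paths.glandular_interior(cfg.erode_px)
        st = gf_error_stats(est, img.paths.m_true, interior)
        rows.append({"offset_cm": off, "mean_gf": st.mean_estimate,
                     "sd_gf": st.sd_estimate, "n": st.n_pixels})
    return pd.DataFrame(rows)


def default_calcs(T: float) -> Tuple[MicroCalc, ...]:
    """Two 1 mm x 0.5 mm deposits in different spots of the glandular region,
    centered mid-slab."""
    z_mid = 1.5 + 0.5 / 2 + T / 2  # air gap + lower paddle + half stack
    return (
        MicroCalc(x=1.0, y=2.0, z_center=z_mid),
        MicroCalc(x=-2.0, y=3.0, z_center=z_mid),
    )


def run_cnr_study(
    cfg: Optional[GridConfig] = None,
    T: float = 4.0,
    gfs: Sequence[float] = (0.3, 0.5),
    asg: bool = True,
    base_seed: int = 0,
) -> pd.DataFrame:
    """CNR of each inserted microcalcification in the raw count image versus
    the glandular-fraction image, with the percent improvement."""
    cfg = cfg or GridConfig()
    spec = study_spectrum(cfg.spectrum)
    rows = []
    for i, gf in enumerate(gfs):
        calcs = default_calcs(T)
        img = _simulate_cell(T, gf, cfg, base_seed + 313 * i, asg=asg,
                             calcs=calcs, spectrum=spec)
        est = estimate_gf_from_sim(img, spr_model=cfg.spr_model,
                                   scatter_mode=cfg.scatter_mode,
                                   ref_glandular_fraction=gf)
        interior = img.paths.glandular_interior(cfg.erode_px)
        for ci, mc in enumerate(calcs):
            sig, bg = calc_rois(img.paths, mc, cfg.geometry, restrict=interior)
            raw = compute_cnr(img.measured, sig, bg)
            gfi = compute_cnr(est.m, sig & est.mask, bg & est.mask)
            rows.append({"gf": gf, "calc": ci, "cnr_raw": raw.cnr, "cnr_gf": gfi.cnr,
                         "improvement_pct": cnr_improvement(gfi, raw)})
    return pd.DataFrame(rows)


def run_experiment_grid(cfg: Optional[GridConfig] = None) -> Dict[str, pd.DataFrame]:
    """Full study: loss-error table, both scatter branches over the grid,
    the narrow-spectrum 9 cm comparison, the location study and the CNR study."""
    cfg = cfg or GridConfig()
    out: Dict[str, pd.DataFrame] = {}
    out["loss_error"] = run_loss_error_table(cfg)
    per_asg, pool_asg = run_gf_grid(cfg, asg=True)
    per_ml, pool_ml = run_gf_grid(cfg, asg=False)
    out["grid_asg"] = per_asg
    out["grid_gridless"] = per_ml
    out["pooled"] = pd.DataFrame([
        {"branch": "asg", "rmse_pp": pool_asg.rmse, "mae_pp": pool_asg.mae,
         "bias_pp": pool_asg.bias, "n": pool_asg.n_pixels},
        {"branch": "gridless", "rmse_pp": pool_ml.rmse, "mae_pp": pool_ml.mae,
         "bias_pp": pool_ml.bias, "n": pool_ml.n_pixels},
    ])
    import dataclasses as _dc
    cfg_ag = _dc.replace(cfg, spectrum="W/Ag", thicknesses=(9.0,))
    cfg_al = _dc.replace(cfg, thicknesses=(9.0,))
    per_al, _ = run_gf_grid(cfg_al, asg=True)
    per_ag, _ = run_gf_grid(cfg_ag, asg=True)
    out["extreme_9cm"] = pd.concat(
        [per_al.assign(spectrum="W/Al"), per_ag.assign(spectrum="W/Ag")],
        ignore_index=True,
    )
    out["location"] = run_location_study(cfg)
    out["cnr"] = run_cnr_study(cfg)
    return out
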
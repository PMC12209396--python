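"""Software scatter removal by per-pixel Poisson maximum likelihood.

Given the measured counts Im, the flat field I0, a modeled scatter raster Sc
and the total traversal length t, each pixel's net attenuation coefficient
mu maximizes

    f(mu) = Im ln(Ie) - Ie,      Ie = I0 e^(-mu t) + Sc

via Newton-Raphson on f'(mu).  The scatter-corrected image is
Iq = I0 e^(-mu t).  Pixels with Im <= Sc carry no physical primary signal
and are flagged and excluded; pixels with Im = 0 are censored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._mle import solve_exp_poisson
from .simulate import SprModel, DEFAULT_SPR, spr_value

__all__ = ["ScatterCorrectionResult", "ml_scatter_removal", "scatter_model_for_estimation"]


@dataclass
class ScatterCorrectionResult:
    mu: np.ndarray           # net linear attenuation, 1/cm (NaN off-mask)
    iq: np.ndarray           # scatter-corrected counts I0 e^(-mu t)
    iterations: np.ndarray
    converged: np.ndarray
    mask: np.ndarray         # pixels actually estimated
    n_non_physical: int      # Im - Sc <= 0, dropped from the mask
    n_censored: int          # Im == 0, dropped from the mask


def ml_scatter_removal(
    im: np.ndarray,
    i0: np.ndarray,
    sc: np.ndarray,
    t_total: np.ndarray,
    mask: Optional[np.ndarray] = None,
    tol: float = 1e-10,
    max_iter: int = 50,
    theta0: Optional[np.ndarray] = None,
) -> ScatterCorrectionResult:
    im = np.asarray(im, dtype=float)
    i0, sc, t_total = (np.broadcast_to(np.asarray(v, dtype=float), im.shape)
                       for v in (i0, sc, t_total))
    base = np.ones(im.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if np.any((i0 <= 0) & base) or np.any((t_total <= 0) & base):
        raise ValueError("i0 and t_total must be positive on the mask")
    if np.any((sc < 0) & base):
        raise ValueError("modeled scatter must be >= 0 on the mask")

    censored = base & (im == 0)
    non_physical = base & (im - sc <= 0) & ~censored
    eff = base & ~censored & ~non_physical

    mu = np.full(im.shape, np.nan)
    iters = np.zeros(im.shape, dtype=np.int32)
    conv = np.zeros(im.shape, dtype=bool)
    if eff.any():
        res = solve_exp_poisson(
            im[eff], i0[eff], t_total[eff], sc[eff],
            theta0=None if theta0 is None else np.broadcast_to(theta0, im.shape)[eff],
            tol=tol, max_iter=max_iter,
        )
        mu[eff] = res.theta
        iters[eff] = res.iterations
        conv[eff] = res.converged

    iq = np.where(eff, i0 * np.exp(-np.where(eff, mu, 0.0) * t_total), np.nan)
    return ScatterCorrectionResult(
        mu=mu, iq=iq, iterations=iters, converged=conv, mask=eff,
        n_non_physical=int(non_physical.sum()), n_censored=int(censored.sum()),
    )


def scatter_model_for_estimation(
    i0: np.ndarray,
    im: np.ndarray,
    t_breast: np.ndarray,
    spr_model: SprModel = DEFAULT_SPR,
    grid_transmission: float = 1.0,
    sc_external: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Scatter raster consistent with the measured totals.

    Under the multiplicative model S = SPR x primary, the measured total
    Im = P + S implies S = SPR/(1 + SPR) x Im; SPR comes from the
    thickness-driven table, scaled by ``grid_transmission`` when an
    anti-scatter grid transmitted only that fraction of the scatter.  An
    externally supplied raster ``sc_external`` bypasses the model.
    """
    if sc_external is not None:
        return np.asarray(sc_external, dtype=float)
    spr = grid_transmission * spr_value(np.asarray(t_breast, dtype=float), spr_model)
    return spr / (1.0 + spr) * np.asarray(im, dtype=float)
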
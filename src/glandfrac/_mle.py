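"""Vectorized scalar Newton-Raphson for the shared Poisson likelihood shape.

Both estimation steps maximize, independently per pixel, a log-likelihood of
the form

    f(theta) = N ln(lambda) - lambda,    lambda(theta) = A e^(-b theta) + S

with observed counts N, amplitude A > 0, slope b > 0 and additive offset
S >= 0.  The scatter-removal step has theta = mu, b = t, S = Sc; the
glandular-fraction step has theta = m1, b = (mu_g - mu_a) t, S = 0 (with the
known-material attenuation folded into A).  The stationary point has the
closed form theta* = -ln((N - S)/A)/b, which doubles as the default start;
Newton-Raphson is the general mechanism (and converges in a couple of steps
from that start), with step halving whenever the likelihood would decrease.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NewtonResult", "solve_exp_poisson", "closed_form", "loglik", "dloglik"]


@dataclass
class NewtonResult:
    theta: np.ndarray
    iterations: np.ndarray
    converged: np.ndarray


def closed_form(n, a, b, s, floor: float = 1.0) -> np.ndarray:
    """Analytic stationary point with the net counts floored at ``floor``."""
    net = np.maximum(np.asarray(n, dtype=float) - s, floor)
    return -np.log(net / a) / b


def loglik(theta, n, a, b, s):
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        lam = a * np.exp(-b * theta) + s
        return n * np.log(lam) - lam


def dloglik(theta, n, a, b, s):
    """First and second derivatives of the log-likelihood at ``theta``."""
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        p = a * np.exp(-b * theta)
        lam = p + s
        d1 = (n / lam - 1.0) * (-b * p)
        d2 = b**2 * p * ((n / lam - 1.0) - p * n / lam**2)
    return d1, d2


def solve_exp_poisson(
    n,
    a,
    b,
    s=0.0,
    theta0=None,
    tol: float = 1e-10,
    max_iter: int = 50,
    count_floor: float = 1.0,
) -> NewtonResult:
    """Maximize f per element; any execution order gives identical results."""
    n = np.asarray(n, dtype=float)
    a, b, s = (np.broadcast_to(np.asarray(v, dtype=float), n.shape)
               for v in (a, b, s))
    theta = (closed_form(n, a, b, s, count_floor) if theta0 is None
             else np.array(np.broadcast_to(theta0, n.shape), dtype=float))

    iters = np.zeros(n.shape, dtype=np.int32)
    converged = np.zeros(n.shape, dtype=bool)
    active = np.ones(n.shape, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        d1, d2 = dloglik(theta, n, a, b, s)
        with np.errstate(divide="ignore", invalid="ignore"):
            newton = d1 / d2
        # Newton step only where the log-likelihood is locally concave;
        # elsewhere walk uphill a fixed distance and let the damping shrink it
        step = np.where(np.isfinite(newton) & (d2 < 0.0), newton,
                        -np.sign(d1) * 0.5)
        step = np.clip(step, -2.0, 2.0)   # trust region for far-off starts
        f_old = loglik(theta, n, a, b, s)
        slack = 1e-9 * (1.0 + np.abs(f_old))  # roundoff-scaled acceptance
        proposal = theta - step
        # halve the step while the likelihood would decrease (NaN counts as
        # a decrease, so diverging proposals are pulled back too)
        for _damp in range(40):
            bad = active & ~(loglik(proposal, n, a, b, s) >= f_old - slack)
            if not bad.any():
                break
            step = np.where(bad, step / 2.0, step)
            proposal = theta - step
        theta = np.where(active, proposal, theta)
        iters = iters + active.astype(np.int32)
        # convergence on the *undamped* Newton step in the concave basin, so
        # a step shrunk by damping cannot masquerade as convergence
        done = active & (np.abs(newton) < tol) & np.isfinite(newton) & (d2 < 0.0)
        converged |= done
        active &= ~done

    return NewtonResult(theta=theta, iterations=iters, converged=converged)
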
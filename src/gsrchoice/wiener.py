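"""First-passage utilities for a Wiener process between two boundaries.

These closed forms describe the 1-D special case of the simulator
(``gamma = pi``): a Brownian motion with drift ``delta`` and infinitesimal
SD ``sigma`` between absorbing boundaries at ``-theta`` and ``+theta``,
starting at the relative position ``beta`` (0 = lower boundary, 1 = upper,
0.5 = unbiased).  The first-passage-time density is evaluated with the
standard small-time / large-time series representations, switching to
whichever needs fewer terms for an absolute truncation error of 1e-7.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["wiener_fpt_density", "absorption_probability"]

_ERR = 1e-7


def _n_terms_small(tt: float, err: float) -> int:
    # number of terms for the small-time representation at scaled time tt
    if 2.0 * math.sqrt(2.0 * math.pi * tt) * err < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * err * math.sqrt(2.0 * math.pi * tt)))
        ks = max(ks, math.sqrt(tt) + 1.0)
    else:
        ks = 2.0
    return int(math.ceil(ks))

def _n_terms_large(tt: float, err: float) -> int:
    if math.pi * tt * err < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * err) / (math.pi**2 * tt))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tt)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))
    return int(math.ceil(kl))


def _density_lower(t: np.ndarray, a: float, v: float, w: float) -> np.ndarray:
    """Density of absorption at the lower boundary.

    ``a`` is the boundary separation and ``w`` the relative start, both in
    units of the noise SD (unit-diffusion scaling).
    """
    t = np.asarray(t, dtype=float)
    out = np.empty_like(t)
    tt = t / a**2  # scaled time
    lead = np.exp(-v * a * w - v**2 * t / 2.0)
    for i, (ti, tti) in enumerate(zip(t, tt)):
        ks = _n_terms_small(tti, _ERR)
        kl = _n_terms_large(tti, _ERR)
        if ks < kl:
            k = np.arange(-((ks) // 2), (ks) // 2 + 1)
            terms = (w + 2.0 * k) * np.exp(-((w + 2.0 * k) ** 2) / (2.0 * tti))
            out[i] = terms.sum() / math.sqrt(2.0 * math.pi * tti**3)
        else:
            k = np.arange(1, kl + 1)
            terms = k * np.sin(k * math.pi * w) * np.exp(-(k**2) * math.pi**2 * tti / 2.0)
            out[i] = terms.sum() * math.pi
    # back from scaled time density to real time (divide by a^2)
    return lead * out / a**2


def wiener_fpt_density(t, theta: float, delta: float, beta: float = 0.5, sigma: float = 1.0):
    """First-passage-time densities at the upper and lower boundaries.

    Parameters
    ----------
    t : array-like
        Decision times (seconds), strictly positive.
    theta : float
        Boundary at ``+theta`` / ``-theta``; must be positive.
    delta : float
        Drift rate of the balance of evidence.
    beta : float
        Relative start point in ``(0, 1)``; 0.5 is unbiased.
    sigma : float
        Infinitesimal standard deviation.

    Returns
    -------
    (f_upper, f_lower) : pair of ndarrays
        Defective densities; each integrates to the corresponding
        absorption probability and their sum integrates to one.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t <= 0):
        raise ValueError("t must be positive")
    if theta <= 0 or sigma <= 0:
        raise ValueError("theta and sigma must be positive")
    if not (0.0 < beta < 1.0):
        raise ValueError("beta must lie in (0, 1)")
    a = 2.0 * theta / sigma
    v = delta / sigma
    f_lower = _density_lower(t, a, v, beta)
    f_upper = _density_lower(t, a, -v, 1.0 - beta)
    return f_upper, f_lower


def absorption_probability(theta: float, delta: float, beta: float = 0.5, sigma: float = 1.0) -> float:
    """Probability of absorption at the upper boundary ``+theta``.

    Closed form for a Wiener process with drift between two absorbing
    boundaries; reduces to ``beta`` when the drift is zero.
    """
    if theta <= 0 or sigma <= 0:
        raise ValueError("theta and sigma must be positive")
    if not (0.0 <= beta <= 1.0):
        raise ValueError("beta must lie in [0, 1]")
    a = 2.0 * theta / sigma
    v = delta / sigma
    if abs(v) * a < 1e-12:
        return float(beta)
    # numerically stable form of (1 - exp(-2 v a w)) / (1 - exp(-2 v a))
    num = -math.expm1(-2.0 * v * a * beta)
    den = -math.expm1(-2.0 * v * a)
    return float(num / den)
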
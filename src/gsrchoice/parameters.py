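"""Generative parameters, priors, and the urn-drawing posterior.

One simulated participant is described by a :class:`ParameterSet`: a drift
direction ``phi`` and magnitude ``mu_mag`` (mean of the bivariate-normal
evidence increments), a projection threshold ``theta``, non-decision time
``tau``, across-trial drift variability ``nu``, the inter-option angle
``gamma``, the diffusion (noise) rate ``sigma``, and start-point parameters
``s_v`` (half-width) and ``beta`` (bias on the balance axis).

:class:`PriorSpec` holds the prior distributions from which simulated
participants are drawn.  Gamma distributions are in shape-scale form
throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np

from .geometry import GAMMA_ACCUMULATOR, GAMMA_DIFFUSION

__all__ = [
    "ParameterSet",
    "PriorSpec",
    "sample_parameters",
    "sample_parameter_arrays",
    "urn_posterior",
    "MODEL_CLASSES",
]

MODEL_CLASSES = ("diffusion", "accumulator", "gsr")

#: drift-magnitude rescaling applied to the diffusion class, compensating the
#: shorter projection of the accumulation trajectory onto each option vector
#: when the options are opposed rather than orthogonal.
SQRT2 = math.sqrt(2.0)


@dataclass
class ParameterSet:
    """Generative parameters of one simulated participant.

    ``delta`` is the signed 1-D drift used by the Wiener first-passage
    utilities; it is only meaningful for the pure relative-evidence case
    (``gamma = pi``), where it equals the projection of the drift vector onto
    the balance axis.
    """

    phi: float
    mu_mag: float
    theta: float
    tau: float
    nu: float
    gamma: float
    sigma: float = 1.0
    s_v: float = 0.0
    beta: float = 0.0
    delta: float | None = None

    def __post_init__(self) -> None:
        if self.mu_mag < 0:
            raise ValueError("mu_mag must be non-negative")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.tau < 0 or self.nu < 0 or self.s_v < 0:
            raise ValueError("tau, nu and s_v must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0.0 < self.gamma <= np.pi):
            raise ValueError("gamma must lie in (0, pi]")
        if self.delta is None and abs(self.gamma - np.pi) < 1e-12:
            self.delta = self.mu_mag * math.cos(self.phi)

    def drift_vector(self) -> np.ndarray:
        """Mean drift as a 2-vector in the canonical frame."""
        return self.mu_mag * np.array([math.cos(self.phi), math.sin(self.phi)])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(**d)


# prior families supported in configuration files
_FAMILIES = ("uniform", "gamma")


@dataclass
class PriorSpec:
    """Per-parameter prior distributions (family, hyperparameters).

    Defaults: ``phi ~ U(0, 1)`` (radians), ``mu_mag ~ Gamma(2, 2)``,
    ``theta ~ Gamma(2, 2)``, ``tau ~ Gamma(1, .4)``, ``nu ~ Gamma(1, 1)``
    and, when the option angle is free, ``gamma ~ U(0, pi)``.  Gamma is in
    shape-scale form.
    """

    phi: tuple = ("uniform", 0.0, 1.0)
    mu_mag: tuple = ("gamma", 2.0, 2.0)
    theta: tuple = ("gamma", 2.0, 2.0)
    tau: tuple = ("gamma", 1.0, 0.4)
    nu: tuple = ("gamma", 1.0, 1.0)
    gamma: tuple = ("uniform", 0.0, math.pi)

    PARAM_NAMES = ("phi", "mu_mag", "theta", "tau", "nu", "gamma")

    def __post_init__(self) -> None:
        for name in self.PARAM_NAMES:
            fam, *args = getattr(self, name)
            if fam not in _FAMILIES:
                raise ValueError(f"unknown prior family {fam!r} for {name}")
            if fam == "gamma" and not all(a > 0 for a in args):
                raise ValueError(f"gamma hyperparameters for {name} must be positive")

    def draw(self, name: str, n: int, rng: np.random.Generator) -> np.ndarray:
        fam, *args = getattr(self, name)
        if fam == "uniform":
            lo, hi = args
            return rng.uniform(lo, hi, n)
        shape, scale = args
        return rng.gamma(shape, scale, n)

    def to_dict(self) -> dict:
        return {name: list(getattr(self, name)) for name in self.PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        kwargs = {k: tuple(v) for k, v in d.items() if k in cls.PARAM_NAMES}
        return cls(**kwargs)


def sample_parameter_arrays(
    prior: PriorSpec,
    n: int,
    model_class: str,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Draw ``n`` independent parameter vectors from the priors, as arrays.

    For the diffusion class the drift magnitude is scaled by ``sqrt(2)``
    after the Gamma draw and ``gamma`` is fixed at ``pi``; the accumulator
    class fixes ``gamma = pi/2``; the gsr class draws ``gamma`` from its
    prior (clipped away from 0, where the options coincide).
    """
    if model_class not in MODEL_CLASSES:
        raise ValueError(
            f"model_class must be one of {MODEL_CLASSES}, got {model_class!r}"
        )
    if n < 1:
        raise ValueError("n must be >= 1")
    out = {name: prior.draw(name, n, rng) for name in ("phi", "mu_mag", "theta", "tau", "nu")}
    if model_class == "diffusion":
        out["mu_mag"] = out["mu_mag"] * SQRT2
        out["gamma"] = np.full(n, GAMMA_DIFFUSION)
    elif model_class == "accumulator":
        out["gamma"] = np.full(n, GAMMA_ACCUMULATOR)
    else:
        g = prior.draw("gamma", n, rng)
        # gamma = 0 means indistinguishable options; keep draws inside (0, pi]
        out["gamma"] = np.clip(g, 1e-9, np.pi)
    return out


def sample_parameters(
    prior: PriorSpec,
    n: int,
    model_class: str,
    rng: np.random.Generator,
) -> list[ParameterSet]:
    """Draw ``n`` :class:`ParameterSet` objects from the priors.

    See :func:`sample_parameter_arrays` for the model-class conventions.
    """
    arrs = sample_parameter_arrays(prior, n, model_class, rng)
    return [
        ParameterSet(
            phi=float(arrs["phi"][i]),
            mu_mag=float(arrs["mu_mag"][i]),
            theta=float(arrs["theta"][i]),
            tau=float(arrs["tau"][i]),
            nu=float(arrs["nu"][i]),
            gamma=float(arrs["gamma"][i]),
        )
        for i in range(n)
    ]


def urn_posterior(p_majority: float, n_majority_draws: int, prior_R: float) -> float:
    """Posterior that the majority-colour hypothesis is true.

    A decision-maker draws balls with replacement from one of two urns whose
    majority colour differs; ``p_majority`` is the majority colour's
    proportion in either urn.  After ``n_majority_draws`` consecutive
    majority-colour draws, Bayes' rule gives

    ``Pr(R | D) = p^n q_R / (p^n q_R + (1-p)^n (1-q_R))``

    where ``q_R`` is the prior.  The posterior grows with both the urn
    discriminability ``p_majority`` and the number of draws, which is how
    option discriminability maps onto the strength of the balance of
    evidence in a relative-evidence model.
    """
    if not (0.0 < p_majority < 1.0):
        raise ValueError("p_majority must lie in (0, 1)")
    if not (0.0 < prior_R < 1.0):
        raise ValueError("prior_R must lie in (0, 1)")
    if n_majority_draws < 0:
        raise ValueError("n_majority_draws must be >= 0")
    like_r = p_majority**n_majority_draws
    like_b = (1.0 - p_majority) ** n_majority_draws
    num = like_r * prior_R
    return num / (num + like_b * (1.0 - prior_R))
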
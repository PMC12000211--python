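"""Geometry of option representations.

Two-alternative choice is modelled in a 2-D evidence space in which each
option is a unit direction vector.  The angle ``gamma`` between the two
vectors is the model-identity parameter: ``gamma = pi`` places the options in
direct opposition (a relative-evidence / diffusion representation) while
``gamma = pi/2`` makes them orthogonal (an absolute-evidence / racing
accumulator representation).  Intermediate angles interpolate between the two
model classes.

The global orientation of the frame is unidentifiable, so ``u_A`` is fixed
along the positive x-axis and ``u_B`` is rotated counter-clockwise by
``gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["OptionFrame", "make_option_frame", "project", "frame_angle"]

#: canonical model-class angles
GAMMA_DIFFUSION = np.pi
GAMMA_ACCUMULATOR = np.pi / 2

_UNIT_TOL = 1e-8


@dataclass(frozen=True)
class OptionFrame:
    """Unit direction vectors for options A and B separated by ``gamma``.

    Attributes
    ----------
    gamma : float
        Angle between the option vectors, in radians, in ``(0, pi]``.
    u_A, u_B : ndarray of shape (2,)
        Unit vectors representing the two options.
    """

    gamma: float
    u_A: np.ndarray = field(repr=False)
    u_B: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        for name, u in (("u_A", self.u_A), ("u_B", self.u_B)):
            if abs(np.linalg.norm(u) - 1.0) > 1e-12:
                raise ValueError(f"{name} is not a unit vector")
        if not (0.0 < self.gamma <= np.pi):
            raise ValueError(f"gamma must lie in (0, pi], got {self.gamma}")
        if abs(float(self.u_A @ self.u_B) - np.cos(self.gamma)) > 1e-12:
            raise ValueError("angle between u_A and u_B does not equal gamma")


def make_option_frame(gamma: float) -> OptionFrame:
    """Build the canonical option frame for an inter-option angle ``gamma``.

    ``u_A`` lies along the positive x-axis; ``u_B`` is rotated
    counter-clockwise by ``gamma``.  ``gamma = pi`` yields polar-opposite
    options (relative choice boundary), ``gamma = pi/2`` orthogonal options
    (absolute choice boundary).

    Parameters
    ----------
    gamma : float
        Inter-option angle in radians, in ``(0, pi]``.

    Returns
    -------
    OptionFrame
    """
    gamma = float(gamma)
    if not np.isfinite(gamma) or not (0.0 < gamma <= np.pi):
        raise ValueError(f"gamma must lie in (0, pi], got {gamma}")
    u_a = np.array([1.0, 0.0])
    u_b = np.array([np.cos(gamma), np.sin(gamma)])
    return OptionFrame(gamma=gamma, u_A=u_a, u_B=u_b)


def frame_angle(frame: OptionFrame) -> float:
    """Recover the inter-option angle from the frame's vectors."""
    return float(np.arccos(np.clip(frame.u_A @ frame.u_B, -1.0, 1.0)))


def project(state, direction) -> float:
    """Scalar component of ``state`` along a unit ``direction``.

    The degree of support a piece of evidence provides for an option is the
    projection of the evidence vector onto the option's direction vector.

    Parameters
    ----------
    state : array-like of shape (2,)
        Evidence state or increment.
    direction : array-like of shape (2,)
        Unit vector; a non-unit vector raises ``ValueError``.
    """
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > _UNIT_TOL:
        raise ValueError("direction must be a unit vector")
    return float(np.asarray(state, dtype=float) @ direction)
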
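"""Periodic 2D box geometry.

The simulation domain is a square with periodic boundary conditions, so
that the observed field (a small part of a much larger substrate) is free
of wall artefacts.  All positions are kept wrapped into ``[0, L)`` on each
axis; displacements between points are always measured through the nearest
periodic image.

Angles are handled in degrees throughout (the motion rules of the
agent-based model are stated in degrees).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BoxSpec",
    "DirectionLaw",
    "wrap_position",
    "min_image_vector",
    "pbc_center_of_mass",
    "sample_direction",
]


@dataclass(frozen=True)
class BoxSpec:
    """Square periodic simulation box.

    Parameters
    ----------
    side_length
        Side of the square box in µm.  The default reproduces the field of
        view of the time-lapse experiments (1280 px of 0.658 µm).
    """

    side_length: float = 842.24
    periodic: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.side_length) or self.side_length <= 0:
            raise ValueError(f"side_length must be positive, got {self.side_length}")
        if not self.periodic:
            raise ValueError("only periodic boxes are supported")


@dataclass(frozen=True)
class DirectionLaw:
    """Law for drawing a motion direction.

    ``uniform`` draws from the full circle; ``sector`` draws uniformly in
    ``[center_angle - half_width, center_angle + half_width]`` (degrees,
    mod 360); ``halfplane`` is the sector of half-width 90° used for the
    hydrodynamic-flux bias.
    """

    mode: str = "uniform"
    center_angle: float = 0.0
    half_width: float = 180.0

    def __post_init__(self) -> None:
        if self.mode not in ("uniform", "sector", "halfplane"):
            raise ValueError(f"unknown direction mode {self.mode!r}")
        if self.mode == "halfplane" and self.half_width != 90.0:
            object.__setattr__(self, "half_width", 90.0)
        if self.mode != "uniform" and not (0.0 < self.half_width <= 180.0):
            raise ValueError(f"half_width must be in (0, 180], got {self.half_width}")


def wrap_position(p, box: BoxSpec):
    """Wrap point(s) into ``[0, L)`` per axis.

    Accepts a single 2-vector or an ``(n, 2)`` array; the displacement from
    the input to the output is an integer multiple of the box side on each
    axis.
    """
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite coordinate")
    return np.mod(p, box.side_length)


def min_image_vector(p, q, box: BoxSpec):
    """Shortest displacement ``v`` with ``q = p + v (mod L)``.

    Components lie in ``[-L/2, L/2]``.  Works element-wise on arrays of
    points.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("non-finite coordinate")
    L = box.side_length
    return np.mod(q - p + 0.5 * L, L) - 0.5 * L


def min_image_distance(p, q, box: BoxSpec):
    """Periodic distance between points (norm of the minimal-image vector)."""
    v = min_image_vector(p, q, box)
    return np.linalg.norm(v, axis=-1)


def pbc_center_of_mass(points, box: BoxSpec):
    """Center of mass of a point set under periodic boundaries.

    Uses the per-axis circular mean: each coordinate is mapped to an angle
    on a circle of circumference L, the unit vectors are averaged and the
    mean angle mapped back.  For clusters of extent < L/2 (always the case
    for aggregates in this model) this equals the minimal-image arithmetic
    mean relative to any member.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("cannot compute center of mass of an empty point set")
    L = box.side_length
    theta = pts * (2.0 * np.pi / L)
    mean_angle = np.arctan2(np.sin(theta).mean(axis=0), np.cos(theta).mean(axis=0))
    return np.mod(mean_angle * (L / (2.0 * np.pi)), L)


def sample_direction(law: DirectionLaw, rng: np.random.Generator, size=None):
    """Draw motion direction(s) in degrees according to ``law``.

    Returns angles in ``[0, 360)``; a scalar when ``size`` is None.
    """
    if law.mode == "uniform":
        u = rng.uniform(0.0, 360.0, size=size)
        return u
    # sector and halfplane: uniform in [center - hw, center + hw] mod 360
    hw = law.half_width
    u = rng.uniform(-hw, hw, size=size)
    return np.mod(law.center_angle + u, 360.0)
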
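"""3D simulation geometries and particle snapshots.

Supported containers: a (periodic or reflective) box with its origin at a
corner, and a reflective sphere centered at the origin, optionally holding a
coaxial production cylinder ("DNA") along z.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["Box", "Sphere", "Cylinder", "Geometry", "ParticleSnapshot",
           "minimum_image"]


@dataclass(frozen=True)
class Cylinder:
    """Axis-aligned (z) cylinder centered at the origin."""

    radius: float
    half_length: float

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.half_length <= 0:
            raise ValueError("cylinder dimensions must be positive")

    @property
    def volume(self) -> float:
        return float(np.pi * self.radius ** 2 * 2.0 * self.half_length)


@dataclass(frozen=True)
class Box:
    Lx: float
    Ly: float
    Lz: float
    periodic: bool = True

    def __post_init__(self) -> None:
        if min(self.Lx, self.Ly, self.Lz) <= 0:
            raise ValueError("box dimensions must be positive")

    @classmethod
    def cube(cls, volume: float, periodic: bool = True) -> "Box":
        L = volume ** (1.0 / 3.0)
        return cls(L, L, L, periodic=periodic)

    @property
    def volume(self) -> float:
        return self.Lx * self.Ly * self.Lz

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.Lx, self.Ly, self.Lz])

    def contains(self, pos: np.ndarray) -> np.ndarray:
        pos = np.atleast_2d(pos)
        return np.all((pos >= 0) & (pos <= self.lengths), axis=1)

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(0.0, 1.0, size=(n, 3)) * self.lengths


@dataclass(frozen=True)
class Sphere:
    radius: float
    cylinder: Optional[Cylinder] = None  # production region, fully inside

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        c = self.cylinder
        if c is not None:
            reach = np.hypot(c.radius, c.half_length)
            if reach > self.radius:
                raise ValueError("cylinder extends outside the sphere "
                                 f"(reach {reach:.3g} > radius {self.radius:.3g})")

    @classmethod
    def from_volume(cls, volume: float,
                    cylinder: Optional[Cylinder] = None) -> "Sphere":
        return cls(radius=(3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0),
                   cylinder=cylinder)

    @property
    def volume(self) -> float:
        return float(4.0 / 3.0 * np.pi * self.radius ** 3)

    def contains(self, pos: np.ndarray) -> np.ndarray:
        pos = np.atleast_2d(pos)
        return np.einsum("ij,ij->i", pos, pos) <= self.radius ** 2

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty((n, 3))
        filled = 0
        while filled < n:
            cand = rng.uniform(-self.radius, self.radius, size=(2 * (n - filled) + 8, 3))
            ok = cand[np.einsum("ij,ij->i", cand, cand) <= self.radius ** 2]
            take = min(len(ok), n - filled)
            out[filled:filled + take] = ok[:take]
            filled += take
        return out


Geometry = Box | Sphere


def minimum_image(delta: np.ndarray, geometry: Geometry) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    delta = np.asarray(delta, dtype=float)
    if isinstance(geometry, Box) and geometry.periodic:
        L = geometry.lengths
        return delta - L * np.rint(delta / L)
    return delta


@dataclass
class ParticleSnapshot:
    """Positions of all particles per species at one instant."""

    time: float
    x_positions: np.ndarray   # (n_X, 3) monomers
    x2_positions: np.ndarray  # (n_X2, 3) dimers
    geometry: Geometry

    def __post_init__(self) -> None:
        self.x_positions = np.asarray(self.x_positions, dtype=float).reshape(-1, 3)
        self.x2_positions = np.asarray(self.x2_positions, dtype=float).reshape(-1, 3)

    @property
    def n_X(self) -> int:
        return len(self.x_positions)

    @property
    def n_X2(self) -> int:
        return len(self.x2_positions)
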
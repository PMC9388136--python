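"""Thin-box geometry: periodic X/Y, reflective Z.

The simulation domain is a quasi-two-dimensional slab: the X and Y
directions wrap periodically (minimum-image convention) while Z is
bounded by mirrors at 0 and ``size_z``.  All lengths are in micrometers.
Coordinates themselves are never wrapped by the dynamics -- filament
vertices live in unbounded X/Y so trajectories stay continuous
("unwrapped") -- and periodicity enters only through pairwise
displacements computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SimulationBox", "minimum_image", "reflect_z"]


@dataclass(frozen=True)
class SimulationBox:
    """A thin 3D box, periodic in X and Y, mirror-bounded in Z.

    For the scenarios of interest ``size_z`` (0.2 µm) is much smaller
    than the lateral extent; that is a modelling convention, not an
    enforced invariant.
    """

    size_x: float
    size_y: float
    size_z: float

    def __post_init__(self) -> None:
        if not (self.size_x > 0 and self.size_y > 0 and self.size_z > 0):
            raise ValueError("box dimensions must be strictly positive")

    @property
    def area_xy(self) -> float:
        return self.size_x * self.size_y


def minimum_image(dx: np.ndarray, box: SimulationBox) -> np.ndarray:
    """Wrap a displacement vector to its shortest periodic image.

    X and Y components are mapped to the half-open interval
    ``[-L/2, L/2)`` (the half-open convention resolves the exact-half
    tie deterministically); the Z component is returned unchanged.
    Accepts a single vector or an array of vectors (last axis length 3).
    """
    dx = np.asarray(dx, dtype=float)
    if not np.all(np.isfinite(dx)):
        raise ValueError("non-finite displacement: corrupted state")
    out = dx.copy()
    for axis, period in ((0, box.size_x), (1, box.size_y)):
        c = out[..., axis]
        out[..., axis] = c - period * np.floor(c / period + 0.5)
    return out


def reflect_z(z: float | np.ndarray, box: SimulationBox) -> float | np.ndarray:
    """Mirror-reflect a Z coordinate into ``[0, size_z]``.

    The mirror rule ``z < 0 -> -z``, ``z > H -> 2H - z`` is applied
    repeatedly (an unconstrained Brownian update can overshoot by more
    than one box height).  Positions only: overdamped dynamics carries
    no velocity state to flip.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite z coordinate")
    h = box.size_z
    # One fold of the 2H-periodic triangular wave resolves any input.
    z = np.mod(z, 2.0 * h)
    z = np.where(z > h, 2.0 * h - z, z)
    if z.ndim == 0:
        return float(z)
    return z
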
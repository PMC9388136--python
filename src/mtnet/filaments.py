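"""Polar, bendable, growing microtubules.

Microtubules are discretized polar lines: vertex 0 is the minus end,
the last vertex the plus end.  Only the plus end grows, at a speed that
decreases linearly as the shared tubulin pool is consumed,

    vg(t) = alpha * (1 - sum_i L_i(t) / Omega),

where ``Omega`` (µm of polymer) is the finite pool and ``alpha`` a
per-filament maximum speed drawn as ``alpha0 * |1 + 0.25 N(0,1)|``
(clipped to 0--2 µm/s) to emulate the broad length distributions of
drug-nucleated microtubules.  There is no catastrophe: lengths are
non-decreasing, and once the growth phase ends they are fixed.

Cross-linker units bind to a discrete lattice of 8-nm sites along the
filament.  Bending elasticity uses the standard linear worm-like-chain
discretization on (near-)uniform segments of rest length ``l``:

    E = (kappa / 2 l^3) * sum_i |r_{i+1} - 2 r_i + r_{i-1}|^2

whose gradient is linear in the vertex positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LATTICE_UM",
    "GrowthModel",
    "TubulinPool",
    "Filament",
    "growth_speed",
    "draw_max_speed",
    "nucleate_from_seeds",
    "grow_plus_end",
    "site_of_abscissa",
    "abscissa_of_site",
    "bending_forces",
    "bending_energy",
    "bending_matrix",
]

#: Spacing of cross-linker binding sites along a microtubule (µm).
LATTICE_UM = 0.008


@dataclass
class GrowthModel:
    """Parameters of the pool-limited growth law."""

    alpha0: float = 0.05  # reference maximum growth speed, µm/s
    omega: float = 100.0  # tubulin pool, µm of polymer
    speed_sd_factor: float = 0.25
    speed_clip: tuple[float, float] = (0.0, 2.0)

    def __post_init__(self) -> None:
        if self.omega <= 0 or self.alpha0 <= 0:
            raise ValueError("omega and alpha0 must be positive")
        if self.speed_clip[0] < 0:
            raise ValueError("speed_clip lower bound must be >= 0")


@dataclass
class TubulinPool:
    """Finite polymerizable material shared by all filaments (µm)."""

    omega: float
    polymerized: float = 0.0

    def withdraw(self, amount: float) -> float:
        """Take up to ``amount`` µm of polymer from the pool."""
        take = min(amount, self.omega - self.polymerized)
        if take < 0:
            raise ValueError("tubulin pool overdrawn: conservation violated")
        self.polymerized += take
        return take


@dataclass
class Filament:
    """A discretized microtubule.  Vertex 0 is the minus end."""

    id: int
    vertices: np.ndarray  # (nv, 3), µm; unwrapped coordinates
    rest_segment_length: float = 0.5
    alpha: float = 0.05
    rigidity: float = 20.0  # flexural rigidity kappa, pN µm^2
    growing: bool = True
    #: target length of the terminal (plus-end) segment; all earlier
    #: segments have rest_segment_length.  Maintained by growth.
    last_rest: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 2 or self.vertices.shape[1] != 3:
            raise ValueError("a filament needs >= 2 three-dimensional vertices")
        if self.last_rest == 0.0:
            self.last_rest = float(np.linalg.norm(self.vertices[-1] - self.vertices[-2]))

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def length(self) -> float:
        """Contour length implied by the segment rest lengths."""
        return (self.n_vertices - 2) * self.rest_segment_length + self.last_rest

    @property
    def minus_end(self) -> np.ndarray:
        return self.vertices[0]

    @property
    def plus_end(self) -> np.ndarray:
        return self.vertices[-1]

    def point_at_abscissa(self, a: float) -> np.ndarray:
        """Position at arc length ``a`` from the minus end."""
        k, t = self.segment_fraction(a)
        return (1.0 - t) * self.vertices[k] + t * self.vertices[k + 1]

    def segment_fraction(self, a: float) -> tuple[int, float]:
        """Map an abscissa to (segment index, fractional position)."""
        if not 0.0 <= a <= self.length + 1e-9:
            raise ValueError(f"abscissa {a} outside filament of length {self.length}")
        l = self.rest_segment_length
        body = (self.n_vertices - 2) * l
        if a >= body:
            t = (a - body) / self.last_rest if self.last_rest > 0 else 0.0
            return self.n_vertices - 2, min(t, 1.0)
        k = int(a // l)
        return k, a / l - k


def growth_speed(alpha: float, polymerized: float, omega: float) -> float:
    """Pool-limited plus-end growth speed ``alpha (1 - polymerized/omega)``."""
    if polymerized > omega * (1 + 1e-12):
        raise ValueError("polymerized length exceeds the tubulin pool")
    if polymerized < 0:
        raise ValueError("negative polymerized length")
    return alpha * (1.0 - min(polymerized, omega) / omega)


def draw_max_speed(alpha0: float, rng: np.random.Generator,
                   sd_factor: float = 0.25,
                   clip: tuple[float, float] = (0.0, 2.0)) -> float:
    """Draw a per-filament maximum growth speed ``alpha0 |1 + 0.25 Z|``.

    ``Z`` is standard normal; the result is hard-clipped to ``clip``
    (the admissible 0--2 µm/s window).
    """
    if alpha0 <= 0:
        raise ValueError("alpha0 must be positive")
    z = rng.standard_normal()
    return float(np.clip(alpha0 * abs(1.0 + sd_factor * z), *clip))


def nucleate_from_seeds(seeds: np.ndarray, used: np.ndarray, rate: float,
                        dt: float, rng: np.random.Generator,
                        pool: TubulinPool, growth: GrowthModel,
                        initial_length: float = 0.1,
                        rest_segment_length: float = 0.5,
                        rigidity: float = 20.0,
                        next_id: int = 0) -> list[Filament]:
    """Fire unused nucleation seeds, each with probability ``1-exp(-rate dt)``.

    Each seed nucleates at most one filament: a minimal two-vertex
    filament centered at the seed with a uniformly random in-plane
    orientation.  The seed material is withdrawn from the pool.
    ``used`` is a boolean array updated in place.
    """
    p = -np.expm1(-rate * dt)
    new: list[Filament] = []
    for i in range(len(seeds)):
        if used[i]:
            continue
        if rng.random() < p:
            theta = rng.uniform(0.0, 2.0 * np.pi)
            d = np.array([np.cos(theta), np.sin(theta), 0.0])
            l0 = pool.withdraw(initial_length)
            if l0 <= 0.0:
                continue  # pool exhausted; seed stays dormant
            used[i] = True
            v = np.stack([seeds[i] - 0.5 * l0 * d, seeds[i] + 0.5 * l0 * d])
            alpha = draw_max_speed(growth.alpha0, rng, growth.speed_sd_factor,
                                   growth.speed_clip)
            new.append(Filament(id=next_id + len(new), vertices=v,
                                rest_segment_length=rest_segment_length,
                                alpha=alpha, rigidity=rigidity,
                                growing=True, last_rest=l0))
    return new


def grow_plus_end(filament: Filament, vg: float, dt: float,
                  pool: TubulinPool) -> None:
    """Extend the plus end by ``min(vg dt, remaining pool)``.

    The terminal segment is elongated along its current direction and
    split once it exceeds 1.5x the rest segment length, keeping the
    discretization near-uniform without global re-meshing.
    """
    if vg < 0:
        raise ValueError("growth speed must be non-negative")
    if not filament.growing or vg == 0.0:
        return
    dl = pool.withdraw(vg * dt)
    if dl <= 0.0:
        return
    v = filament.vertices
    d = v[-1] - v[-2]
    n = np.linalg.norm(d)
    d = d / n if n > 0 else np.array([1.0, 0.0, 0.0])
    v[-1] = v[-1] + dl * d
    filament.last_rest += dl
    if filament.last_rest > 1.5 * filament.rest_segment_length:
        l = filament.rest_segment_length
        split = v[-2] + l * d
        filament.vertices = np.vstack([v[:-1], split, v[-1]])
        filament.last_rest -= l


def site_of_abscissa(a: float, length: float) -> int:
    """Index of the 8-nm lattice site containing arc length ``a``."""
    if not 0.0 <= a <= length + 1e-12:
        raise ValueError(f"abscissa {a} outside filament of length {length}")
    return int(a / LATTICE_UM)


def abscissa_of_site(site: int, length: float) -> float:
    """Center abscissa of a lattice site, clamped to the filament."""
    return float(np.clip((site + 0.5) * LATTICE_UM, 0.0, length))


def bending_matrix(nv: int) -> np.ndarray:
    """Second-difference operator ``A`` ((nv-2) x nv) used by the
    discrete bending energy; ``D = A^T A`` is its (pentadiagonal) Gram
    matrix."""
    a = np.zeros((max(nv - 2, 0), nv))
    for i in range(nv - 2):
        a[i, i:i + 3] = (1.0, -2.0, 1.0)
    return a


def bending_energy(filament: Filament) -> float:
    """Discrete worm-like-chain bending energy (pN µm)."""
    nv = filament.n_vertices
    if nv < 3:
        return 0.0
    l = filament.rest_segment_length
    sec = filament.vertices[2:] - 2.0 * filament.vertices[1:-1] + filament.vertices[:-2]
    return 0.5 * filament.rigidity / l ** 3 * float(np.sum(sec * sec))


def bending_forces(filament: Filament) -> np.ndarray:
    """Per-vertex bending forces, the negative gradient of
    :func:`bending_energy`.  Internal forces: they sum to zero and
    carry zero net torque."""
    nv = filament.n_vertices
    f = np.zeros((nv, 3))
    if nv < 3:
        return f
    l = filament.rest_segment_length
    sec = filament.vertices[2:] - 2.0 * filament.vertices[1:-1] + filament.vertices[:-2]
    k = filament.rigidity / l ** 3
    # distribute -k * A^T (A x)
    f[2:] -= k * sec
    f[1:-1] += 2.0 * k * sec
    f[:-2] -= k * sec
    return f
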
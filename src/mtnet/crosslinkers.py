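"""Cross-linker complexes: unit kinetics, link mechanics, variant catalog.

A cross-linker is two microtubule-binding *units* joined by a Hookean
spring of stiffness ``k`` and nonzero rest length ``e``; the force on
the units at extension ``u`` is ``f = k (1 - e/|u|) u`` and the joints
rotate freely.  A unit is either a *motor* (stochastic 8-nm stepping
toward its directional end, linear force--velocity ``v = vm (1 + f.d/fs)``
clipped to ``[0, 2 vm]``) or *diffusive* (force-biased hopping with
rates ``r± = (D/a^2) exp(±f a / 2 kBT)``, which satisfies detailed
balance ``r+/r- = exp(f a / kBT)``).  Unbinding is force-dependent via
the Bell law ``k_off0 exp(|f|/f_unb)``.  At a filament end a unit either
holds (stepping past the end suppressed) or releases instantly.

The catalog reconstructs kinesin-5 (KIF11: two processive plus-end
motors, end release), kinesin-14 (HSET: one nonprocessive minus-end
motor averaging two steps per engagement plus one diffusive tail whose
zero-force dwell is 500x the motor's, both holding at ends) and the
hypothetical variants used in mixed-motor experiments.  Parameters not
fixed by those printed constraints are documented reconstructions and
every default is overridable through the scenario configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .filaments import LATTICE_UM
from .geometry import SimulationBox, minimum_image

__all__ = [
    "UnitSpec",
    "LinkerSpec",
    "LinkerState",
    "linker_catalog",
    "CATALOG_NAMES",
    "unbinding_rate",
    "motor_velocity",
    "diffusive_hop_rates",
    "link_force",
    "apply_end_policy",
    "binding_attempt",
    "advance_motor",
    "simulate_unit_episode",
]


@dataclass(frozen=True)
class UnitSpec:
    """One microtubule-binding unit of a cross-linker complex."""

    kind: str  # "motor" | "diffusive"
    direction: int = 0  # +1 toward plus end, -1 toward minus end (motors)
    vm: float = 0.0  # unloaded speed, µm/s (motors)
    fs: float = 5.0  # stall force, pN (motors)
    D: float = 0.0  # lattice diffusion coefficient, µm^2/s (diffusive)
    k_on: float = 10.0  # binding rate within range, 1/s
    binding_range: float = 0.06  # capture distance, µm
    k_off0: float = 0.1  # zero-force unbinding rate, 1/s
    f_unb: float = 3.0  # characteristic unbinding force, pN
    end_policy: str = "release"  # "release" | "hold"

    def __post_init__(self) -> None:
        if self.kind not in ("motor", "diffusive"):
            raise ValueError(f"unknown unit kind {self.kind!r}")
        if self.kind == "motor" and (self.vm < 0 or self.fs <= 0):
            raise ValueError("motors need vm >= 0 and fs > 0")
        if self.kind == "diffusive" and self.D < 0:
            raise ValueError("diffusive unit needs D >= 0")
        if self.k_on < 0 or self.k_off0 < 0 or self.binding_range <= 0:
            raise ValueError("invalid kinetic parameters")
        if self.end_policy not in ("release", "hold"):
            raise ValueError(f"unknown end policy {self.end_policy!r}")


@dataclass(frozen=True)
class LinkerSpec:
    """A parameterized cross-linker complex: two units and a spring."""

    name: str
    unit_a: UnitSpec
    unit_b: UnitSpec
    k_spring: float = 50.0  # pN/µm
    rest_length: float = 0.05  # µm
    drag_free: float = 0.015  # pN s/µm, drag of the unbound complex

    def __post_init__(self) -> None:
        if self.k_spring <= 0 or self.rest_length < 0:
            raise ValueError("need k_spring > 0 and rest_length >= 0")

    @property
    def units(self) -> tuple[UnitSpec, UnitSpec]:
        return (self.unit_a, self.unit_b)


@dataclass
class LinkerState:
    """Binding state of one complex: per-unit anchors or a free position.

    ``anchors[j]`` is ``None`` (unbound) or ``(filament_id, abscissa)``.
    The two anchors may never reference the same filament.
    """

    spec: LinkerSpec
    position: np.ndarray
    anchors: list[tuple[int, float] | None]

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.check()

    def check(self) -> None:
        a, b = self.anchors
        if a is not None and b is not None and a[0] == b[0]:
            raise ValueError("both units anchored to the same filament")


# ---------------------------------------------------------------------------
# catalog

_KIF11_MOTOR = UnitSpec(kind="motor", direction=+1, vm=0.03, fs=5.0,
                        k_on=10.0, binding_range=0.06, k_off0=0.1,
                        f_unb=3.0, end_policy="release")

# Nonprocessive minus-end motor: step rate vm/a = 0.08/0.008 = 10/s and
# k_off0 = 5/s give on average two steps per engagement (dwell 0.2 s).
_HSET_MOTOR = UnitSpec(kind="motor", direction=-1, vm=0.08, fs=5.0,
                       k_on=10.0, binding_range=0.06, k_off0=5.0,
                       f_unb=3.0, end_policy="hold")

# Diffusive tail: dwell 500x the motor unit's -> k_off0 = 0.01/s.
_HSET_TAIL = UnitSpec(kind="diffusive", D=0.02, k_on=10.0,
                      binding_range=0.06, k_off0=0.01, f_unb=10.0,
                      end_policy="hold")

# "Mildly processive" symmetric minus motor: mean ten steps per engagement.
_SYM_MINUS_MOTOR = replace(_HSET_MOTOR, k_off0=1.0)

_CATALOG: dict[str, LinkerSpec] = {
    "kif11": LinkerSpec("kif11", _KIF11_MOTOR, _KIF11_MOTOR),
    "hset": LinkerSpec("hset", _HSET_MOTOR, _HSET_TAIL),
    "hset_plus": LinkerSpec("hset_plus", replace(_HSET_MOTOR, direction=+1),
                            _HSET_TAIL),
    "hset_stiff_tail": LinkerSpec("hset_stiff_tail", _HSET_MOTOR,
                                  replace(_HSET_TAIL, D=0.0)),
    "double_motor_hset": LinkerSpec("double_motor_hset", _HSET_MOTOR,
                                    _HSET_MOTOR),
    "double_tail_hset": LinkerSpec("double_tail_hset", _HSET_TAIL,
                                   _HSET_TAIL),
    "double_tail_end_release": LinkerSpec(
        "double_tail_end_release",
        replace(_HSET_TAIL, end_policy="release"),
        replace(_HSET_TAIL, end_policy="release")),
    "symmetric_minus": LinkerSpec("symmetric_minus", _SYM_MINUS_MOTOR,
                                  _SYM_MINUS_MOTOR),
}

CATALOG_NAMES = tuple(_CATALOG)


def linker_catalog(name: str) -> LinkerSpec:
    """Return the fully parameterized spec for a catalog entry."""
    try:
        return _CATALOG[name]
    except KeyError:
        raise KeyError(
            f"unknown cross-linker {name!r}; catalog: {', '.join(CATALOG_NAMES)}"
        ) from None


# ---------------------------------------------------------------------------
# unit-level kinetics

def unbinding_rate(k_off0: float, f_unb: float, f: float) -> float:
    """Bell-law force-dependent unbinding rate ``k_off0 exp(f/f_unb)``."""
    if f < 0:
        raise ValueError("load magnitude must be >= 0")
    return k_off0 * np.exp(min(f / f_unb, 40.0))


def motor_velocity(vm: float, fs: float, f_par: float) -> float:
    """Linear force--velocity law ``vm (1 + f_par/fs)`` clipped to [0, 2 vm].

    ``f_par`` is the projection of the spring force on the unit's motion
    direction: antagonistic load (``f_par < 0``) slows the motor, with
    stall at ``f_par = -fs``; assisting load at most doubles the speed.
    """
    if fs <= 0:
        raise ValueError("stall force must be positive")
    return float(np.clip(vm * (1.0 + f_par / fs), 0.0, 2.0 * vm))


def diffusive_hop_rates(D: float, f_par: float, kBT: float,
                        a: float = LATTICE_UM) -> tuple[float, float]:
    """Force-biased hopping rates ``(r_plus, r_minus)``.

    Symmetric exponent splitting ``r± = (D/a^2) exp(±f a / 2 kBT)``;
    any splitting satisfying detailed balance
    ``r+/r- = exp(f a / kBT)`` differs only at O((fa/kBT)^2).
    """
    if D < 0:
        raise ValueError("D must be >= 0")
    r0 = D / a ** 2
    x = np.clip(f_par * a / (2.0 * kBT), -40.0, 40.0)
    return float(r0 * np.exp(x)), float(r0 * np.exp(-x))


def link_force(pos_a: np.ndarray, pos_b: np.ndarray, k: float, e: float,
               box: SimulationBox | None = None) -> np.ndarray:
    """Hookean force on unit ``a``: ``k (1 - e/|u|) u`` with
    ``u = pos_b - pos_a`` (minimum image if a box is given).

    Attractive beyond the rest length ``e``, repulsive inside it; the
    force on ``b`` is the exact negation.  The degenerate coincident
    case ``|u| = 0`` with ``e > 0`` returns zero force (measure-zero
    configuration with no defined direction).
    """
    u = np.asarray(pos_b, dtype=float) - np.asarray(pos_a, dtype=float)
    if box is not None:
        u = minimum_image(u, box)
    d = float(np.linalg.norm(u))
    if d < 1e-12:
        return np.zeros(3)
    return k * (1.0 - e / d) * u


def apply_end_policy(unit: UnitSpec, at_minus_end: bool,
                     at_plus_end: bool) -> str:
    """Decide ``"keep"`` or ``"release"`` for a unit sitting at an end.

    Hold units always keep (they dwell at ends, enabling end
    clustering); release motors detach at the end they walk toward
    (e.g. KIF11 at plus ends), and release diffusive units detach at
    either end.
    """
    if not (at_minus_end or at_plus_end):
        return "keep"
    if unit.end_policy == "hold":
        return "keep"
    if unit.kind == "diffusive":
        return "release"
    at_target = at_plus_end if unit.direction > 0 else at_minus_end
    return "release" if at_target else "keep"


def binding_attempt(state: LinkerState, unit_index: int,
                    candidates: list[tuple[int, float]], dt: float,
                    rng: np.random.Generator) -> bool:
    """Attempt to bind one unbound unit of a complex.

    Binds with probability ``1 - exp(-k_on dt)`` to a uniformly chosen
    candidate ``(filament_id, abscissa)`` site, excluding any filament
    already engaged by the partner unit.  Returns True on binding.
    """
    if state.anchors[unit_index] is not None:
        raise ValueError("unit already bound")
    unit = state.spec.units[unit_index]
    partner = state.anchors[1 - unit_index]
    allowed = [c for c in candidates if partner is None or c[0] != partner[0]]
    if not allowed:
        return False
    if rng.random() < -np.expm1(-unit.k_on * dt):
        state.anchors[unit_index] = allowed[rng.integers(len(allowed))]
        state.check()
        return True
    return False


def advance_motor(abscissa: float, length: float, unit: UnitSpec, v: float,
                  dt: float, rng: np.random.Generator) -> tuple[float, bool]:
    """Stochastic 8-nm stepping of a bound motor over one time step.

    Steps toward the unit's directional end as a Poisson process of
    rate ``v / a`` (expected displacement ``v dt``).  The position is
    clamped at the filament end; the caller then applies the end
    policy.  Returns ``(new_abscissa, clamped_at_directional_end)``.
    """
    if v < 0:
        raise ValueError("motor speed must be >= 0")
    n = rng.poisson(v * dt / LATTICE_UM) if v > 0 else 0
    a = abscissa + unit.direction * n * LATTICE_UM
    clamped = a < 0.0 or a > length
    return float(np.clip(a, 0.0, length)), bool(clamped)


def simulate_unit_episode(unit: UnitSpec, rng: np.random.Generator,
                          kBT: float = 4.23e-3,
                          f_par: float = 0.0) -> tuple[float, int]:
    """Kinetic Monte Carlo of one bind-to-unbind episode of a single
    unit on an unbounded lattice (no partner, no ends).

    The competition between translocation events (motor stepping at
    ``v/a``, or diffusive hops at ``r+ + r-``) and unbinding at the
    Bell rate is a pair of independent Poisson processes, so the
    episode is sampled exactly: the dwell is exponential with the
    unbinding rate and, conditioned on it, the number of translocation
    events is Poisson (equivalently, event-by-event Gillespie with the
    hop events marginalized).  Returns
    ``(dwell_time_s, n_translocation_events)``.
    """
    k_off = unbinding_rate(unit.k_off0, unit.f_unb, abs(f_par))
    if unit.kind == "motor":
        r_move = motor_velocity(unit.vm, unit.fs, f_par) / LATTICE_UM
    else:
        rp, rm = diffusive_hop_rates(unit.D, f_par, kBT)
        r_move = rp + rm
    if k_off <= 0.0:
        return np.inf, 0
    t = rng.exponential(1.0 / k_off)
    steps = int(rng.poisson(r_move * t)) if r_move > 0.0 else 0
    return t, steps
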
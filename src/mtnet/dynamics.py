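"""Force assembly and overdamped Langevin integration.

Each vertex of drag ``gamma`` moves per step by

    dx = F dt / gamma + sqrt(2 kBT dt / gamma) xi,

with ``F`` the sum of bending, cross-link spring and soft-core steric
forces, followed by re-imposition of the segment-length constraints,
mirror reflection in Z, the cross-linker kinetic update (unbinding,
stepping/hopping, binding) driven by the pre-update spring loads, and
finally nucleation and pool-limited growth.  Bending is integrated
implicitly (see :mod:`mtnet._kernels`); everything else is explicit
first order.

Drag is isotropic per vertex, ``gamma = 3 pi eta l / ln(l / 2 r)``
(slender-body scaling with microtubule radius ``r`` = 12.5 nm).  The
medium viscosity default (0.5 pN s/µm², ~500x water) represents a
crowded assay buffer and, together with the default spring stiffnesses,
keeps the explicit pair-force update stable at the production time
step of 0.005 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .crosslinkers import LinkerSpec
from .filaments import Filament, GrowthModel, TubulinPool, bending_energy
from .geometry import SimulationBox, minimum_image

__all__ = [
    "PhysicsParams",
    "SystemState",
    "assemble_forces",
    "steric_forces",
    "potential_energy",
    "langevin_step",
    "enforce_segment_lengths",
    "run_until",
    "check_conservation",
]


@dataclass
class PhysicsParams:
    """Thermal, viscous and steric parameters."""

    dt: float = 0.005  # s
    kBT: float = 4.23e-3  # pN µm (306 K)
    eta: float = 0.5  # pN s/µm²
    k_steric: float = 50.0  # pN/µm
    d_steric: float = 0.05  # µm, repulsion onset distance
    r_mt: float = 0.0125  # µm, microtubule radius (drag logarithm)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.kBT < 0 or self.d_steric <= 0:
            raise ValueError("invalid physics parameters")

    def gamma_vertex(self, seg_rest: float) -> float:
        """Translational drag per vertex (pN s/µm)."""
        return 3.0 * math.pi * self.eta * seg_rest / math.log(
            seg_rest / (2.0 * self.r_mt))


class SystemState:
    """Complete simulation state advanced by the Langevin integrator.

    Filaments, cross-linkers and the tubulin pool live in flat numpy
    arrays shared with the compiled kernels.  Construction places
    nucleation seeds (z at mid-plane, uniform X/Y, random in-plane
    orientation on firing) and unbound cross-linker complexes uniformly
    in the box; all randomness derives from ``seed``.
    """

    def __init__(self, box: SimulationBox,
                 params: PhysicsParams | None = None,
                 linker_specs: list[LinkerSpec] = (),
                 linker_counts: list[int] = (),
                 n_seeds: int = 0,
                 growth: GrowthModel | None = None,
                 nucleation_rate: float = 0.1,
                 growth_duration: float = 600.0,
                 initial_length: float = 0.1,
                 seg_rest: float = 0.5,
                 kappa: float = 20.0,
                 seed: int = 0,
                 capacity: int | None = None,
                 max_vertices: int = 24) -> None:
        self.box = box
        self.params = params or PhysicsParams()
        self.growth = growth or GrowthModel()
        self.nucleation_rate = float(nucleation_rate)
        self.growth_duration = float(growth_duration)
        self.initial_length = float(initial_length)
        self.seg_rest = float(seg_rest)
        self.kappa = float(kappa)
        self.seed = int(seed)
        self.maxv = int(max_vertices)
        if len(linker_specs) != len(linker_counts):
            raise ValueError("one count per linker spec required")

        rng = np.random.default_rng(seed)
        cap = int(capacity) if capacity is not None else max(n_seeds, 8)
        self.capacity = cap
        self.fverts = np.zeros((cap, self.maxv, 3))
        self.fnv = np.zeros(cap, np.int64)
        self.flen = np.zeros(cap)
        self.flast = np.zeros(cap)
        self.falpha = np.zeros(cap)
        self.nf_a = np.zeros(1, np.int64)
        self.time_a = np.zeros(1)

        self.seeds = np.zeros((n_seeds, 3))
        if n_seeds:
            self.seeds[:, 0] = rng.uniform(0.0, box.size_x, n_seeds)
            self.seeds[:, 1] = rng.uniform(0.0, box.size_y, n_seeds)
            self.seeds[:, 2] = box.size_z / 2.0
        self.seed_used = np.zeros(n_seeds, np.uint8)
        self.pool = np.array([self.growth.omega, 0.0])

        self.linker_specs = list(linker_specs)
        self.linker_names = [s.name for s in self.linker_specs]
        nl = int(sum(linker_counts))
        self.lspec = np.zeros(nl, np.int64)
        i = 0
        for si, cnt in enumerate(linker_counts):
            self.lspec[i:i + cnt] = si
            i += cnt
        self.lpos = np.zeros((nl, 3))
        if nl:
            self.lpos[:, 0] = rng.uniform(0.0, box.size_x, nl)
            self.lpos[:, 1] = rng.uniform(0.0, box.size_y, nl)
            self.lpos[:, 2] = rng.uniform(0.0, box.size_z, nl)
        self.lfil = np.full((nl, 2), -1, np.int64)
        self.labs = np.zeros((nl, 2))
        self._pack_spec_tables()

        self.gamma_vertex = self.params.gamma_vertex(self.seg_rest)
        max_range = max((u.binding_range for s in self.linker_specs
                         for u in s.units), default=0.0)
        # steric broadphase must reach two half-segments plus the onset
        # distance; binding queries only half a segment plus the capture
        # radius, so they use a finer grid
        self._cell_min = 1.5 * self.seg_rest + max(self.params.d_steric,
                                                   max_range)
        self._cell_min_bind = 0.75 * self.seg_rest + max_range
        self._binv = self._bending_inverse()
        self._F = np.zeros((cap, self.maxv, 3))
        self._lforce = np.zeros((nl, 3))
        self._lfpar = np.zeros((nl, 2))
        self._kernel_seed = int(rng.integers(2 ** 31))
        self._kernel_seeded = False

    # -- construction helpers ------------------------------------------

    def _pack_spec_tables(self) -> None:
        ns = len(self.linker_specs)
        self.s_k = np.zeros(ns)
        self.s_e = np.zeros(ns)
        self.s_gfree = np.zeros(ns)
        self.u_is_motor = np.zeros((ns, 2), np.uint8)
        self.u_dir = np.zeros((ns, 2), np.int64)
        self.u_vm = np.zeros((ns, 2))
        self.u_fs = np.ones((ns, 2))
        self.u_D = np.zeros((ns, 2))
        self.u_kon = np.zeros((ns, 2))
        self.u_range = np.ones((ns, 2))
        self.u_koff0 = np.zeros((ns, 2))
        self.u_funb = np.ones((ns, 2))
        self.u_hold = np.zeros((ns, 2), np.uint8)
        for si, sp in enumerate(self.linker_specs):
            self.s_k[si] = sp.k_spring
            self.s_e[si] = sp.rest_length
            self.s_gfree[si] = sp.drag_free
            for j, u in enumerate(sp.units):
                self.u_is_motor[si, j] = 1 if u.kind == "motor" else 0
                self.u_dir[si, j] = u.direction if u.kind == "motor" else 0
                self.u_vm[si, j] = u.vm
                self.u_fs[si, j] = u.fs
                self.u_D[si, j] = u.D
                self.u_kon[si, j] = u.k_on
                self.u_range[si, j] = u.binding_range
                self.u_koff0[si, j] = u.k_off0
                self.u_funb[si, j] = u.f_unb
                self.u_hold[si, j] = 1 if u.end_policy == "hold" else 0

    def _bending_inverse(self) -> np.ndarray:
        """Per-vertex-count inverses of the implicit bending operator
        ``I + (dt kappa / gamma l^3) A^T A``, used both as the direct
        bending solve and as the CG block preconditioner."""
        mv = self.maxv
        binv = np.zeros((mv + 1, mv, mv))
        fac = self.params.dt * self.kappa / (self.gamma_vertex
                                             * self.seg_rest ** 3)
        for nv in range(2, mv + 1):
            a = np.zeros((max(nv - 2, 0), nv))
            for i in range(nv - 2):
                a[i, i:i + 3] = (1.0, -2.0, 1.0)
            m = np.eye(nv) + fac * (a.T @ a)
            binv[nv, :nv, :nv] = np.linalg.inv(m)
        return binv

    # -- inspection -----------------------------------------------------

    @property
    def time(self) -> float:
        return float(self.time_a[0])

    @property
    def n_filaments(self) -> int:
        return int(self.nf_a[0])

    @property
    def n_linkers(self) -> int:
        return self.lspec.shape[0]

    @property
    def polymerized(self) -> float:
        return float(self.pool[1])

    def filament(self, i: int, copy: bool = True) -> Filament:
        """A :class:`~mtnet.filaments.Filament` view of filament ``i``."""
        if not 0 <= i < self.n_filaments:
            raise IndexError(f"no filament {i}")
        nv = int(self.fnv[i])
        v = self.fverts[i, :nv]
        return Filament(id=i, vertices=v.copy() if copy else v,
                        rest_segment_length=self.seg_rest,
                        alpha=float(self.falpha[i]), rigidity=self.kappa,
                        growing=self.time < self.growth_duration,
                        last_rest=float(self.flast[i]))

    @property
    def filaments(self) -> list[Filament]:
        return [self.filament(i) for i in range(self.n_filaments)]

    def tubulin_pool(self) -> TubulinPool:
        return TubulinPool(omega=float(self.pool[0]),
                           polymerized=float(self.pool[1]))

    # -- mutation (tests and scenario assembly) -------------------------

    def add_filament(self, vertices: np.ndarray, alpha: float = 0.0,
                     last_rest: float | None = None) -> int:
        """Insert a filament directly (bypassing nucleation); the pool
        is debited by its length."""
        v = np.asarray(vertices, dtype=float)
        if v.shape[0] > self.maxv:
            raise ValueError("too many vertices for this state")
        i = self.n_filaments
        if i >= self.capacity:
            raise ValueError("filament capacity exhausted")
        nv = v.shape[0]
        self.fverts[i, :nv] = v
        self.fnv[i] = nv
        lr = float(np.linalg.norm(v[-1] - v[-2])) if last_rest is None \
            else float(last_rest)
        self.flast[i] = lr
        self.flen[i] = (nv - 2) * self.seg_rest + lr
        self.falpha[i] = alpha
        self.nf_a[0] = i + 1
        self.pool[1] = min(self.pool[0], self.pool[1] + self.flen[i])
        return i

    def bind(self, linker: int, unit: int, fil: int, abscissa: float) -> None:
        """Force a unit onto a filament (test/scenario plumbing)."""
        if self.lfil[linker, 1 - unit] == fil:
            raise ValueError("both units on one filament is forbidden")
        if not 0.0 <= abscissa <= self.flen[fil]:
            raise ValueError("abscissa outside filament")
        self.lfil[linker, unit] = fil
        self.labs[linker, unit] = abscissa

    # -- integration -----------------------------------------------------

    def step(self, n: int = 1) -> None:
        """Advance ``n`` Langevin steps."""
        if not self._kernel_seeded:
            _kernels.seed_rng(self._kernel_seed)
            self._kernel_seeded = True
        p = self.params
        status = _kernels.run_chunk(
            n,
            self.fverts, self.fnv, self.flen, self.flast, self.falpha,
            self.nf_a, self.seg_rest, self.kappa, self.maxv,
            self.seeds, self.seed_used, self.pool,
            self.growth.alpha0, self.growth.speed_sd_factor,
            self.growth.speed_clip[0], self.growth.speed_clip[1],
            self.nucleation_rate, self.growth_duration, self.initial_length,
            self.box.size_x, self.box.size_y, self.box.size_z,
            p.dt, p.kBT, self.gamma_vertex, p.k_steric, p.d_steric,
            self._cell_min, self._cell_min_bind, self._binv,
            self.lspec, self.lpos, self.lfil, self.labs,
            self.s_k, self.s_e, self.s_gfree,
            self.u_is_motor, self.u_dir, self.u_vm, self.u_fs, self.u_D,
            self.u_kon, self.u_range, self.u_koff0, self.u_funb, self.u_hold,
            self.time_a, self._F, self._lforce, self._lfpar)
        if status == 1:
            raise RuntimeError(
                f"segment-length constraint solver failed to converge "
                f"at t = {self.time:.3f} s")
        if status == 2:
            raise RuntimeError(
                f"implicit (bending+spring) solver failed to converge "
                f"at t = {self.time:.3f} s")
        if not np.all(np.isfinite(self.fverts[:self.n_filaments])):
            raise FloatingPointError(
                f"non-finite vertex position at t = {self.time:.3f} s")


# ---------------------------------------------------------------------------
# module-level operations

def assemble_forces(state: SystemState) -> np.ndarray:
    """Deterministic per-vertex forces: bending + cross-link springs +
    steric repulsion.  Thermal noise excluded; internal forces sum to
    zero over the whole system."""
    nf = state.n_filaments
    F = np.zeros_like(state._F)
    lforce = np.zeros_like(state._lforce)
    lfpar = np.zeros_like(state._lfpar)
    _kernels.compute_forces(
        state.fverts, state.fnv, state.flen, state.flast, nf,
        state.seg_rest, state.kappa, True, True,
        state.box.size_x, state.box.size_y,
        state.params.k_steric, state.params.d_steric, state._cell_min,
        state.lspec, state.lfil, state.labs, state.s_k, state.s_e,
        state.u_is_motor, state.u_dir, F, lforce, lfpar)
    if not np.all(np.isfinite(F[:nf])):
        raise FloatingPointError("non-finite force encountered")
    return F[:nf]


def steric_forces(fil_a: Filament, fil_b: Filament,
                  params: PhysicsParams, box: SimulationBox
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Soft-core repulsion between two filaments.

    For each close segment pair the Hookean overlap force acts along
    the closest-approach direction with the components parallel to
    both filament axes removed, so that repulsion produces minimal
    axial sliding force; the forces on the pair are exactly equal and
    opposite.  Returns per-vertex force arrays for the two filaments.
    """
    mv = max(fil_a.n_vertices, fil_b.n_vertices)
    st = SystemState(box, params=params, seg_rest=fil_a.rest_segment_length,
                     kappa=0.0, capacity=2, max_vertices=mv)
    st.add_filament(fil_a.vertices, last_rest=fil_a.last_rest)
    st.add_filament(fil_b.vertices, last_rest=fil_b.last_rest)
    F = assemble_forces(st)
    return F[0, :fil_a.n_vertices].copy(), F[1, :fil_b.n_vertices].copy()


def potential_energy(state: SystemState) -> float:
    """Bending plus cross-link spring energy (pN µm).

    The steric term is excluded: its axial projection makes the steric
    force deliberately non-conservative, so only the bending and spring
    contributions admit a potential.
    """
    e = sum(bending_energy(f) for f in state.filaments)
    for li in range(state.n_linkers):
        if state.lfil[li, 0] < 0 or state.lfil[li, 1] < 0:
            continue
        sp = state.lspec[li]
        pa = state.filament(int(state.lfil[li, 0])).point_at_abscissa(
            float(state.labs[li, 0]))
        pb = state.filament(int(state.lfil[li, 1])).point_at_abscissa(
            float(state.labs[li, 1]))
        u = minimum_image(pb - pa, state.box)
        d = float(np.linalg.norm(u))
        e += 0.5 * state.s_k[sp] * (d - state.s_e[sp]) ** 2
    return float(e)


def langevin_step(state: SystemState) -> SystemState:
    """Advance one time step (in place); returns the state."""
    state.step(1)
    return state


def enforce_segment_lengths(filament: Filament, tol: float = 1e-6,
                            max_iter: int = 100) -> np.ndarray:
    """Restore consecutive-vertex distances to the rest lengths by
    iterative pairwise projection (in place; returns the vertices)."""
    v = filament.vertices
    nv = filament.n_vertices
    for _ in range(max_iter):
        maxrel = 0.0
        for j in range(nv - 1):
            target = (filament.rest_segment_length if j < nv - 2
                      else filament.last_rest)
            d = v[j + 1] - v[j]
            dn = float(np.linalg.norm(d))
            if dn < 1e-12:
                v[j + 1] = v[j] + np.array([target, 0.0, 0.0])
                continue
            err = dn - target
            maxrel = max(maxrel, abs(err) / target)
            corr = 0.5 * err / dn
            v[j] += corr * d
            v[j + 1] -= corr * d
        if maxrel < tol:
            return v
    raise RuntimeError(
        f"constraint projection did not converge for filament {filament.id}")


def check_conservation(state: SystemState, tol: float = 1e-6) -> None:
    """Assert tubulin conservation: the pool's polymerized record
    matches the summed filament lengths and never exceeds Omega."""
    total = float(np.sum(state.flen[:state.n_filaments]))
    if abs(total - state.polymerized) > tol * max(1.0, state.pool[0]):
        raise AssertionError(
            f"tubulin conservation violated: sum L = {total}, "
            f"pool records {state.polymerized}")
    if state.polymerized > state.pool[0] * (1 + 1e-9):
        raise AssertionError("polymerized length exceeds the pool")


def run_until(state: SystemState, t_end: float,
              frame_interval: float | None = None,
              observers: tuple = ()) -> "object":
    """Integrate to ``t_end``, capturing frames every
    ``frame_interval`` seconds (including t = start).

    Observers are callables ``obs(state, frame)`` invoked at each
    captured frame.  Returns a :class:`mtnet.quantify.Trajectory`;
    with ``frame_interval`` None only the initial and final frames are
    kept.  Fully reproducible for a fixed seed and configuration.
    """
    from .quantify import Frame, Trajectory

    if t_end < state.time - 1e-12:
        raise ValueError("t_end precedes current time")
    dt = state.params.dt
    if frame_interval is None:
        frame_interval = max(t_end - state.time, dt)
    nsub = max(1, round(frame_interval / dt))

    def capture() -> Frame:
        fr = Frame(
            time=state.time,
            vertices=[state.fverts[i, :state.fnv[i]].copy()
                      for i in range(state.n_filaments)],
            link_spec=state.lspec.copy(),
            link_fil=state.lfil.copy(),
            link_abs=state.labs.copy())
        for obs in observers:
            obs(state, fr)
        return fr

    frames = [capture()]
    nsteps_total = round((t_end - state.time) / dt)
    done = 0
    while done < nsteps_total:
        n = min(nsub, nsteps_total - done)
        state.step(n)
        done += n
        frames.append(capture())
    return Trajectory(frames=frames, linker_names=list(state.linker_names),
                      meta={"seed": state.seed})
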
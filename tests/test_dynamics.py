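import numpy as np
import pytest

from mtnet.crosslinkers import LinkerSpec, UnitSpec, linker_catalog
from mtnet.dynamics import (PhysicsParams, SystemState, assemble_forces,
                            check_conservation, enforce_segment_lengths,
                            langevin_step, potential_energy, run_until,
                            steric_forces)
from mtnet.filaments import Filament
from mtnet.geometry import SimulationBox

BOX = SimulationBox(20.0, 20.0, 0.2)


def straight(start, direction, n, l=0.5, z=0.1):
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    return np.array([[start[0] + i * l * d[0], start[1] + i * l * d[1], z]
                     for i in range(n)])


def two_filament_state(va, vb, spec=None, n_link=0, params=None,
                       box=BOX, seed=0, kappa=20.0):
    st = SystemState(box, params=params or PhysicsParams(),
                     linker_specs=[spec] if spec else [],
                     linker_counts=[n_link] if spec else [],
                     capacity=2, max_vertices=max(len(va), len(vb), 4),
                     kappa=kappa, seed=seed)
    st.add_filament(va)
    st.add_filament(vb)
    return st


#: inert anchor unit: never binds, never unbinds, never moves
PIN = UnitSpec(kind="diffusive", D=0.0, k_on=0.0, k_off0=0.0, f_unb=10.0,
               end_policy="hold")
PIN_SPEC = LinkerSpec("pin", PIN, PIN, k_spring=50.0, rest_length=0.05)


class TestAssembleForces:
    def test_isolated_straight_filaments_zero(self):
        st = two_filament_state(straight((2, 2, 0), (1, 0), 4),
                                straight((10, 10, 0), (0, 1), 4))
        F = assemble_forces(st)
        np.testing.assert_allclose(F, 0.0, atol=1e-12)

    def test_single_linker_action_reaction(self):
        va = straight((5, 5, 0), (1, 0), 4)
        vb = straight((5, 5.5, 0), (1, 0), 4)
        st = two_filament_state(va, vb, PIN_SPEC, 1)
        st.bind(0, 0, 0, 0.7)
        st.bind(0, 1, 1, 0.9)
        F = assemble_forces(st)
        fa = F[0].sum(axis=0)
        fb = F[1].sum(axis=0)
        np.testing.assert_allclose(fa + fb, 0.0, atol=1e-10)
        assert np.linalg.norm(fa) > 0  # 0.5 µm apart vs 0.05 rest length

    def test_forces_are_negative_energy_gradient(self, rng):
        """Central finite differences of bending + spring energy match
        the assembled forces (no steric contacts in this layout)."""
        va = straight((5, 5, 0), (1, 0.2), 5) + rng.normal(0, 0.02, (5, 3))
        vb = straight((5, 6.5, 0), (1, -0.1), 5) + rng.normal(0, 0.02, (5, 3))
        st = two_filament_state(va, vb, PIN_SPEC, 2)
        st.bind(0, 0, 0, 0.6)
        st.bind(0, 1, 1, 1.1)
        st.bind(1, 0, 0, 1.7)
        st.bind(1, 1, 1, 0.3)
        F = assemble_forces(st)
        h = 1e-5
        for fi in range(2):
            for j in range(5):
                for c in range(3):
                    orig = st.fverts[fi, j, c]
                    st.fverts[fi, j, c] = orig + h
                    ep = potential_energy(st)
                    st.fverts[fi, j, c] = orig - h
                    em = potential_energy(st)
                    st.fverts[fi, j, c] = orig
                    fd = -(ep - em) / (2 * h)
                    assert F[fi, j, c] == pytest.approx(fd, rel=1e-4,
                                                        abs=1e-6)

    def test_momentum_neutrality_with_contacts(self, rng):
        """Total internal force vanishes even with steric overlaps."""
        va = straight((5, 5, 0), (1, 0), 5)
        vb = straight((5, 5.02, 0), (1, 0.1), 5)  # overlapping
        st = two_filament_state(va, vb, PIN_SPEC, 1)
        st.bind(0, 0, 0, 0.6)
        st.bind(0, 1, 1, 0.8)
        F = assemble_forces(st)
        total = np.abs(F.sum(axis=(0, 1))).max()
        assert total < 1e-10 * max(np.abs(F).max(), 1.0)


class TestStericForces:
    P = PhysicsParams()

    def test_zero_outside_range(self):
        fa = Filament(id=0, vertices=straight((5, 5, 0), (1, 0), 3))
        fb = Filament(id=1, vertices=straight((5, 5.2, 0), (1, 0), 3))
        Fa, Fb = steric_forces(fa, fb, self.P, BOX)
        np.testing.assert_allclose(Fa, 0.0)
        np.testing.assert_allclose(Fb, 0.0)

    def test_parallel_offset_magnitude_and_direction(self):
        d = 0.5 * self.P.d_steric
        fa = Filament(id=0, vertices=straight((5, 5, 0), (1, 0), 3))
        fb = Filament(id=1, vertices=straight((5, 5 + d, 0), (1, 0), 3))
        Fa, Fb = steric_forces(fa, fb, self.P, BOX)
        # purely perpendicular to both (parallel) axes
        assert np.abs(Fa[:, 0]).max() < 1e-9
        assert np.abs(Fa[:, 2]).max() < 1e-9
        assert Fa[:, 1].sum() < 0  # pushed apart
        np.testing.assert_allclose(Fa.sum(axis=0), -Fb.sum(axis=0),
                                   atol=1e-12)
        # per contact the magnitude is k (d_steric - r); two fully
        # overlapping 2-segment filaments make 4 segment-pair contacts
        total = -Fa[:, 1].sum()
        per_contact = self.P.k_steric * (self.P.d_steric - d)
        assert total == pytest.approx(4 * per_contact, rel=1e-6)

    def test_perpendicular_crossing_has_no_axial_component(self):
        fa = Filament(id=0, vertices=straight((5, 5), (1, 0), 3, z=0.09))
        fb = Filament(id=1, vertices=straight((5.7, 4.5), (0, 1), 3, z=0.11))
        Fa, Fb = steric_forces(fa, fb, self.P, BOX)
        assert np.abs(Fa).max() > 0
        # axial = x for filament a, y for filament b
        assert np.abs(Fa[:, 0]).max() < 1e-6 * np.abs(Fa).max()
        assert np.abs(Fb[:, 1]).max() < 1e-6 * np.abs(Fb).max()


class TestLangevinStep:
    def test_quiescent_system_does_not_move(self):
        par = PhysicsParams(kBT=0.0)
        st = two_filament_state(straight((2, 2, 0), (1, 0), 4),
                                straight((10, 10, 0), (0, 1), 4),
                                params=par)
        before = st.fverts.copy()
        langevin_step(st)
        np.testing.assert_allclose(st.fverts, before, atol=1e-12)

    def test_spring_relaxation_rate(self):
        """Two rigid 2-vertex filaments joined by one cross-link relax
        toward the rest length as exp(-k t / gamma)."""
        par = PhysicsParams(dt=1e-4, kBT=0.0)
        d0, e, k = 0.30, 0.05, 50.0
        va = straight((8, 8, 0), (1, 0), 2)
        vb = straight((8, 8 + d0, 0), (1, 0), 2)
        st = two_filament_state(va, vb, PIN_SPEC, 1, params=par)
        st.bind(0, 0, 0, 0.25)
        st.bind(0, 1, 1, 0.25)
        gamma = st.gamma_vertex
        n = 1000
        st.step(n)
        t = n * par.dt
        d = st.fverts[1, 0, 1] - st.fverts[0, 0, 1]
        expected = e + (d0 - e) * np.exp(-k * t / gamma)
        assert d == pytest.approx(expected, rel=0.02)

    def test_free_linker_msd(self):
        """Unbound complexes diffuse with their own drag:
        MSD = 6 kBT dt n / gamma."""
        box = SimulationBox(40, 40, 40)
        st = SystemState(box, params=PhysicsParams(),
                         linker_specs=[PIN_SPEC], linker_counts=[3000],
                         capacity=1, seed=5)
        st.lpos[:] = 20.0  # center: no wrap or wall within reach
        p0 = st.lpos.copy()
        n = 200
        st.step(n)
        msd = float(np.mean(np.sum((st.lpos - p0) ** 2, axis=1)))
        expected = 6 * st.params.kBT * st.params.dt * n / PIN_SPEC.drag_free
        assert msd == pytest.approx(expected, rel=0.05)

    def test_same_seed_bitwise_identical(self):
        def make():
            st = SystemState(BOX, params=PhysicsParams(),
                             linker_specs=[linker_catalog("hset")],
                             linker_counts=[50], n_seeds=20,
                             capacity=20, seed=42)
            st.step(400)
            return st
        a, b = make(), make()
        assert np.array_equal(a.fverts, b.fverts)
        assert np.array_equal(a.lpos, b.lpos)
        assert np.array_equal(a.lfil, b.lfil)
        assert np.array_equal(a.labs, b.labs)
        assert a.time == b.time and a.n_filaments == b.n_filaments

    def test_dt_halving_consistency(self):
        """Halving dt changes the measured sliding speed of a
        two-filament KIF11 pair by < 5% (first-order integrator
        consistency)."""
        from mtnet.quantify import signed_mt_speed

        def sliding_speed(dt):
            par = PhysicsParams(dt=dt)
            box = SimulationBox(30, 30, 0.2)
            st = SystemState(box, params=par,
                             linker_specs=[linker_catalog("kif11")],
                             linker_counts=[100], capacity=2,
                             max_vertices=12, seed=7)
            n, l = 11, 0.5
            va = np.array([[10 + i * l, 15.0, 0.1] for i in range(n)])
            vb = np.array([[10 + (n - 1 - i) * l, 15.03, 0.1]
                           for i in range(n)])
            st.add_filament(va)
            st.add_filament(vb)
            rng = np.random.default_rng(3)
            for li in range(100):
                a = rng.uniform(0.5, 4.5)
                st.bind(li, 0, 0, a)
                st.bind(li, 1, 1, 5.0 - a)
            traj = run_until(st, 30.0, frame_interval=30.0)
            return signed_mt_speed(traj, 30.0)

        v1 = sliding_speed(0.005)
        v2 = sliding_speed(0.0025)
        assert v1 == pytest.approx(v2, rel=0.05)


class TestConstraints:
    def test_already_satisfied_identity(self):
        f = Filament(id=0, vertices=straight((0, 0, 0), (1, 0), 5))
        before = f.vertices.copy()
        enforce_segment_lengths(f)
        np.testing.assert_allclose(f.vertices, before, atol=1e-12)

    def test_uniform_stretch_contracts_preserving_direction(self):
        v = straight((0, 0, 0), (1, 0), 5) * 1.01
        f = Filament(id=0, vertices=v, last_rest=0.5)
        enforce_segment_lengths(f)
        d = np.linalg.norm(np.diff(f.vertices, axis=0), axis=1)
        np.testing.assert_allclose(d, 0.5, rtol=1e-6)
        # still along +x
        assert np.abs(np.diff(f.vertices, axis=0)[:, 1:]).max() < 1e-12

    def test_random_perturbation_projected_back(self, rng):
        v = straight((0, 0, 0), (1, 0), 6)
        pert = rng.normal(0, 0.004, v.shape)
        f = Filament(id=0, vertices=v + pert, last_rest=0.5)
        enforce_segment_lengths(f)
        d = np.linalg.norm(np.diff(f.vertices, axis=0), axis=1)
        np.testing.assert_allclose(d, 0.5, rtol=1e-6)
        disp = np.linalg.norm(f.vertices - (v + pert), axis=1).max()
        assert disp <= np.linalg.norm(pert, axis=1).max() * 2.5


class TestRunUntil:
    def _state(self):
        return SystemState(BOX, params=PhysicsParams(),
                           n_seeds=10, capacity=10, seed=9)

    def test_no_steps_when_t_end_now(self):
        st = self._state()
        traj = run_until(st, 0.0)
        assert len(traj.frames) == 1 and st.time == 0.0

    def test_frame_counting(self):
        st = self._state()
        traj = run_until(st, 600.0, frame_interval=60.0)
        assert len(traj.frames) == 11
        np.testing.assert_allclose(traj.times, np.arange(11) * 60.0,
                                   atol=1e-6)

    def test_past_t_end_rejected(self):
        st = self._state()
        st.step(10)
        with pytest.raises(ValueError):
            run_until(st, 0.01)


class TestConservation:
    def test_growth_conserves_tubulin_and_lengths_monotone(self):
        from mtnet.scenarios import ScenarioConfig, build_state
        cfg = ScenarioConfig(size_x_um=5.0, size_y_um=5.0,
                             duration_s=300.0, frame_interval_s=50.0,
                             delta_t_s=100.0, seed=11)
        st = build_state(cfg)
        traj = run_until(st, 300.0, frame_interval=50.0)
        check_conservation(st)
        # no catastrophe: every filament's length is non-decreasing
        lens = [
            {i: np.sum(np.linalg.norm(np.diff(f.vertices[i], axis=0),
                                      axis=1))
             for i in range(f.n_filaments)} for f in traj.frames]
        for a, b in zip(lens, lens[1:]):
            for i, la in a.items():
                assert b[i] >= la - 1e-6
        # pool near exhaustion: mean length approaches Omega / n
        mean = st.polymerized / st.n_filaments
        assert mean == pytest.approx(cfg.mean_length_um, rel=0.02)
        assert st.polymerized <= st.pool[0] * (1 + 1e-9)
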
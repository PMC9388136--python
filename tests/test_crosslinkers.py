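import numpy as np
import pytest

from mtnet.crosslinkers import (CATALOG_NAMES, LinkerState, UnitSpec,
                                advance_motor, apply_end_policy,
                                binding_attempt, diffusive_hop_rates,
                                link_force, linker_catalog, motor_velocity,
                                simulate_unit_episode, unbinding_rate)
from mtnet.filaments import LATTICE_UM
from mtnet.geometry import SimulationBox

KBT = 4.23e-3


class TestCatalog:
    def test_kif11_symmetric_plus_release(self):
        sp = linker_catalog("kif11")
        for u in sp.units:
            assert u.kind == "motor" and u.direction == +1
            assert u.end_policy == "release"
        assert sp.unit_a == sp.unit_b

    def test_hset_asymmetric_with_500x_dwell(self):
        sp = linker_catalog("hset")
        motor, tail = sp.unit_a, sp.unit_b
        assert motor.kind == "motor" and motor.direction == -1
        assert tail.kind == "diffusive" and tail.D > 0
        assert motor.end_policy == tail.end_policy == "hold"
        # zero-force dwell ratio diffusive/motor = 500
        assert motor.k_off0 / tail.k_off0 == pytest.approx(500.0)
        # nonprocessive: two steps per engagement on average
        assert (motor.vm / LATTICE_UM) / motor.k_off0 == pytest.approx(2.0)

    def test_variants(self):
        assert linker_catalog("hset_plus").unit_a.direction == +1
        assert linker_catalog("hset_stiff_tail").unit_b.D == 0.0
        dm = linker_catalog("double_motor_hset")
        assert dm.unit_a == dm.unit_b and dm.unit_a.kind == "motor"
        dt = linker_catalog("double_tail_hset")
        assert dt.unit_a == dt.unit_b and dt.unit_a.kind == "diffusive"
        assert dt.unit_a.end_policy == "hold"
        rel = linker_catalog("double_tail_end_release")
        assert rel.unit_a.end_policy == "release"
        sm = linker_catalog("symmetric_minus")
        assert sm.unit_a == sm.unit_b and sm.unit_a.direction == -1
        # mildly processive: more steps per engagement than HSET's motor
        hm = linker_catalog("hset").unit_a
        assert (sm.unit_a.vm / LATTICE_UM) / sm.unit_a.k_off0 \
            > (hm.vm / LATTICE_UM) / hm.k_off0

    def test_unknown_name_lists_catalog(self):
        with pytest.raises(KeyError, match="kif11"):
            linker_catalog("dynein")
        assert set(CATALOG_NAMES) == {
            "kif11", "hset", "hset_plus", "hset_stiff_tail",
            "double_motor_hset", "double_tail_hset",
            "double_tail_end_release", "symmetric_minus"}


class TestUnbindingRate:
    def test_bell_law(self):
        assert unbinding_rate(2.0, 3.0, 0.0) == pytest.approx(2.0)
        assert unbinding_rate(2.0, 3.0, 3.0) == pytest.approx(2.0 * np.e)

    def test_log_linearity(self):
        r = lambda f: unbinding_rate(0.5, 2.0, f)
        assert r(4.0) * r(0.0) == pytest.approx(r(2.0) ** 2)


class TestMotorVelocity:
    @pytest.mark.parametrize("f_par,expected", [
        (0.0, 0.08), (-5.0, 0.0), (-2.5, 0.04),
    ])
    def test_linear_law(self, f_par, expected):
        assert motor_velocity(0.08, 5.0, f_par) == pytest.approx(expected)

    def test_clipped_to_twice_unloaded(self):
        assert motor_velocity(0.08, 5.0, 50.0) == pytest.approx(0.16)
        assert motor_velocity(0.08, 5.0, -50.0) == 0.0


class TestHopRates:
    def test_unbiased(self):
        rp, rm = diffusive_hop_rates(0.02, 0.0, KBT)
        assert rp == rm == pytest.approx(0.02 / LATTICE_UM ** 2)

    def test_detailed_balance(self):
        for f in (-2.0, -0.5, 0.3, 1.7):
            rp, rm = diffusive_hop_rates(0.02, f, KBT)
            assert rp / rm == pytest.approx(np.exp(f * LATTICE_UM / KBT))

    def test_einstein_relation_small_force(self):
        """Lattice drift a (r+ - r-) approaches D f / kBT."""
        f = 0.1 * 2 * KBT / LATTICE_UM  # exponent x = 0.1
        rp, rm = diffusive_hop_rates(0.02, f, KBT)
        drift = LATTICE_UM * (rp - rm)
        assert drift == pytest.approx(0.02 * f / KBT, rel=0.02)

    def test_drift_recovered_by_hop_sampling(self, rng):
        """Monte-Carlo hop counts reproduce the closed-form drift."""
        D, T = 0.02, 50.0
        f = 0.1 * 2 * KBT / LATTICE_UM
        rp, rm = diffusive_hop_rates(D, f, KBT)
        n = 2000
        net = rng.poisson(rp * T, n) - rng.poisson(rm * T, n)
        drift = LATTICE_UM * net.mean() / T
        se = LATTICE_UM * np.sqrt((rp + rm) / (T * n))
        assert abs(drift - D * f / KBT) < 4 * se + 0.02 * D * f / KBT


class TestLinkForce:
    def test_zero_at_rest_length(self):
        f = link_force([0, 0, 0], [0.05, 0, 0], 50.0, 0.05)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_stretched_pulls_toward_partner(self):
        e = 0.05
        f = link_force([0, 0, 0], [2 * e, 0, 0], 50.0, e)
        np.testing.assert_allclose(f, [50.0 * e, 0, 0], atol=1e-12)

    def test_compressed_repels(self):
        f = link_force([0, 0, 0], [0.02, 0, 0], 50.0, 0.05)
        assert f[0] < 0

    def test_newton_third_law(self, rng):
        a, b = rng.normal(size=3), rng.normal(size=3)
        fa = link_force(a, b, 50.0, 0.05)
        fb = link_force(b, a, 50.0, 0.05)
        np.testing.assert_allclose(fa, -fb, atol=1e-12)

    def test_minimum_image_applied(self):
        box = SimulationBox(20, 20, 0.2)
        f = link_force([0.5, 0, 0.1], [19.5, 0, 0.1], 50.0, 0.05, box)
        assert f[0] < 0  # nearest image is across the boundary

    def test_degenerate_coincident_is_zero(self):
        f = link_force([1, 1, 1], [1, 1, 1], 50.0, 0.05)
        np.testing.assert_allclose(f, 0.0)


class TestEndPolicy:
    def test_kif11_releases_at_plus_end_only(self):
        u = linker_catalog("kif11").unit_a
        assert apply_end_policy(u, False, True) == "release"
        assert apply_end_policy(u, True, False) == "keep"
        assert apply_end_policy(u, False, False) == "keep"

    def test_hset_units_hold_at_ends(self):
        sp = linker_catalog("hset")
        assert apply_end_policy(sp.unit_a, True, False) == "keep"
        assert apply_end_policy(sp.unit_b, False, True) == "keep"

    def test_release_tails_release_at_either_end(self):
        u = linker_catalog("double_tail_end_release").unit_a
        assert apply_end_policy(u, True, False) == "release"
        assert apply_end_policy(u, False, True) == "release"


class TestBindingAttempt:
    def _state(self):
        return LinkerState(spec=linker_catalog("hset"),
                           position=np.zeros(3), anchors=[None, None])

    def test_no_candidates_no_change(self, rng):
        s = self._state()
        assert not binding_attempt(s, 0, [], 0.005, rng)
        assert s.anchors == [None, None]

    def test_partner_filament_excluded(self, rng):
        s = self._state()
        s.anchors[1] = (7, 1.0)
        # only the partner's filament in range: can never bind
        for _ in range(2000):
            assert not binding_attempt(s, 0, [(7, 0.5)], 0.005, rng)

    def test_binding_probability(self, rng):
        n, dt = 20000, 0.005
        k_on = linker_catalog("hset").unit_a.k_on
        hits = 0
        for _ in range(n):
            s = self._state()
            if binding_attempt(s, 0, [(3, 0.5)], dt, rng):
                hits += 1
                assert s.anchors[0] == (3, 0.5)
        p = -np.expm1(-k_on * dt)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 4 * se

    def test_same_filament_state_rejected(self):
        with pytest.raises(ValueError):
            LinkerState(spec=linker_catalog("kif11"), position=np.zeros(3),
                        anchors=[(1, 0.2), (1, 0.8)])


class TestAdvanceMotor:
    def test_zero_speed_stays(self, rng):
        u = linker_catalog("hset").unit_a
        a, clamped = advance_motor(1.0, 2.5, u, 0.0, 0.005, rng)
        assert a == 1.0 and not clamped

    def test_poisson_stepping_statistics(self, rng):
        """Sustained zero-load stepping: mean displacement v t toward
        the minus end with Poisson step-count variance."""
        u = linker_catalog("hset").unit_a  # minus-directed, vm = 0.08
        v, t_total, dt = u.vm, 10.0, 0.005
        n = 1500
        disp = np.empty(n)
        for i in range(n):
            a = 5.0
            for _ in range(int(t_total / dt)):
                a, _ = advance_motor(a, 10.0, u, v, dt, rng)
            disp[i] = a - 5.0
        lam = v * t_total / LATTICE_UM  # expected number of steps
        mean, var = disp.mean(), disp.var()
        assert mean == pytest.approx(-v * t_total,
                                     abs=4 * LATTICE_UM * np.sqrt(lam / n))
        assert var == pytest.approx(lam * LATTICE_UM ** 2, rel=0.15)

    def test_clamped_at_end(self, rng):
        u = linker_catalog("kif11").unit_a  # plus-directed
        a, clamped = advance_motor(2.499, 2.5, u, 10.0, 1.0, rng)
        assert a == 2.5 and clamped


class TestEpisodes:
    def test_hset_motor_two_steps_per_engagement(self, rng):
        u = linker_catalog("hset").unit_a
        steps = [simulate_unit_episode(u, rng)[1] for _ in range(20000)]
        assert np.mean(steps) == pytest.approx(2.0, rel=0.03)

    def test_dwell_ratio_500(self, rng):
        sp = linker_catalog("hset")
        dw_m = np.mean([simulate_unit_episode(sp.unit_a, rng)[0]
                        for _ in range(10000)])
        dw_t = np.mean([simulate_unit_episode(sp.unit_b, rng)[0]
                        for _ in range(10000)])
        assert dw_t / dw_m == pytest.approx(500.0, rel=0.05)

    def test_stall_no_net_motion(self, rng):
        """A motor loaded at exactly -fs has zero velocity, hence zero
        steps over any horizon."""
        u = linker_catalog("kif11").unit_a
        for _ in range(200):
            _, steps = simulate_unit_episode(u, rng, f_par=-u.fs)
            assert steps == 0
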
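import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurorun.dynamics import Kinematics
from neurorun.muscle import (CurveSet, MTUParams, MuscleError, MuscleState,
                             activation_step, fiber_power, moment_arms,
                             mtu_force, mtu_length_velocity,
                             muscle_generalized_force)
from neurorun.skeleton import build_model

CURVES = CurveSet()


def _two_link():
    """World-anchored two-link chain with a pin joint j1 between the links."""
    L = 0.6
    return build_model({
        "bodies": [
            {"name": "l0", "mass": 1.0, "inertia": [0.05, 0.05, 0.05],
             "com": [0, 0, -0.3]},
            {"name": "l1", "mass": 1.0, "inertia": [0.05, 0.05, 0.05],
             "com": [0, 0, -0.3]},
        ],
        "joints": [
            {"name": "j0", "type": "revolute1", "child": "l0", "axis": [0, 1, 0]},
            {"name": "j1", "type": "revolute1", "parent": "l0", "child": "l1",
             "translation": [0, 0, -L], "axis": [0, 1, 0]},
        ],
    }), L


class TestActivationDynamics:
    def test_fixed_point(self):
        assert activation_step(0.4, 0.4, 1e-3) == pytest.approx(0.4)

    def test_exponential_rise_matches_closed_form(self):
        a = 0.0
        for _ in range(50):  # 0.05 s at dt = 1e-3, tau_act = 0.01
            a = activation_step(a, 1.0, 1e-3, tau_act=0.01)
        assert a == pytest.approx(1.0 - np.exp(-5.0), rel=0.02)

    def test_monotone_decay(self):
        a = activation_step(1.0, 0.0, 1e-3)
        assert a < 1.0

    def test_dt_validation(self):
        with pytest.raises(ValueError):
            activation_step(0.5, 0.5, 0.0)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60),
           st.floats(0, 1))
    def test_activation_stays_bounded(self, excitations, a0):
        a = a0
        for e in excitations:
            a = activation_step(a, e, 5e-3)
            assert 0.0 <= a <= 1.0


class TestPathGeometry:
    def test_same_body_path_constant_length(self, rng):
        m, L = _two_link()
        path = [("l0", (0.02, 0, -0.1)), ("l0", (0.0, 0.03, -0.5))]
        lens = []
        for _ in range(5):
            q = rng.uniform(-1.5, 1.5, 2)
            u = rng.uniform(-3, 3, 2)
            l_mt, v_mt = mtu_length_velocity(m, q, u, path)
            lens.append(l_mt)
            assert v_mt == pytest.approx(0.0, abs=1e-12)
        assert np.ptp(lens) < 1e-12

    def test_pin_joint_law_of_cosines(self):
        m, L = _two_link()
        a, b = 0.15, 0.22
        path = [("l0", (0, 0, -(L - a))), ("l1", (0, 0, -b))]
        for th in (0.0, 0.5, -0.9, 2.0):
            l_mt, _ = mtu_length_velocity(m, np.array([0.3, th]), np.zeros(2), path)
            expected = np.sqrt(a * a + b * b + 2 * a * b * np.cos(th))
            assert l_mt == pytest.approx(expected, abs=1e-10)

    def test_velocity_matches_finite_difference(self, rng):
        m, L = _two_link()
        path = [("l0", (0.03, 0, -0.2)), ("l1", (0.02, 0.01, -0.3))]
        q = rng.uniform(-1, 1, 2)
        u = rng.uniform(-2, 2, 2)
        _, v_mt = mtu_length_velocity(m, q, u, path)
        eps = 1e-6
        lp, _ = mtu_length_velocity(m, q + eps * u, np.zeros(2), path)
        lm, _ = mtu_length_velocity(m, q - eps * u, np.zeros(2), path)
        assert v_mt == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)

    def test_degenerate_path_rejected(self):
        m, L = _two_link()
        path = [("l0", (0, 0, -0.1)), ("l0", (0, 0, -0.1))]
        with pytest.raises(MuscleError):
            mtu_length_velocity(m, np.zeros(2), np.zeros(2), path)


class TestMomentArms:
    def test_unspanned_coordinate_has_zero_arm(self):
        m, L = _two_link()
        path = [("l0", (0.02, 0, -0.1)), ("l0", (0.04, 0, -0.4))]
        r = moment_arms(m, np.array([0.7, 0.3]), path)
        assert r[m.coord_index["j1"]] == pytest.approx(0.0, abs=1e-12)

    def test_pin_joint_closed_form_arm(self):
        # |r| = a b sin(pi - th') ... = a b sin(th) / l for the symmetric strap
        m, L = _two_link()
        a, b = 0.18, 0.18
        path = [("l0", (0, 0, -(L - a))), ("l1", (0, 0, -b))]
        th = 0.8
        q = np.array([0.0, th])
        l_mt, _ = mtu_length_velocity(m, q, np.zeros(2), path)
        r = moment_arms(m, q, path)
        expected = a * b * np.sin(th) / l_mt
        assert abs(r[m.coord_index["j1"]]) == pytest.approx(expected, abs=1e-6)

    def test_virtual_work_equivalence(self, rng):
        m, L = _two_link()
        path = [("l0", (0.05, 0.01, -0.15)), ("l1", (0.03, -0.02, -0.25))]
        q = rng.uniform(-1, 1, 2)
        F = 137.0
        kin = Kinematics(m, q, np.zeros(2))
        tau = muscle_generalized_force(m, kin, path, F)
        eps = 1e-7
        for j in range(2):
            dq = np.zeros(2)
            dq[j] = eps
            lp, _ = mtu_length_velocity(m, q + dq, np.zeros(2), path)
            lm, _ = mtu_length_velocity(m, q - dq, np.zeros(2), path)
            dl_dq = (lp - lm) / (2 * eps)
            assert tau[j] == pytest.approx(-F * dl_dq, abs=1e-5 * F)


def _params(l_opt=0.1, l_slack=0.05):
    return MTUParams("m", f_max=1000.0, l_opt=l_opt, l_slack=l_slack,
                     path=[("a", (0, 0, 0)), ("b", (0, 0, 1))])


class TestForceGeneration:
    def test_isometric_at_optimal_gives_f_max(self):
        p = _params()
        F, lf, vf = mtu_force(p, CURVES, p.l_slack + p.l_opt, 0.0, 1.0, "rigid")
        assert F == pytest.approx(p.f_max, rel=1e-12)
        assert lf == pytest.approx(p.l_opt)

    def test_shortening_at_v_max_kills_active_force(self):
        p = _params()
        v = -p.v_max * p.l_opt
        F, _, _ = mtu_force(p, CURVES, p.l_slack + p.l_opt, v, 1.0, "rigid")
        assert F == pytest.approx(p.f_max * float(CURVES.fpe(1.0)), abs=1e-9)

    def test_force_never_negative(self, rng):
        p = _params()
        for _ in range(50):
            l = rng.uniform(0.5, 1.8) * p.l_opt + p.l_slack
            v = rng.uniform(-3, 3)
            a = rng.uniform(0, 1)
            F, _, _ = mtu_force(p, CURVES, l, v, a, "rigid")
            assert F >= 0.0

    def test_elastic_matches_dense_scan(self):
        p = _params(l_slack=0.2)
        l_mt = p.l_slack * 1.02 + p.l_opt
        F, lf, _ = mtu_force(p, CURVES, l_mt, 0.0, 0.7, "elastic")
        grid = np.linspace(1e-4 * p.l_opt, l_mt - 1e-9, 40000)
        eps = (l_mt - grid) / p.l_slack - 1.0
        resid = np.abs(CURVES.ft(eps)
                       - (0.7 * CURVES.fl_active(grid / p.l_opt)
                          + CURVES.fpe(grid / p.l_opt)))
        lf_scan = grid[int(np.argmin(resid))]
        assert lf == pytest.approx(lf_scan, abs=2 * (grid[1] - grid[0]))
        assert F == pytest.approx(p.f_max * float(CURVES.ft((l_mt - lf) / p.l_slack - 1)),
                                  rel=1e-9)

    def test_elastic_isometric_close_to_f_max_with_short_tendon(self):
        p = _params(l_slack=0.05)
        F, _, _ = mtu_force(p, CURVES, p.l_slack + p.l_opt, 0.0, 1.0, "elastic")
        assert F == pytest.approx(p.f_max, rel=0.02)

    def test_rigid_and_elastic_agree_for_stiff_tendon(self):
        stiff = CurveSet(k_tendon=300.0)
        p = _params(l_slack=0.05)
        l_mt = p.l_slack + p.l_opt
        Fr, _, _ = mtu_force(p, stiff, l_mt, 0.0, 1.0, "rigid")
        Fe, _, _ = mtu_force(p, stiff, l_mt, 0.0, 1.0, "elastic")
        assert Fe == pytest.approx(Fr, rel=0.05)

    def test_activation_out_of_range(self):
        with pytest.raises(MuscleError):
            mtu_force(_params(), CURVES, 0.2, 0.0, 1.5, "rigid")


class TestCurves:
    def test_force_velocity_endpoints_and_monotonicity(self):
        v = np.linspace(-1.5, 1.5, 2001)
        f = CURVES.fv(v)
        assert CURVES.fv(-1.0) == pytest.approx(0.0, abs=1e-12)
        assert CURVES.fv(0.0) == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(f) >= -1e-12)
        assert f[-1] <= CURVES.f_ecc + 1e-9

    def test_tendon_curve_toe_then_linear_monotone(self):
        e = np.linspace(-0.01, 0.1, 2001)
        f = CURVES.ft(e)
        assert np.all(f[e <= 0] == 0.0)
        assert np.all(np.diff(f) >= 0.0)
        # linear region slope
        s = (CURVES.ft(0.09) - CURVES.ft(0.08)) / 0.01
        assert s == pytest.approx(CURVES.k_tendon, rel=1e-9)

    def test_active_force_length_vanishes_far_from_optimum(self):
        assert CURVES.fl_active(0.5) < 0.3
        assert CURVES.fl_active(1.5) < 0.3
        assert CURVES.fl_active(1.0) == pytest.approx(1.0)


class TestFiberPower:
    @pytest.mark.parametrize("F,v,P", [
        (100.0, -0.1, 10.0),   # shortening -> positive power
        (100.0, 0.0, 0.0),
        (100.0, 0.1, -10.0),   # lengthening -> negative power
    ])
    def test_sign_convention(self, F, v, P):
        assert fiber_power(F, v) == pytest.approx(P)

    def test_passive_element_conservative_over_closed_cycle(self):
        p = _params()
        T, n = 1.0, 20000
        t = np.linspace(0, T, n, endpoint=False)
        l = p.l_slack + p.l_opt * (1.1 + 0.15 * np.sin(2 * np.pi * t))
        v = np.gradient(l, t[1] - t[0])
        W = 0.0
        for li, vi in zip(l, v):
            F, _, vf = mtu_force(p, CURVES, li, vi, 0.0, "rigid")
            W += fiber_power(F, vf) * (t[1] - t[0])
        peak = p.f_max * float(CURVES.fpe(1.25)) * 0.15 * p.l_opt
        assert abs(W) < 0.01 * max(peak, 1e-6)


def test_muscle_state_validation():
    with pytest.raises(MuscleError):
        MuscleState(activation=1.5)
    with pytest.raises(MuscleError):
        MTUParams("bad", f_max=-1, l_opt=0.1, l_slack=0.1,
                  path=[("a", (0, 0, 0)), ("b", (0, 0, 1))])
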
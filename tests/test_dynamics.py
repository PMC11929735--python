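import numpy as np
import pytest

from neurorun.contact import ContactParams, contact_wrenches
from neurorun.dynamics import (GenState, IntegrationError, Kinematics,
                               bias_forces, forward_dynamics,
                               generalized_external, integrate_semi_implicit,
                               kinetic_energy, mass_matrix, potential_energy,
                               step)
from neurorun.skeleton import build_model

from oracles import ChainOracle, chain_config


def _random_chain(rng, n):
    lengths = list(0.4 + rng.uniform(0, 0.6, n))
    masses = list(0.5 + rng.uniform(0, 2.5, n))
    coms = [0.5 * L for L in lengths]
    iyy = [m * L ** 2 / 12 for m, L in zip(masses, lengths)]
    return lengths, masses, coms, iyy


class TestMassMatrix:
    def test_free_body_blockdiag(self):
        cfg = {
            "bodies": [{"name": "b", "mass": 2.5, "inertia": [0.1, 0.2, 0.3]}],
            "joints": [{"name": "root", "type": "free6", "child": "b"}],
        }
        m = build_model(cfg)
        q, u = m.default_state_arrays()
        M = mass_matrix(m, q)
        expected = np.diag([0.1, 0.2, 0.3, 2.5, 2.5, 2.5])
        assert np.allclose(M, expected, atol=1e-12)

    def test_symmetry_and_positive_definiteness(self, desk_model, rng):
        for _ in range(5):
            q, u = desk_model.default_state_arrays()
            q[7:] += rng.normal(0, 0.4, desk_model.n_q - 7)
            M = mass_matrix(desk_model, q)
            assert np.abs(M - M.T).max() < 1e-10
            assert np.linalg.eigvalsh(M).min() > 0


class TestBiasForces:
    def test_pendulum_gravity_torque(self):
        L, m = 0.8, 1.7
        cfg = chain_config([L], [m], [L], [1e-9])
        mdl = build_model(cfg)
        th = 0.37
        c = bias_forces(mdl, np.array([th]), np.zeros(1))
        assert c[0] == pytest.approx(m * 9.81 * L * np.sin(th), rel=1e-10)

    def test_zero_gravity_at_rest_gives_zero(self, rng):
        cfg = chain_config(*_random_chain(rng, 2), g=0.0)
        mdl = build_model(cfg)
        q = rng.uniform(-1, 1, 2)
        assert np.allclose(bias_forces(mdl, q, np.zeros(2)), 0.0, atol=1e-12)


class TestForwardDynamicsOracle:
    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_chain_matches_symbolic_lagrangian(self, n, rng):
        params = _random_chain(rng, n)
        oracle = ChainOracle(*params)
        mdl = build_model(chain_config(*params))
        for _ in range(25):
            q = rng.uniform(-np.pi, np.pi, n)
            u = rng.uniform(-4, 4, n)
            tau = rng.uniform(-8, 8, n)
            assert np.abs(mass_matrix(mdl, q) - oracle.M(q)).max() < 1e-8
            assert np.abs(bias_forces(mdl, q, u) - oracle.c(q, u)).max() < 1e-8
            assert np.abs(forward_dynamics(mdl, q, u, tau)
                          - oracle.qddot(q, u, tau)).max() < 1e-8

    def test_free_fall_acceleration(self):
        cfg = {
            "bodies": [{"name": "b", "mass": 3.0, "inertia": [0.1, 0.1, 0.1]}],
            "joints": [{"name": "root", "type": "free6", "child": "b"}],
            "gravity": [0, 0, -9.81],
        }
        m = build_model(cfg)
        q, u = m.default_state_arrays()
        ud = forward_dynamics(m, q, u, np.zeros(6))
        assert np.allclose(ud, [0, 0, 0, 0, 0, -9.81], atol=1e-12)

    def test_equilibrium_torque_yields_zero_acceleration(self, desk_model, rng):
        q, u = desk_model.default_state_arrays()
        q[7:] += rng.normal(0, 0.3, desk_model.n_q - 7)
        u[:] = rng.normal(0, 1.0, desk_model.n_u)
        c = bias_forces(desk_model, q, u)
        ud = forward_dynamics(desk_model, q, u, c)
        assert np.abs(ud).max() < 1e-7

    def test_wrong_tau_dimension(self, desk_model):
        q, u = desk_model.default_state_arrays()
        with pytest.raises(ValueError):
            forward_dynamics(desk_model, q, u, np.zeros(3))


class TestStep:
    def test_free_fall_kinematics(self):
        cfg = {
            "bodies": [{"name": "b", "mass": 1.0, "inertia": [0.1, 0.1, 0.1]}],
            "joints": [{"name": "root", "type": "free6", "child": "b"}],
        }
        m = build_model(cfg)
        st = GenState(*m.default_state_arrays())
        for _ in range(1000):
            st = step(m, st, np.zeros(6), dt=1e-3)
        assert st.q[6] == pytest.approx(-4.905, rel=5e-3)

    def test_zero_everything_is_a_fixed_point(self, desk_model):
        cfg = chain_config([1.0], [1.0], [0.5], [0.1], g=0.0)
        m = build_model(cfg)
        st = GenState(*m.default_state_arrays())
        st2 = step(m, st, np.zeros(m.n_u), dt=1e-2)
        assert np.array_equal(st2.q, st.q)
        assert np.array_equal(st2.u, st.u)

    def test_dt_must_be_positive(self, desk_model):
        st = GenState(*desk_model.default_state_arrays())
        with pytest.raises(ValueError):
            step(desk_model, st, np.zeros(desk_model.n_u), dt=0.0)

    def test_nonfinite_state_names_offending_coordinate(self):
        cfg = chain_config([1.0, 1.0], [1.0, 1.0], [0.5, 0.5], [0.1, 0.1])
        m = build_model(cfg)
        st = GenState(np.zeros(2), np.zeros(2))
        with pytest.raises(IntegrationError, match="j1"):
            integrate_semi_implicit(m, st, np.array([0.0, np.inf]), 1e-3)

    def test_conservative_pendulum_energy_drift(self, rng):
        params = _random_chain(rng, 2)
        mdl = build_model(chain_config(*params))
        st = GenState(np.array([0.9, -0.4]), np.array([0.0, 0.0]))
        E0 = kinetic_energy(mdl, st.q, st.u) + potential_energy(mdl, st.q)
        worst = 0.0
        for i in range(20000):  # 2 s at dt = 1e-4
            st = step(mdl, st, np.zeros(2), dt=1e-4)
            if i % 500 == 0:
                E = kinetic_energy(mdl, st.q, st.u) + potential_energy(mdl, st.q)
                worst = max(worst, abs(E - E0))
        scale = max(abs(E0), 1.0)
        assert worst / scale < 5e-3


class TestContactEquilibrium:
    def test_box_on_spheres_supports_its_weight(self):
        mass = 12.0
        cfg = {
            "bodies": [{"name": "box", "mass": mass, "inertia": [0.2, 0.2, 0.3]}],
            "joints": [{"name": "root", "type": "free6", "child": "box"}],
            "contact_spheres": [
                {"body": "box", "offset": [x, y, -0.1], "radius": 0.05,
                 "foot": "right"}
                for x, y in ((0.15, 0.1), (0.15, -0.1), (-0.15, 0.1), (-0.15, -0.1))
            ],
        }
        m = build_model(cfg)
        params = ContactParams(k_n=2e5, c_n=2.0, mu=0.9)
        st = GenState(*m.default_state_arrays())
        st.q[6] = 0.16   # spheres just above ground
        for _ in range(2000):
            kin = Kinematics(m, st.q, st.u)
            res = contact_wrenches(m, st.q, st.u, params, kin=kin)
            tau = generalized_external(m, kin, res.forces)
            ud = forward_dynamics(m, st.q, st.u, tau, kin=kin)
            st = integrate_semi_implicit(m, st, ud, 1e-3)
        res = contact_wrenches(m, st.q, st.u, params)
        total_fz = res.grf["right"][2]
        assert total_fz == pytest.approx(mass * 9.81, rel=0.01)
        assert np.abs(st.u).max() < 0.01
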
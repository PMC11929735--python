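import numpy as np
import pytest

import neurorun as nr
from neurorun.conditions import (ConditionError, apply_condition, arm_condition,
                                 warm_start)
from neurorun.controller import RewardWeights
from neurorun.dynamics import Kinematics


@pytest.fixture(scope="module")
def weights():
    return RewardWeights()


class TestApplyCondition:
    def test_active_is_identity(self, desk_model, weights):
        app = apply_condition(desk_model, weights,
                              arm_condition("active", desk_model))
        assert app.model is desk_model
        assert app.weights is weights
        assert app.enabled_muscles.all()

    def test_fixed_fullscale_drops_eight_joint_dof(self, fullscale_model, weights):
        app = apply_condition(fullscale_model, weights,
                              arm_condition("fixed", fullscale_model))
        assert fullscale_model.n_joint_dof == 25
        assert app.model.n_joint_dof == 17  # - (3+3) shoulders - (1+1) elbows

    def test_passive_fullscale_controls_92_muscles(self, fullscale_model, weights):
        app = apply_condition(fullscale_model, weights,
                              arm_condition("passive", fullscale_model))
        assert len(fullscale_model.muscles) == 150
        assert int(app.enabled_muscles.sum()) == 92
        assert app.model.n_joint_dof == 25  # skeleton untouched

    def test_mass_conserved_across_conditions(self, desk_model, weights):
        for name in ("active", "fixed", "passive"):
            app = apply_condition(desk_model, weights,
                                  arm_condition(name, desk_model))
            assert app.model.total_mass == pytest.approx(desk_model.total_mass)

    def test_fixed_reward_and_observation_shrink_consistently(self, desk_model,
                                                              weights):
        app = apply_condition(desk_model, weights,
                              arm_condition("fixed", desk_model))
        assert all(not c.startswith(("shoulder", "elbow"))
                   for c in app.model.coord_names)
        assert all(not c.startswith(("shoulder", "elbow"))
                   for c in app.weights.coord_mask)
        assert "hand_r" not in app.weights.ee_mask
        from neurorun.controller import ObservationSpec
        assert len(ObservationSpec.for_model(app.model)) == \
            22 + 2 * app.model.n_joint_dof

    def test_locking_missing_joint_raises(self, desk_model, weights):
        cond = arm_condition("fixed", desk_model)
        cond.locked_joints.append("antenna_j")
        with pytest.raises(ConditionError, match="antenna_j"):
            apply_condition(desk_model, weights, cond)

    def test_active_condition_rejects_modifications(self):
        from neurorun.conditions import ArmCondition
        with pytest.raises(ConditionError):
            ArmCondition("active", locked_joints=["shoulder_r"])


class TestFixedArmKinematics:
    def test_hands_move_rigidly_with_thorax(self, desk_cfg, rng):
        cfg = dict(desk_cfg, condition="fixed")
        exp = nr.Experiment(cfg)
        env = exp.make_env(0)
        env.reset(0.25)
        model = exp.model
        tb = model.body_index["torso"]
        hand = model.site_index["hand_r"]
        rel = []
        for _ in range(4):
            env.step(rng.uniform(0, 0.5, env.n_action))
            kin = Kinematics(model, env.state.q, env.state.u)
            world = kin.point_position(model.body_index[hand.body], hand.point)
            rel.append(kin.R[tb].T @ (world - kin.p[tb]))
        rel = np.array(rel)
        assert np.abs(rel - rel[0]).max() < 1e-9

    def test_arm_coordinates_absent_from_trajectory(self, desk_cfg):
        cfg = dict(desk_cfg, condition="fixed")
        exp = nr.Experiment(cfg)
        assert not any(c.startswith(("shoulder", "elbow"))
                       for c in exp.model.coord_names)


class TestPassiveArms:
    def test_disabled_muscles_stay_silent_through_rollout(self, desk_cfg):
        from neurorun.envsim import rollout
        from neurorun.nets import Controller
        cfg = dict(desk_cfg, condition="passive")
        exp = nr.Experiment(cfg)
        env = exp.make_env(0)
        labels, names = exp.controller_labels()
        ctrl = Controller.create(labels, names, hidden=[16], seed=0)
        traj = rollout(env, ctrl, duration=0.5)
        disabled = ~exp.enabled
        assert np.all(traj.excitations[:, disabled] == 0.0)
        assert np.all(traj.activations[:, disabled] == 0.0)
        # enabled muscles do activate
        assert traj.activations[:, exp.enabled].max() > 0.0

    def test_masked_arm_error_does_not_change_reward(self, desk_cfg):
        import dataclasses
        from neurorun.controller import tracking_reward
        cfg = dict(desk_cfg, condition="passive")
        exp = nr.Experiment(cfg)
        model, ref = exp.model, exp.reference
        # COM tracking is deliberately not masked (arm mass moves the COM);
        # zero its weight to isolate the masked angle/end-effector terms
        w = dataclasses.replace(exp.weights, w_com=0.0)
        tab = ref.tables(model)
        phi = tab["phases"][9]
        st = ref.gen_state(model, phi * ref.cycle_T)
        r0 = tracking_reward(model, st, ref, w, phi * ref.cycle_T)
        st.q[model.q_coord_index("shoulder_r_y")] += 1.0
        st.q[model.q_coord_index("elbow_l")] -= 0.8
        r1 = tracking_reward(model, st, ref, w, phi * ref.cycle_T)
        assert r1 == pytest.approx(r0, abs=1e-12)


class TestWarmStart:
    def test_surviving_parameters_copied_bitwise(self):
        from neurorun.nets import Controller
        ref = Controller.create(["a", "b", "c"], ["m1", "m2", "m3"],
                                hidden=[8, 8], seed=5)
        ctrl = warm_start(ref, ["a", "c"], ["m1", "m3"])
        assert np.array_equal(ctrl.policy.mlp.W[0][0], ref.policy.mlp.W[0][0])
        assert np.array_equal(ctrl.policy.mlp.W[0][1], ref.policy.mlp.W[0][2])
        assert np.array_equal(ctrl.policy.mlp.W[1], ref.policy.mlp.W[1])
        assert np.array_equal(ctrl.policy.mlp.W[-1][:, 1], ref.policy.mlp.W[-1][:, 2])
        assert np.array_equal(ctrl.policy.log_std,
                              ref.policy.log_std[[0, 2]])

    def test_identical_layout_warm_start_is_exact_copy(self):
        from neurorun.nets import Controller
        ref = Controller.create(["a", "b"], ["m1", "m2"], hidden=[8], seed=2)
        ctrl = warm_start(ref, ["a", "b"], ["m1", "m2"])
        assert ctrl.params_equal(ref)
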
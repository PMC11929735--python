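"""Arm-condition variants: active swing, fixed (crossed) arms, passive arms.

* ``active`` — the unmodified model and reward.
* ``fixed`` — shoulder and elbow joints are welded (DOF removed) at a
  crossed-arm pose in front of the chest; the reward drops upper-limb
  coordinates and hand end-effectors.  Welding (rather than stiff springs)
  makes the condition literally effort-free to maintain.
* ``passive`` — the skeleton is unchanged but every upper-limb-group muscle
  receives zero excitation for the whole simulation; passive muscle/tendon
  forces and joint-limit torques still act, which is what makes a passive
  swing nontrivial.  The reward mask matches the fixed condition.

Retraining warm-starts a condition controller from the reference (active)
controller by copying every parameter whose observation/muscle label
survives the condition.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ._math import euler_zxy_to_mat, mat_to_euler_zxy, rot_axis_angle
from .controller import RewardWeights
from .nets import Controller
from .skeleton import SkeletonModel, build_model

CONDITIONS = ("active", "fixed", "passive")

# crossed-arm pose in front of the chest: shoulder flexion 60 deg,
# adduction 20 deg, elbow flexion 120 deg
DEFAULT_LOCKED_POSE = {"shoulder_flexion": 60.0, "shoulder_adduction": 20.0,
                       "elbow_flexion": 120.0}


class ConditionError(ValueError):
    pass


@dataclass
class ArmCondition:
    name: str
    locked_joints: list[str] = field(default_factory=list)        # fixed only
    locked_pose: dict[str, float] = field(default_factory=dict)   # deg, fixed only
    disabled_muscles: list[str] = field(default_factory=list)     # passive only
    reward_exclusions: tuple[list[str], list[str]] = ((), ())     # (coords, sites)

    def __post_init__(self) -> None:
        if self.name not in CONDITIONS:
            raise ConditionError(f"unknown condition {self.name!r}")
        if self.name == "active" and (self.locked_joints or self.disabled_muscles):
            raise ConditionError("active condition must have no modifications")


def _arm_joint_names(model: SkeletonModel) -> list[str]:
    return [j.name for j in model.joints
            if j.name.startswith(("shoulder_", "elbow_"))]


def _arm_coord_names(model: SkeletonModel) -> list[str]:
    return [c for c in model.coord_names
            if c.startswith(("shoulder_", "elbow_"))]


def arm_condition(name: str, model: SkeletonModel,
                  locked_pose: dict[str, float] | None = None) -> ArmCondition:
    """Build the condition descriptor for a given model."""
    if name == "active":
        return ArmCondition("active")
    excl = (_arm_coord_names(model),
            [s.name for s in model.sites if s.name.startswith("hand_")])
    if name == "fixed":
        return ArmCondition("fixed", locked_joints=_arm_joint_names(model),
                            locked_pose=dict(locked_pose or DEFAULT_LOCKED_POSE),
                            reward_exclusions=excl)
    if name == "passive":
        disabled = [m["name"] for m in model.muscles if m.get("group") == "upper_limb"]
        return ArmCondition("passive", disabled_muscles=disabled,
                            reward_exclusions=excl)
    raise ConditionError(f"unknown condition {name!r}")


@dataclass
class ConditionApplication:
    condition: ArmCondition
    model: SkeletonModel
    weights: RewardWeights
    enabled_muscles: np.ndarray        # bool mask over the model muscle list


def _locked_joint_angles(jname: str, jtype: str, pose: dict[str, float]) -> np.ndarray | float:
    side = jname.rsplit("_", 1)[-1]
    medial = 1.0 if side == "r" else -1.0
    if jname.startswith("shoulder"):
        flex = np.deg2rad(pose.get("shoulder_flexion", 60.0))
        add = np.deg2rad(pose.get("shoulder_adduction", 20.0))
        # ZXY triplet: flexion forward is -Y, adduction is signed X
        return np.array([0.0, medial * add, -flex])
    if jname.startswith("elbow"):
        return np.deg2rad(pose.get("elbow_flexion", 120.0))
    raise ConditionError(f"no locked pose rule for joint {jname!r}")


def apply_condition(model: SkeletonModel, weights: RewardWeights,
                    condition: ArmCondition) -> ConditionApplication:
    """Produce the modified model/reward/excitation mask for a condition.

    Fixed: locked joints become welds with the crossed-arm rotation folded
    into the fixed parent->joint transform; the coordinate map and the
    observation shrink accordingly.  Passive: the listed muscles are removed
    from the excitation-controlled set (mask False) but keep exerting
    passive force.  Total model mass is unchanged in all conditions.
    """
    if condition.name == "active":
        enabled = np.ones(len(model.muscles), dtype=bool)
        return ConditionApplication(condition, model, weights, enabled)

    new_model = model
    if condition.locked_joints:
        known = {j.name for j in model.joints}
        for jn in condition.locked_joints:
            if jn not in known:
                raise ConditionError(f"cannot lock joint {jn!r}: not in model")
        cfg = copy.deepcopy(model.source_config)
        for j in cfg["joints"]:
            if j["name"] not in condition.locked_joints:
                continue
            R_fix = euler_zxy_to_mat(np.deg2rad(np.asarray(
                j.get("rotation_zxy_deg", [0, 0, 0]), dtype=float)))
            ang = _locked_joint_angles(j["name"], j["type"], condition.locked_pose)
            if j["type"] == "spherical3":
                R_lock = euler_zxy_to_mat(np.asarray(ang))
            elif j["type"] == "revolute1":
                R_lock = rot_axis_angle(np.asarray(j["axis"], float), float(ang))
            else:
                raise ConditionError(f"cannot lock joint type {j['type']!r}")
            j["type"] = "weld0"
            j.pop("axis", None)
            j.pop("limits_deg", None)
            j["rotation_zxy_deg"] = list(np.rad2deg(mat_to_euler_zxy(R_fix @ R_lock)))
        new_model = build_model(cfg)

    excl_coords, excl_sites = condition.reward_exclusions
    coord_mask = [c for c in new_model.coord_names if c not in excl_coords]
    ee_mask = [s.name for s in new_model.sites if s.name not in excl_sites]
    new_weights = copy.replace(weights, coord_mask=coord_mask, ee_mask=ee_mask) \
        if hasattr(copy, "replace") else _replace_weights(weights, coord_mask, ee_mask)

    disabled = set(condition.disabled_muscles)
    unknown = disabled - {m["name"] for m in new_model.muscles}
    if unknown:
        raise ConditionError("unknown muscles to disable: " + ", ".join(sorted(unknown)))
    enabled = np.array([m["name"] not in disabled for m in new_model.muscles])
    return ConditionApplication(condition, new_model, new_weights, enabled)


def _replace_weights(w: RewardWeights, coord_mask, ee_mask) -> RewardWeights:
    import dataclasses
    return dataclasses.replace(w, coord_mask=coord_mask, ee_mask=ee_mask)


def warm_start(reference: Controller, obs_labels: list[str],
               muscle_names: list[str]) -> Controller:
    """Build a condition controller initialized from the reference controller.

    Parameters are copied wherever shapes and labels allow: input-layer rows
    are matched by observation label, output-layer columns (and log-std
    entries) by muscle name; hidden layers and the value network are copied
    when the hidden architecture matches, otherwise the new controller keeps
    its fresh initialization for the mismatched parts.
    """
    hidden = reference.policy.mlp.sizes[1:-1]
    ctrl = Controller.create(obs_labels, muscle_names, hidden=hidden,
                             meta=dict(reference.meta))
    obs_map = {lab: i for i, lab in enumerate(reference.obs_labels)}
    mus_map = {nm: i for i, nm in enumerate(reference.muscle_names)}
    obs_src = [obs_map.get(lab, -1) for lab in obs_labels]
    mus_src = [mus_map.get(nm, -1) for nm in muscle_names]

    def copy_input_rows(dst: np.ndarray, src: np.ndarray) -> None:
        for i, si in enumerate(obs_src):
            if si >= 0:
                dst[i, :] = src[si, :]

    # policy
    pm, rm = ctrl.policy.mlp, reference.policy.mlp
    if pm.sizes[1:-1] == rm.sizes[1:-1]:
        copy_input_rows(pm.W[0], rm.W[0])
        pm.b[0][:] = rm.b[0]
        for i in range(1, len(pm.W) - 1):
            pm.W[i][:] = rm.W[i]
            pm.b[i][:] = rm.b[i]
        for j, sj in enumerate(mus_src):
            if sj >= 0:
                pm.W[-1][:, j] = rm.W[-1][:, sj]
                pm.b[-1][j] = rm.b[-1][sj]
                ctrl.policy.log_std[j] = reference.policy.log_std[sj]
    # value
    vm, rv = ctrl.value, reference.value
    if vm.sizes[1:-1] == rv.sizes[1:-1]:
        copy_input_rows(vm.W[0], rv.W[0])
        vm.b[0][:] = rv.b[0]
        for i in range(1, len(vm.W)):
            vm.W[i][:] = rv.W[i]
            vm.b[i][:] = rv.b[i]
    return ctrl


def retrain(reference_controller: Controller, make_env, ppo_config,
            log=None):
    """Warm-start from the reference controller and train in the modified
    environment.  With ``n_updates == 0`` on the active condition this
    returns a controller identical to the reference."""
    from .rl import train
    probe = make_env(0)
    obs_labels = probe.obs_spec.labels()
    muscle_names = [n for n, on in zip(probe.muscles.names, probe.enabled) if on]
    # with an identical layout the warm start is an exact parameter copy
    ctrl = warm_start(reference_controller, obs_labels, muscle_names)
    return train(make_env, ctrl, ppo_config, log=log)
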
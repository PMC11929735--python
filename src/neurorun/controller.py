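"""Controller-facing observation construction and imitation reward.

The observation mirrors the dynamic-state layout used by the running
controller: pelvis orientation (3 ZXY Euler angles), pelvis rotational and
translational velocity (6, pelvis frame), pelvis height (1), joint angular
positions and velocities (n_j each), then per-foot ground reaction force and
center of pressure (3 each, right then left) expressed in the pelvis frame —
22 + 2 n_j values in total (72 for the full 25-joint-DOF model).

The reward is the sum of a motion-tracking score and a muscle-activation
score.  Tracking combines four exponentiated negative squared errors (joint
angles, joint angular velocities, whole-body COM position, end-effector
positions of feet/hands/head); the activation score decreases with the mean
squared muscle activation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._math import mat_to_euler_zxy
from .dynamics import GenState, Kinematics
from .reference import ReferenceMotion
from .skeleton import SkeletonModel

FEET = ("right", "left")


class ObservationError(ValueError):
    """Non-finite value encountered while building an observation."""


@dataclass
class ObservationSpec:
    """Component layout + per-component normalization scales."""
    coord_names: list[str]
    scale_angvel: float = 10.0     # rad/s
    scale_linvel: float = 5.0      # m/s
    scale_qdot: float = 10.0       # rad/s
    scale_grf: float = 650.0       # N (about one body weight)
    scale_cop: float = 1.0         # m

    @classmethod
    def for_model(cls, model: SkeletonModel) -> "ObservationSpec":
        return cls(coord_names=list(model.coord_names))

    @property
    def n_joint(self) -> int:
        return len(self.coord_names)

    def __len__(self) -> int:
        return 22 + 2 * self.n_joint

    def labels(self) -> list[str]:
        lab = ["pelvis_rz", "pelvis_rx", "pelvis_ry",
               "wx", "wy", "wz", "vx", "vy", "vz", "height"]
        lab += [f"q:{n}" for n in self.coord_names]
        lab += [f"u:{n}" for n in self.coord_names]
        for foot in FEET:
            lab += [f"grf:{foot}:{ax}" for ax in "xyz"]
        for foot in FEET:
            lab += [f"cop:{foot}:{ax}" for ax in "xyz"]
        return lab


def build_observation(model: SkeletonModel, state: GenState,
                      grf: dict[str, np.ndarray], cop: dict[str, np.ndarray],
                      spec: ObservationSpec,
                      kin: Kinematics | None = None) -> np.ndarray:
    """Assemble the controller observation vector (length 22 + 2 n_j).

    GRF and CoP are rotated into the pelvis frame (CoP additionally taken
    relative to the pelvis origin); a foot with zero GRF contributes zeros.
    Raises :class:`ObservationError` naming the first non-finite component.
    """
    kin = kin or Kinematics(model, state.q, state.u)
    rb = model._root_body
    Rp = kin.R[rb]
    pp = kin.p[rb]

    parts = [
        mat_to_euler_zxy(Rp),
        (Rp.T @ state.u[0:3]) / spec.scale_angvel,
        (Rp.T @ state.u[3:6]) / spec.scale_linvel,
        np.array([state.q[6]]),
        state.q[7:7 + spec.n_joint],
        state.u[6:6 + spec.n_joint] / spec.scale_qdot,
    ]
    for foot in FEET:
        parts.append((Rp.T @ grf.get(foot, np.zeros(3))) / spec.scale_grf)
    for foot in FEET:
        f = grf.get(foot, np.zeros(3))
        c = cop.get(foot, np.zeros(3))
        if np.linalg.norm(f) > 1e-9:
            parts.append((Rp.T @ (c - pp)) / spec.scale_cop)
        else:
            parts.append(np.zeros(3))
    obs = np.concatenate(parts)
    if not np.all(np.isfinite(obs)):
        bad = int(np.flatnonzero(~np.isfinite(obs))[0])
        raise ObservationError(f"non-finite observation component {spec.labels()[bad]!r}")
    return obs


@dataclass
class RewardWeights:
    """Imitation reward scales; masked terms contribute exactly zero."""
    w_q: float = 0.65
    w_qdot: float = 0.1
    w_com: float = 0.1
    w_ee: float = 0.15
    w_act: float = 0.2
    sigma_q: float = 0.3       # rad
    sigma_qdot: float = 3.0    # rad/s
    sigma_com: float = 0.2     # m
    sigma_ee: float = 0.2      # m
    coord_mask: list[str] | None = None   # None = all model joint coordinates
    ee_mask: list[str] | None = None      # None = all model sites

    def __post_init__(self) -> None:
        if min(self.sigma_q, self.sigma_qdot, self.sigma_com, self.sigma_ee) <= 0:
            raise ValueError("error scales must be > 0")

    @property
    def max_reward(self) -> float:
        return self.w_q + self.w_qdot + self.w_com + self.w_ee + self.w_act


def _wrap(x: np.ndarray) -> np.ndarray:
    return (x + np.pi) % (2 * np.pi) - np.pi


def tracking_reward(model: SkeletonModel, state: GenState,
                    reference: ReferenceMotion, weights: RewardWeights,
                    t_ref: float, kin: Kinematics | None = None) -> float:
    """Motion-tracking score at reference time ``t_ref``: the weighted sum of
    exponentiated negative squared errors in joint angles, joint velocities,
    COM position and end-effector positions.  Maximal (= sum of the four
    weights) when the state lies exactly on the reference."""
    kin = kin or Kinematics(model, state.q, state.u)
    tab = reference.tables(model)
    phi = reference.phase(t_ref)
    i = int(phi * tab["n"]) % tab["n"]

    coords = weights.coord_mask if weights.coord_mask is not None else model.coord_names
    idx = np.array([model.coord_index[c] for c in coords], dtype=int)
    if idx.size:
        dq = _wrap(state.q[1 + idx] - tab["qjoint"][i][idx - 6])
        du = state.u[idx] - tab["ujoint"][i][idx - 6]
        r_q = weights.w_q * np.exp(-float(dq @ dq) / weights.sigma_q ** 2)
        r_qdot = weights.w_qdot * np.exp(-float(du @ du) / weights.sigma_qdot ** 2)
    else:
        r_q = weights.w_q
        r_qdot = weights.w_qdot

    drift = np.array([reference.speed * t_ref, 0.0, 0.0])
    dcom = kin.com() - (tab["com"][i] + drift)
    r_com = weights.w_com * np.exp(-float(dcom @ dcom) / weights.sigma_com ** 2)

    sites = weights.ee_mask if weights.ee_mask is not None else [s.name for s in model.sites]
    err2 = 0.0
    for name in sites:
        s = model.site_index[name]
        pos = kin.point_position(model.body_index[s.body], s.point)
        d = pos - (tab["sites"][name][i] + drift)
        err2 += float(d @ d)
    r_ee = weights.w_ee * np.exp(-err2 / weights.sigma_ee ** 2)
    return float(r_q + r_qdot + r_com + r_ee)


def activation_reward(activations: np.ndarray, weights: RewardWeights) -> float:
    """Activation score w_act * exp(-mean(a^2)); maximal at rest, strictly
    decreasing in every activation."""
    a = np.asarray(activations, dtype=float)
    if a.size == 0:
        return weights.w_act
    return float(weights.w_act * np.exp(-float(a @ a) / a.size))


def total_reward(model: SkeletonModel, state: GenState, activations: np.ndarray,
                 reference: ReferenceMotion, weights: RewardWeights,
                 t_ref: float, kin: Kinematics | None = None) -> float:
    """Sum of motion-tracking and activation scores."""
    return (tracking_reward(model, state, reference, weights, t_ref, kin=kin)
            + activation_reward(activations, weights))
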
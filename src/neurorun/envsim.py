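"""Muscle-driven running environment: physics stepping at the control rate.

One control step holds the commanded excitations (zero-order hold), advances
the physics ``substeps`` times with semi-implicit Euler, accumulates
per-muscle fiber work, and returns the observation and imitation reward.
Episodes start from reference states at a (random or given) stride phase and
terminate when the pelvis drops below a fraction of its reference height or
the torso tilts past a threshold.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact import ContactParams, contact_wrenches
from .controller import (ObservationSpec, RewardWeights, activation_reward,
                         build_observation, tracking_reward)
from .dynamics import (GenState, IntegrationError, Kinematics, dynamics_terms,
                       generalized_external, integrate_semi_implicit)
from .muscle import MuscleSystem
from .reference import ReferenceMotion
from .skeleton import SkeletonModel
from .trajlog import TrajectoryLog


@dataclass
class SimParams:
    dt: float = 1e-3                 # physics timestep, s
    substeps: int = 33               # physics substeps per control step
    joint_damping: float = 0.5      # N m s/rad, all joint DOF
    limit_stiffness: float = 50.0    # N m/rad outside a joint limit
    limit_damping: float = 2.0       # extra damping inside the limit violation

    @property
    def control_dt(self) -> float:
        return self.dt * self.substeps


@dataclass
class Termination:
    min_height_frac: float = 0.6     # pelvis height fraction of reference
    max_tilt_deg: float = 60.0       # torso pitch/roll threshold


class RunningEnv:
    """Forward-dynamics imitation environment for one musculoskeletal model."""

    def __init__(self, model: SkeletonModel, muscles: MuscleSystem,
                 reference: ReferenceMotion, weights: RewardWeights,
                 contact: ContactParams | None = None,
                 sim: SimParams | None = None,
                 termination: Termination | None = None,
                 enabled_muscles: np.ndarray | None = None,
                 episode_length: float = 4.0,
                 seed: int = 0):
        self.model = model
        self.muscles = muscles
        self.reference = reference
        self.weights = weights
        self.contact = contact or ContactParams()
        self.sim = sim or SimParams()
        self.termination = termination or Termination()
        self.obs_spec = ObservationSpec.for_model(model)
        self.enabled = (np.ones(muscles.n, dtype=bool)
                        if enabled_muscles is None else np.asarray(enabled_muscles, bool))
        self.episode_length = episode_length
        self.rng = np.random.default_rng(seed)
        self._torso_body = model.body_index.get("torso", model._root_body)

        # joint limit arrays
        lo = np.full(model.n_joint_dof, -np.inf)
        hi = np.full(model.n_joint_dof, np.inf)
        for k, lim in enumerate(model.coord_limits):
            if lim is not None:
                lo[k], hi[k] = lim
        self._lim_lo, self._lim_hi = lo, hi

        self.state: GenState | None = None
        self.activations = np.zeros(muscles.n)
        self._t_ref0 = 0.0
        self._ep_time = 0.0

    # -- episode management ---------------------------------------------
    @property
    def n_action(self) -> int:
        return int(self.enabled.sum())

    def reset(self, phase: float | None = None) -> np.ndarray:
        if phase is None:
            phase = float(self.rng.uniform())
        t_ref = phase * self.reference.cycle_T
        self.state = self.reference.gen_state(self.model, t_ref)
        self.state.t = 0.0
        self._t_ref0 = t_ref
        self._ep_time = 0.0
        self.activations = np.where(self.enabled, 0.02, 0.0)
        kin = Kinematics(self.model, self.state.q, self.state.u)
        res = contact_wrenches(self.model, self.state.q, self.state.u,
                               self.contact, kin=kin)
        self._last = (kin, res)
        self._cached_obs = build_observation(self.model, self.state, res.grf,
                                             res.cop, self.obs_spec, kin=kin)
        return self._cached_obs

    def _passive_torques(self, q: np.ndarray, u: np.ndarray) -> np.ndarray:
        s = self.sim
        qj = q[7:]
        uj = u[6:]
        tau = -s.joint_damping * uj
        over = qj - self._lim_hi
        under = self._lim_lo - qj
        tau -= np.where(over > 0, s.limit_stiffness * over + s.limit_damping * uj, 0.0)
        tau += np.where(under > 0, s.limit_stiffness * under - s.limit_damping * uj, 0.0)
        out = np.zeros_like(u)
        out[6:] = tau
        return out

    _U_GUARD = 500.0   # rad/s or m/s: beyond this the step is declared blown up

    def _substep(self, excitation_full: np.ndarray) -> None:
        m, s = self.model, self.sim
        st = self.state
        if np.abs(st.u).max() > self._U_GUARD:
            raise IntegrationError(
                f"generalized velocity exceeded {self._U_GUARD} at t={st.t:.4g}s")
        kin = Kinematics(m, st.q, st.u)
        self.activations = self.muscles.step_activation(
            self.activations, excitation_full, s.dt)
        l_mt, v_mt = self.muscles.geometry(kin)
        F, _, v_f = self.muscles.rigid_forces(l_mt, v_mt, self.activations)
        tau = self.muscles.project(kin, F)
        tau += self._passive_torques(st.q, st.u)
        res = contact_wrenches(m, st.q, st.u, self.contact, kin=kin)
        if res.forces:
            tau += generalized_external(m, kin, res.forces)
        M, c = dynamics_terms(m, kin)
        udot = np.linalg.solve(M, tau - c)
        self.state = integrate_semi_implicit(m, st, udot, s.dt)
        # fiber work at the physics rate
        P = -F * v_f
        dW = P * s.dt
        self._wpos += np.where(dW > 0, dW, 0.0)
        self._wneg += np.where(dW < 0, dW, 0.0)
        self._last_power = P

    def step(self, action: np.ndarray):
        """Advance one control step.

        ``action``: excitations in [0,1] for the enabled muscles.  Returns
        ``(obs, reward, done, info)``; ``info`` carries GRF/CoP, reward
        terms, fiber powers and the fall flag.
        """
        assert self.state is not None, "call reset() first"
        exc = np.zeros(self.muscles.n)
        exc[self.enabled] = np.clip(np.asarray(action, float).ravel(), 0.0, 1.0)
        self._wpos = getattr(self, "_wpos", np.zeros(self.muscles.n))
        self._wneg = getattr(self, "_wneg", np.zeros(self.muscles.n))
        try:
            for _ in range(self.sim.substeps):
                self._substep(exc)
        except IntegrationError:
            # numerical blow-up (post-fall tangling): truncate with zero
            # reward; the observation from the last good boundary is reused
            _, res = self._last
            info = {"grf": res.grf, "cop": res.cop, "fell": True, "timeout": False,
                    "blowup": True, "r_track": 0.0, "r_act": 0.0,
                    "fiber_power": np.zeros(self.muscles.n),
                    "excitations": exc, "activations": self.activations.copy(),
                    "speed": 0.0}
            return self._cached_obs, 0.0, True, info
        self._ep_time += self.sim.control_dt

        kin = Kinematics(self.model, self.state.q, self.state.u)
        res = contact_wrenches(self.model, self.state.q, self.state.u,
                               self.contact, kin=kin)
        self._last = (kin, res)
        t_ref = self._t_ref0 + self.state.t
        r_track = tracking_reward(self.model, self.state, self.reference,
                                  self.weights, t_ref, kin=kin)
        r_act = activation_reward(self.activations[self.enabled], self.weights)
        reward = r_track + r_act

        fell = self._check_fall(kin, t_ref)
        timeout = self._ep_time >= self.episode_length - 1e-9
        done = fell or timeout
        obs = build_observation(self.model, self.state, res.grf, res.cop,
                                self.obs_spec, kin=kin)
        self._cached_obs = obs
        info = {"grf": res.grf, "cop": res.cop, "fell": fell, "timeout": timeout,
                "r_track": r_track, "r_act": r_act,
                "fiber_power": getattr(self, "_last_power", np.zeros(self.muscles.n)),
                "excitations": exc, "activations": self.activations.copy(),
                "speed": float(self.state.u[3])}
        return obs, reward, done, info

    def _check_fall(self, kin: Kinematics, t_ref: float) -> bool:
        ref_h = float(self.reference.pelvis_z.value(self.reference.phase(t_ref)))
        if self.state.q[6] < self.termination.min_height_frac * ref_h:
            return True
        tilt = np.degrees(np.arccos(np.clip(kin.R[self._torso_body][2, 2], -1, 1)))
        return tilt > self.termination.max_tilt_deg

    # -- work ledger access ----------------------------------------------
    def reset_work(self) -> None:
        self._wpos = np.zeros(self.muscles.n)
        self._wneg = np.zeros(self.muscles.n)

    @property
    def work(self) -> tuple[np.ndarray, np.ndarray]:
        return (getattr(self, "_wpos", np.zeros(self.muscles.n)),
                getattr(self, "_wneg", np.zeros(self.muscles.n)))


def rollout(env: RunningEnv, controller, duration: float,
            start_phase: float = 0.0) -> TrajectoryLog:
    """Deterministic evaluation rollout (mean policy action).

    The log is sampled at the control rate; if the model falls before
    ``duration`` the log is truncated and flagged.
    """
    obs = env.reset(phase=start_phase)
    env.reset_work()
    n_steps = int(round(duration / env.sim.control_dt))
    m = env.muscles.n
    times = [0.0]
    qs, us = [env.state.q.copy()], [env.state.u.copy()]
    exc_log, act_log, pow_log, rew_log = [], [], [], []
    grf_log = {"right": [], "left": []}
    cop_log = {"right": [], "left": []}
    fell = False
    for _ in range(n_steps):
        a = controller.policy.mean_action(obs[None, :])[0]
        obs, r, done, info = env.step(a)
        times.append(env.state.t)
        qs.append(env.state.q.copy())
        us.append(env.state.u.copy())
        exc_log.append(info["excitations"])
        act_log.append(info["activations"])
        pow_log.append(info["fiber_power"])
        rew_log.append(r)
        for foot in ("right", "left"):
            grf_log[foot].append(info["grf"].get(foot, np.zeros(3)))
            cop_log[foot].append(info["cop"].get(foot, np.zeros(3)))
        if info["fell"]:
            fell = True
            break
    wpos, wneg = env.work
    T = len(rew_log)
    return TrajectoryLog(
        dt_control=env.sim.control_dt,
        times=np.array(times), q=np.array(qs), u=np.array(us),
        excitations=np.array(exc_log).reshape(T, m),
        activations=np.array(act_log).reshape(T, m),
        grf={f: np.array(v).reshape(T, 3) for f, v in grf_log.items()},
        cop={f: np.array(v).reshape(T, 3) for f, v in cop_log.items()},
        rewards=np.array(rew_log),
        fiber_power=np.array(pow_log).reshape(T, m),
        work_pos=wpos.copy(), work_neg=wneg.copy(),
        muscle_names=list(env.muscles.names),
        muscle_groups=[("upper_limb", "torso", "lower_limb")[g] for g in env.muscles.groups],
        coord_names=list(env.model.coord_names),
        total_mass=env.model.total_mass,
        fell=fell,
        meta={"start_phase": start_phase},
    )
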
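"""Generalized-coordinate rigid-body dynamics with a floating base.

The equations of motion are assembled densely from body Jacobians:

    M(q) u' = tau - c(q, u) + sum_k J_k^T f_k

with ``M`` from the mass/inertia-weighted Gauss pseudo-inertia sum, and the
bias vector ``c`` (Coriolis, centrifugal and gravity) from the body bias
accelerations obtained by a velocity recursion with ``u' = 0``.  For the model
sizes this package targets (tens of DOF) the dense assembly is simpler than a
propagated articulated-body algorithm and comfortably fast.

Time stepping is semi-implicit (symplectic) Euler: velocities advance first,
positions advance with the new velocities; the base quaternion is advanced on
the unit sphere with the exact exponential map.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._math import cross3, cross_rows, quat_integrate, quat_to_mat, rot_axis_angle, skew
from .skeleton import SkeletonModel


class IntegrationError(RuntimeError):
    """Simulation state became non-finite."""


class SingularMassMatrixError(np.linalg.LinAlgError):
    """Mass matrix could not be factorized."""


@dataclass
class GenState:
    """Generalized state: positions ``q``, velocities ``u``, time ``t``."""
    q: np.ndarray
    u: np.ndarray
    t: float = 0.0

    def copy(self) -> "GenState":
        return GenState(self.q.copy(), self.u.copy(), self.t)


@dataclass
class ExternalForce:
    """A world-frame force applied at a world-frame point on a body, plus an
    optional pure torque."""
    body: int                      # body index
    force: np.ndarray              # N, world frame
    point: np.ndarray              # m, world frame
    torque: np.ndarray | None = None


class Kinematics:
    """Per-state forward-kinematics cache.

    Holds, for every body: world rotation ``R``, frame-origin position ``p``,
    angular velocity ``w``, origin linear velocity ``v``, and the bias
    (zero-``u'``) angular/linear accelerations ``alpha0``/``a0``; for every
    joint DOF: the world axis ``axis_w`` and anchor point ``axis_p``.
    """

    __slots__ = ("model", "R", "p", "w", "v", "alpha0", "a0", "axis_w", "axis_p")

    def __init__(self, model: SkeletonModel, q: np.ndarray, u: np.ndarray):
        nb = len(model.bodies)
        nd = model.n_joint_dof
        self.model = model
        self.R = np.empty((nb, 3, 3))
        self.p = np.empty((nb, 3))
        self.w = np.empty((nb, 3))
        self.v = np.empty((nb, 3))
        self.alpha0 = np.empty((nb, 3))
        self.a0 = np.empty((nb, 3))
        self.axis_w = np.empty((nd, 3))
        self.axis_p = np.empty((nd, 3))

        uoff, qshift = model.u_offset, model._qu_shift
        zero3 = np.zeros(3)
        for bi in model.topo_order:
            cb = model.compiled[bi]
            if cb.parent < 0 and model.floating_base:
                self.R[bi] = quat_to_mat(q[0:4]) @ cb.R_fix
                self.p[bi] = q[4:7]
                self.w[bi] = u[0:3]
                self.v[bi] = u[3:6]
                self.alpha0[bi] = 0.0
                self.a0[bi] = 0.0
                continue
            pi = cb.parent
            if pi >= 0:
                Rp, pp, wp = self.R[pi], self.p[pi], self.w[pi]
                vp, alphap, ap = self.v[pi], self.alpha0[pi], self.a0[pi]
            else:  # world-anchored chain root
                Rp, pp, wp = np.eye(3), zero3, zero3
                vp, alphap, ap = zero3, zero3, zero3
            r = Rp @ cb.t_fix
            pj = pp + r
            Rcur = Rp @ cb.R_fix
            wcur = wp.copy()
            alpha = alphap.copy()
            aj = ap + cross3(alphap, r) + cross3(wp, cross3(wp, r))
            for k, ax in enumerate(cb.axes):
                d = cb.u_start + k
                wk = Rcur @ ax
                uk = u[d]
                self.axis_w[d - uoff] = wk
                self.axis_p[d - uoff] = pj
                alpha = alpha + uk * cross3(wcur, wk)
                wcur = wcur + uk * wk
                Rcur = Rcur @ rot_axis_angle(ax, q[qshift + d])
            self.R[bi] = Rcur
            self.p[bi] = pj
            self.w[bi] = wcur
            self.v[bi] = vp + cross3(wp, r)
            self.alpha0[bi] = alpha
            self.a0[bi] = aj

    # -- Jacobians ------------------------------------------------------
    def point_jacobian(self, body: int, x_world: np.ndarray) -> np.ndarray:
        """3 x n_u Jacobian of a world point fixed to ``body``."""
        m = self.model
        J = np.zeros((3, m.n_u))
        if m.floating_base:
            r = x_world - self.p[m._root_body]
            # base angular columns: e_j x r, i.e. -skew(r)
            J[0, 1], J[0, 2] = r[2], -r[1]
            J[1, 0], J[1, 2] = -r[2], r[0]
            J[2, 0], J[2, 1] = r[1], -r[0]
            J[0, 3] = J[1, 4] = J[2, 5] = 1.0
        dofs = m.supports[body]
        if dofs.size:
            J[:, dofs] = cross_rows(self.axis_w[dofs - m.u_offset],
                                    x_world - self.axis_p[dofs - m.u_offset]).T
        return J

    def rotation_jacobian(self, body: int) -> np.ndarray:
        """3 x n_u Jacobian of the body angular velocity."""
        m = self.model
        J = np.zeros((3, m.n_u))
        if m.floating_base:
            J[0, 0] = J[1, 1] = J[2, 2] = 1.0
        dofs = m.supports[body]
        if dofs.size:
            J[:, dofs] = self.axis_w[dofs - m.u_offset].T
        return J

    def point_position(self, body: int, local: np.ndarray) -> np.ndarray:
        return self.p[body] + self.R[body] @ local

    def point_velocity(self, body: int, x_world: np.ndarray) -> np.ndarray:
        return self.v[body] + cross3(self.w[body], x_world - self.p[body])

    def com(self) -> np.ndarray:
        m = self.model
        c = self.p + np.einsum("bij,bj->bi", self.R, m.com_offsets)
        return (m.masses[:, None] * c).sum(axis=0) / m.total_mass

    def com_velocity(self) -> np.ndarray:
        m = self.model
        r = np.einsum("bij,bj->bi", self.R, m.com_offsets)
        vc = self.v + cross_rows(self.w, r)
        return (m.masses[:, None] * vc).sum(axis=0) / m.total_mass


def mass_matrix(model: SkeletonModel, q: np.ndarray,
                kin: Kinematics | None = None, u: np.ndarray | None = None) -> np.ndarray:
    """Joint-space mass matrix (symmetric positive definite)."""
    kin = kin or Kinematics(model, q, u if u is not None else np.zeros(model.n_u))
    M = np.zeros((model.n_u, model.n_u))
    for bi in model.topo_order:
        b = model.bodies[bi]
        c = kin.point_position(bi, b.com_offset)
        Jv = kin.point_jacobian(bi, c)
        Jw = kin.rotation_jacobian(bi)
        Iw = kin.R[bi] @ b.inertia @ kin.R[bi].T
        M += b.mass * (Jv.T @ Jv) + Jw.T @ (Iw @ Jw)
    return M


def bias_forces(model: SkeletonModel, q: np.ndarray, u: np.ndarray,
                kin: Kinematics | None = None) -> np.ndarray:
    """Coriolis + centrifugal + gravity generalized forces ``c(q, u)``.

    Sign convention: the equations of motion are ``M u' + c = tau``, so with
    ``u = 0`` the entries of ``c`` are minus the generalized gravity forces.
    """
    kin = kin or Kinematics(model, q, u)
    g = model.gravity
    c = np.zeros(model.n_u)
    for bi in model.topo_order:
        b = model.bodies[bi]
        r = kin.R[bi] @ b.com_offset
        cw = kin.p[bi] + r
        a_com = kin.a0[bi] + cross3(kin.alpha0[bi], r) + cross3(kin.w[bi], cross3(kin.w[bi], r))
        Jv = kin.point_jacobian(bi, cw)
        Jw = kin.rotation_jacobian(bi)
        Iw = kin.R[bi] @ b.inertia @ kin.R[bi].T
        c += Jv.T @ (b.mass * (a_com - g))
        c += Jw.T @ (Iw @ kin.alpha0[bi] + cross3(kin.w[bi], Iw @ kin.w[bi]))
    return c


def dynamics_terms(model: SkeletonModel, kin: Kinematics) -> tuple[np.ndarray, np.ndarray]:
    """Mass matrix and bias vector in one pass (hot-path fusion).

    Identical to :func:`mass_matrix` + :func:`bias_forces` but shares the
    per-body Jacobian construction between the two.
    """
    g = model.gravity
    n = model.n_u
    M = np.zeros((n, n))
    c = np.zeros(n)
    for bi in model.topo_order:
        b = model.bodies[bi]
        r = kin.R[bi] @ b.com_offset
        cw = kin.p[bi] + r
        Jv = kin.point_jacobian(bi, cw)
        Jw = kin.rotation_jacobian(bi)
        Iw = kin.R[bi] @ b.inertia @ kin.R[bi].T
        M += b.mass * (Jv.T @ Jv) + Jw.T @ (Iw @ Jw)
        a_com = kin.a0[bi] + cross3(kin.alpha0[bi], r) + cross3(kin.w[bi], cross3(kin.w[bi], r))
        c += Jv.T @ (b.mass * (a_com - g))
        c += Jw.T @ (Iw @ kin.alpha0[bi] + cross3(kin.w[bi], Iw @ kin.w[bi]))
    return M, c


def generalized_external(model: SkeletonModel, kin: Kinematics,
                         ext: list[ExternalForce]) -> np.ndarray:
    """Project world-frame body forces/torques into generalized coordinates."""
    tau = np.zeros(model.n_u)
    for e in ext:
        tau += kin.point_jacobian(e.body, e.point).T @ e.force
        if e.torque is not None:
            tau += kin.rotation_jacobian(e.body).T @ e.torque
    return tau


def forward_dynamics(model: SkeletonModel, q: np.ndarray, u: np.ndarray,
                     tau: np.ndarray, ext: list[ExternalForce] | None = None,
                     kin: Kinematics | None = None) -> np.ndarray:
    """Solve ``M u' = tau - c + J^T f_ext`` for the accelerations ``u'``."""
    if tau.shape != (model.n_u,):
        raise ValueError(f"tau must have shape ({model.n_u},), got {tau.shape}")
    kin = kin or Kinematics(model, q, u)
    M = mass_matrix(model, q, kin=kin)
    rhs = tau - bias_forces(model, q, u, kin=kin)
    if ext:
        rhs = rhs + generalized_external(model, kin, ext)
    try:
        return np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:
        raise SingularMassMatrixError(
            f"mass matrix singular (cond ~ {np.linalg.cond(M):.3g}); "
            "check for zero inertias or degenerate geometry") from exc


def _first_nonfinite_coord(model: SkeletonModel, q: np.ndarray, u: np.ndarray) -> str:
    qo, uo = model.q_offset, model.u_offset
    base_q = ["quat_w", "quat_x", "quat_y", "quat_z", "base_x", "base_y", "base_z"]
    for i, val in enumerate(q):
        if not np.isfinite(val):
            return base_q[i] if i < qo else model.coord_names[i - qo]
    base_u = ["wx", "wy", "wz", "vx", "vy", "vz"]
    for i, val in enumerate(u):
        if not np.isfinite(val):
            return ("base_" + base_u[i]) if i < uo else model.coord_names[i - uo] + "_rate"
    return "<unknown>"


def integrate_semi_implicit(model: SkeletonModel, state: GenState,
                            udot: np.ndarray, dt: float) -> GenState:
    """Semi-implicit Euler step given precomputed accelerations."""
    u_new = state.u + udot * dt
    q_new = state.q.copy()
    if model.floating_base:
        q_new[0:4] = quat_integrate(state.q[0:4], u_new[0:3], dt)
        q_new[4:7] = state.q[4:7] + u_new[3:6] * dt
        q_new[7:] = state.q[7:] + u_new[6:] * dt
    else:
        q_new += u_new * dt
    if not (np.all(np.isfinite(q_new)) and np.all(np.isfinite(u_new))):
        bad = _first_nonfinite_coord(model, q_new, u_new)
        raise IntegrationError(f"non-finite state after step at t={state.t:.6g}s "
                               f"(first offending coordinate: {bad})")
    return GenState(q_new, u_new, state.t + dt)


def step(model: SkeletonModel, state: GenState, tau: np.ndarray,
         ext: list[ExternalForce] | None = None, dt: float = 1e-3) -> GenState:
    """One forward-dynamics + semi-implicit Euler step."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    udot = forward_dynamics(model, state.q, state.u, tau, ext)
    return integrate_semi_implicit(model, state, udot, dt)


def kinetic_energy(model: SkeletonModel, q: np.ndarray, u: np.ndarray) -> float:
    M = mass_matrix(model, q, u=u)
    return 0.5 * float(u @ M @ u)


def potential_energy(model: SkeletonModel, q: np.ndarray) -> float:
    kin = Kinematics(model, q, np.zeros(model.n_u))
    E = 0.0
    for bi in model.topo_order:
        b = model.bodies[bi]
        c = kin.point_position(bi, b.com_offset)
        E -= b.mass * float(model.gravity @ c)
    return E
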
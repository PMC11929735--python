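"""Hill-type muscle-tendon units.

Each muscle-tendon unit (MTU) is a contractile element with active
force-length and force-velocity behaviour, in parallel with a passive fiber
elasticity, all in series with a passive elastic tendon.  Muscles route along
straight polylines through fixed via points attached to bodies; moment arms
follow from the tendon-excursion relation r_j = -dL/dq_j, obtained here by
virtual work through the point Jacobians (no finite differencing).

Two force modes are provided: a rigid tendon (fiber length = path length minus
tendon slack; the default inside control loops) and an elastic tendon whose
fiber length solves the tendon-fiber force balance by bracketed root-finding.

Dimensionless curve shapes (Gaussian active force-length, Hill hyperbola with
an eccentric plateau, exponential passive fiber, quadratic-toe/linear tendon)
are standard published forms; all constants are configurable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from ._math import cross_rows
from .dynamics import Kinematics
from .skeleton import SkeletonModel

MUSCLE_GROUPS = ("upper_limb", "torso", "lower_limb")


class MuscleError(ValueError):
    pass


class EquilibriumError(RuntimeError):
    """Elastic-tendon force balance has no bracketed root."""


@dataclass
class CurveSet:
    """Normalized muscle and tendon curve constants."""
    fl_width: float = 0.45          # active force-length Gaussian width
    af: float = 0.25                # Hill force-velocity shape factor
    f_ecc: float = 1.4              # eccentric force plateau (x f_max)
    fpe_at: float = 0.04            # passive fiber force at l_norm = 1 + fpe_stretch
    fpe_stretch: float = 0.2
    fpe_shape: float = 5.0
    eps_toe: float = 0.02           # tendon toe-region strain
    k_tendon: float = 35.0          # linear tendon stiffness, f_max per unit strain

    def fl_active(self, l_norm):
        return np.exp(-(((np.asarray(l_norm) - 1.0) / self.fl_width) ** 2))

    def fv(self, v_norm):
        """Force-velocity multiplier; v_norm in units of v_max (+ = lengthening).

        Concentric branch is the Hill hyperbola (0 at v_norm = -1, 1 at 0);
        the eccentric branch saturates at ``f_ecc`` with a slope-continuous
        rational blend at zero velocity.
        """
        v = np.asarray(v_norm, dtype=float)
        con = np.clip(1.0 + v, 0.0, None) / (1.0 - np.minimum(v, 0.0) / self.af)
        slope0 = 1.0 + 1.0 / self.af
        c = (self.f_ecc - 1.0) / slope0
        ecc = (self.f_ecc * v + c) / (v + c)
        return np.where(v <= 0.0, con, ecc)

    def fpe(self, l_norm):
        l = np.asarray(l_norm, dtype=float)
        s = self.fpe_shape
        scale = self.fpe_at / np.expm1(s * self.fpe_stretch)
        return np.where(l > 1.0, scale * np.expm1(s * (l - 1.0)), 0.0)

    def ft(self, strain):
        """Normalized tendon force vs strain: quadratic toe then linear."""
        e = np.asarray(strain, dtype=float)
        k, et = self.k_tendon, self.eps_toe
        toe = (k / (2.0 * et)) * e ** 2
        lin = k * (e - et) + k * et / 2.0
        return np.where(e <= 0.0, 0.0, np.where(e < et, toe, lin))


DEFAULT_CURVES = CurveSet()


@dataclass
class MTUParams:
    name: str
    f_max: float                    # maximum isometric force, N
    l_opt: float                    # optimal fiber length, m
    l_slack: float                  # tendon slack length, m
    path: list[tuple[str, np.ndarray]]   # ordered (body label, local point)
    group: str = "lower_limb"
    v_max: float = 10.0             # maximum shortening velocity, l_opt / s
    tau_act: float = 0.010          # activation time constant, s
    tau_deact: float = 0.040        # deactivation time constant, s

    def __post_init__(self) -> None:
        if min(self.f_max, self.l_opt, self.l_slack, self.v_max) <= 0:
            raise MuscleError(f"{self.name}: f_max, l_opt, l_slack, v_max must be > 0")
        if self.tau_act > self.tau_deact:
            raise MuscleError(f"{self.name}: tau_act must be <= tau_deact")
        if len(self.path) < 2:
            raise MuscleError(f"{self.name}: path needs at least 2 points")
        if self.group not in MUSCLE_GROUPS:
            raise MuscleError(f"{self.name}: unknown group {self.group!r}")
        self.path = [(b, np.asarray(p, dtype=float)) for b, p in self.path]


@dataclass
class MuscleState:
    activation: float = 0.0
    fiber_length: float | None = None    # elastic-tendon mode only

    def __post_init__(self) -> None:
        if not 0.0 <= self.activation <= 1.0:
            raise MuscleError("activation must lie in [0, 1]")


def parse_mtu(raw: dict) -> MTUParams:
    """Build MTUParams from a raw model-config muscle entry."""
    return MTUParams(
        name=raw["name"], f_max=float(raw["f_max"]), l_opt=float(raw["l_opt"]),
        l_slack=float(raw["l_slack"]),
        path=[(p["body"], np.asarray(p["point"], dtype=float)) for p in raw["path"]],
        group=raw.get("group", "lower_limb"),
        v_max=float(raw.get("v_max", 10.0)),
        tau_act=float(raw.get("tau_act", 0.010)),
        tau_deact=float(raw.get("tau_deact", 0.040)),
    )


# -- activation dynamics -------------------------------------------------

def activation_step(a, e, dt: float, tau_act: float = 0.010,
                    tau_deact: float = 0.040):
    """First-order activation dynamics, one explicit Euler step.

    da/dt = (e - a)/tau with tau = tau_act while excitation exceeds
    activation and tau_deact otherwise; the result is clamped to [0, 1].
    Accepts scalars or equally shaped arrays.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    tau = np.where(e > a, tau_act, tau_deact)
    out = np.clip(a + dt * (e - a) / tau, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


# -- path geometry -------------------------------------------------------

def _path_world(model: SkeletonModel, kin: Kinematics,
                path: list[tuple[str, np.ndarray]]) -> tuple[np.ndarray, np.ndarray, list[int]]:
    bodies = [model.body_index[b] for b, _ in path]
    pts = np.array([kin.point_position(bi, loc) for bi, (_, loc) in zip(bodies, path)])
    vels = np.array([kin.point_velocity(bi, x) for bi, x in zip(bodies, pts)])
    return pts, vels, bodies


def mtu_length_velocity(model: SkeletonModel, q: np.ndarray, u: np.ndarray,
                        path: list[tuple[str, np.ndarray]],
                        kin: Kinematics | None = None) -> tuple[float, float]:
    """Polyline path length (m) and its time derivative (m/s)."""
    kin = kin or Kinematics(model, q, u)
    pts, vels, _ = _path_world(model, kin, path)
    seg = np.diff(pts, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    if np.any(lens < 1e-12):
        raise MuscleError("degenerate path: coincident adjacent via points")
    dirs = seg / lens[:, None]
    l_mt = float(lens.sum())
    v_mt = float(np.sum(dirs * np.diff(vels, axis=0)))
    return l_mt, v_mt


def muscle_generalized_force(model: SkeletonModel, kin: Kinematics,
                             path: list[tuple[str, np.ndarray]],
                             tension: float) -> np.ndarray:
    """Generalized force produced by a path under the given tension.

    Equal and opposite forces along each polyline segment act on the two
    attached bodies; by virtual work this equals ``-tension * dL/dq``.
    """
    pts, _, bodies = _path_world(model, kin, path)
    seg = np.diff(pts, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    if np.any(lens < 1e-12):
        raise MuscleError("degenerate path: coincident adjacent via points")
    dirs = seg / lens[:, None]
    tau = np.zeros(model.n_u)
    for k in range(len(pts)):
        f = np.zeros(3)
        if k < len(dirs):
            f += tension * dirs[k]       # pulled toward the next point
        if k > 0:
            f -= tension * dirs[k - 1]   # pulled toward the previous point
        tau += kin.point_jacobian(bodies[k], pts[k]).T @ f
    return tau


def moment_arms(model: SkeletonModel, q: np.ndarray,
                path: list[tuple[str, np.ndarray]],
                kin: Kinematics | None = None) -> np.ndarray:
    """Tendon-excursion moment arms r_j = -dL/dq_j for every coordinate in u.

    Entries for unspanned coordinates (and the floating base) are zero only
    where the path does not couple to them; joint coordinates not crossed by
    the path are exactly zero.
    """
    kin = kin or Kinematics(model, q, np.zeros(model.n_u))
    return muscle_generalized_force(model, kin, path, 1.0)


# -- force generation ----------------------------------------------------

def mtu_force(params: MTUParams, curves: CurveSet, l_mt: float, v_mt: float,
              a: float, mode: str = "rigid",
              state: MuscleState | None = None) -> tuple[float, float, float]:
    """MTU force along the path; returns (F, fiber_length, fiber_velocity).

    Rigid mode assigns all path-length change to the fiber.  Elastic mode
    solves the series tendon-fiber force balance for the fiber length by
    bracketed root-finding (quasi-static in fiber velocity), then reports the
    tendon force; fiber velocity is the remainder of the path rate.
    """
    if not 0.0 <= a <= 1.0:
        raise MuscleError("activation must lie in [0, 1]")
    if mode == "rigid":
        l_f = l_mt - params.l_slack
        ln = l_f / params.l_opt
        vn = v_mt / (params.l_opt * params.v_max)
        f = params.f_max * (a * curves.fl_active(ln) * curves.fv(vn) + curves.fpe(ln))
        return max(float(f), 0.0), l_f, v_mt
    if mode != "elastic":
        raise ValueError(f"unknown mode {mode!r}")

    def residual(l_f: float) -> float:
        eps = (l_mt - l_f) / params.l_slack - 1.0
        ln = l_f / params.l_opt
        return float(curves.ft(eps) - (a * curves.fl_active(ln) + curves.fpe(ln)))

    lo = 1e-4 * params.l_opt
    hi = l_mt - 1e-9
    if state is not None and state.fiber_length is not None:
        guess = state.fiber_length
        if lo < guess < hi and abs(residual(guess)) < 1e-9:
            l_f = guess
        else:
            l_f = _solve_balance(residual, lo, hi, params, l_mt, v_mt, a)
    else:
        l_f = _solve_balance(residual, lo, hi, params, l_mt, v_mt, a)
    eps = (l_mt - l_f) / params.l_slack - 1.0
    f = params.f_max * float(curves.ft(eps))
    return max(f, 0.0), l_f, v_mt  # quasi-static: path rate attributed to the fiber


def _solve_balance(residual, lo, hi, params, l_mt, v_mt, a) -> float:
    rlo, rhi = residual(lo), residual(hi)
    if rlo == 0.0:
        return lo
    if rhi == 0.0:
        return hi
    if rlo * rhi > 0:
        raise EquilibriumError(
            f"{params.name}: no tendon-fiber equilibrium in bracket "
            f"(l_mt={l_mt:.6g}, v_mt={v_mt:.6g}, a={a:.3g}, "
            f"residuals {rlo:.3g}/{rhi:.3g})")
    return float(brentq(residual, lo, hi, xtol=1e-12, rtol=1e-10))


def fiber_power(f_fiber: float, fiber_velocity: float) -> float:
    """Fiber mechanical power; shortening (negative velocity) is positive work."""
    return -f_fiber * fiber_velocity


# -- vectorized bundle used in the simulation hot path -------------------

class MuscleSystem:
    """All MTUs of a model packed into flat arrays for fast evaluation.

    Path points of every muscle are concatenated; per-step evaluation does one
    vectorized world-position/velocity pass, computes lengths, rates and
    rigid-tendon forces for all muscles, and projects tensions into
    generalized forces body by body.
    """

    def __init__(self, model: SkeletonModel, curves: CurveSet | None = None,
                 mtus: list[MTUParams] | None = None):
        self.model = model
        self.curves = curves or DEFAULT_CURVES
        self.mtus = mtus if mtus is not None else [parse_mtu(m) for m in model.muscles]
        self.n = len(self.mtus)
        self.names = [m.name for m in self.mtus]
        self.groups = np.array([MUSCLE_GROUPS.index(m.group) for m in self.mtus])
        self.f_max = np.array([m.f_max for m in self.mtus])
        self.l_opt = np.array([m.l_opt for m in self.mtus])
        self.l_slack = np.array([m.l_slack for m in self.mtus])
        self.v_max = np.array([m.v_max for m in self.mtus])
        self.tau_act = np.array([m.tau_act for m in self.mtus])
        self.tau_deact = np.array([m.tau_deact for m in self.mtus])

        pt_body, pt_local, seg_mus = [], [], []
        self._mus_slice = []
        cursor = 0
        for mi, m in enumerate(self.mtus):
            for b, p in m.path:
                pt_body.append(model.body_index[b])
                pt_local.append(p)
            npts = len(m.path)
            seg_mus.extend([mi] * (npts - 1))
            self._mus_slice.append((cursor, cursor + npts))
            cursor += npts
        self.pt_body = np.array(pt_body, dtype=int)
        self.pt_local = np.array(pt_local, dtype=float)
        self.seg_mus = np.array(seg_mus, dtype=int)
        first = np.array([s for s, _ in self._mus_slice])
        # segment k of the flat point list joins point k and k+1 of one muscle
        keep = np.ones(cursor, dtype=bool)
        keep[first[1:] - 1] = False  # drop inter-muscle "segments"
        keep = keep[:-1]
        self.seg_a = np.arange(cursor - 1)[keep]
        self.seg_b = self.seg_a + 1

        # per-body point membership for the force projection pass
        self._body_pts = {bi: np.where(self.pt_body == bi)[0]
                          for bi in set(self.pt_body.tolist())}

    def geometry(self, kin: Kinematics) -> tuple[np.ndarray, np.ndarray]:
        """Lengths and rates of all MTUs (vectorized)."""
        P = kin.p[self.pt_body] + np.einsum("kij,kj->ki", kin.R[self.pt_body], self.pt_local)
        V = kin.v[self.pt_body] + cross_rows(kin.w[self.pt_body], P - kin.p[self.pt_body])
        d = P[self.seg_b] - P[self.seg_a]
        lens = np.linalg.norm(d, axis=1)
        dirs = d / np.maximum(lens, 1e-12)[:, None]
        l_mt = np.bincount(self.seg_mus, weights=lens, minlength=self.n)
        rate = np.sum(dirs * (V[self.seg_b] - V[self.seg_a]), axis=1)
        v_mt = np.bincount(self.seg_mus, weights=rate, minlength=self.n)
        self._P, self._dirs = P, dirs
        return l_mt, v_mt

    def rigid_forces(self, l_mt: np.ndarray, v_mt: np.ndarray,
                     act: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Rigid-tendon forces; returns (F, fiber_length, fiber_velocity)."""
        l_f = l_mt - self.l_slack
        ln = l_f / self.l_opt
        vn = v_mt / (self.l_opt * self.v_max)
        c = self.curves
        F = self.f_max * (act * c.fl_active(ln) * c.fv(vn) + c.fpe(ln))
        return np.maximum(F, 0.0), l_f, v_mt

    def project(self, kin: Kinematics, tensions: np.ndarray) -> np.ndarray:
        """Generalized forces from all muscle tensions (call after geometry)."""
        m = self.model
        P, dirs = self._P, self._dirs
        Fpt = np.zeros_like(P)
        t = tensions[self.seg_mus][:, None] * dirs
        np.add.at(Fpt, self.seg_a, t)
        np.add.at(Fpt, self.seg_b, -t)
        tau = np.zeros(m.n_u)
        uo = m.u_offset
        p0 = kin.p[m._root_body]
        for bi, idx in self._body_pts.items():
            F = Fpt[idx]
            X = P[idx]
            if m.floating_base:
                tau[3:6] += F.sum(axis=0)
                tau[0:3] += cross_rows(X - p0, F).sum(axis=0)
            dofs = m.supports[bi]
            if dofs.size:
                r = X[None, :, :] - kin.axis_p[dofs - uo][:, None, :]
                tau[dofs] += np.einsum("dj,dkj->d", kin.axis_w[dofs - uo],
                                       cross_rows(r, F[None, :, :]))
        return tau

    def step_activation(self, act: np.ndarray, exc: np.ndarray, dt: float) -> np.ndarray:
        tau = np.where(exc > act, self.tau_act, self.tau_deact)
        return np.clip(act + dt * (exc - act) / tau, 0.0, 1.0)
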
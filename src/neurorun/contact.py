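"""Compliant sphere-on-plane foot-ground contact.

Normal force follows a Hunt-Crossley law, F_n = k_n * d^{3/2} * (1 + c_n * d_dot),
clamped at zero so the ground never pulls; tangential force is Coulomb friction
regularized with a tanh profile so it is smooth through zero slip velocity.
The ground is the plane z = 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import ExternalForce, Kinematics
from .skeleton import SkeletonModel


@dataclass
class ContactParams:
    k_n: float = 5e5        # normal stiffness, N / m^{3/2}
    c_n: float = 1.0        # Hunt-Crossley damping coefficient, s/m
    mu: float = 0.9         # Coulomb friction coefficient
    v_reg: float = 0.05     # friction regularization velocity, m/s

    def __post_init__(self) -> None:
        if min(self.k_n, self.c_n, self.mu, self.v_reg) <= 0:
            raise ValueError("all contact parameters must be strictly positive")
        if self.mu > 2:
            raise ValueError("friction coefficient mu must be <= 2")


@dataclass
class ContactResult:
    forces: list[ExternalForce]                      # one per penetrating sphere
    grf: dict[str, np.ndarray] = field(default_factory=dict)   # per-foot total force, N
    cop: dict[str, np.ndarray] = field(default_factory=dict)   # per-foot center of pressure, m


def contact_wrenches(model: SkeletonModel, q: np.ndarray, u: np.ndarray,
                     params: ContactParams,
                     kin: Kinematics | None = None) -> ContactResult:
    """Per-sphere ground forces and per-foot aggregate GRF + center of pressure.

    The center of pressure is the normal-force-weighted centroid of the active
    sphere contact points; a foot with no active contact reports zero GRF and
    a zero CoP vector.
    """
    kin = kin or Kinematics(model, q, u)
    forces: list[ExternalForce] = []
    per_foot: dict[str, list[tuple[np.ndarray, np.ndarray, float]]] = {"left": [], "right": []}

    for s in model.contact_spheres:
        bi = model.body_index[s.body]
        center = kin.point_position(bi, s.offset)
        d = s.radius - center[2]          # penetration depth of the sphere bottom
        if d <= 0.0:
            continue
        cpoint = np.array([center[0], center[1], center[2] - s.radius])
        vel = kin.point_velocity(bi, cpoint)
        ddot = -vel[2]                    # penetration rate
        fn = params.k_n * d ** 1.5 * (1.0 + params.c_n * ddot)
        if fn <= 0.0:
            continue
        vt = vel[:2]
        vt_norm = float(np.hypot(vt[0], vt[1]))
        if vt_norm > 1e-12:
            ft = -params.mu * fn * np.tanh(vt_norm / params.v_reg) * (vt / vt_norm)
        else:
            ft = np.zeros(2)
        force = np.array([ft[0], ft[1], fn])
        forces.append(ExternalForce(bi, force, cpoint))
        per_foot.setdefault(s.foot_id, []).append((force, cpoint, fn))

    result = ContactResult(forces)
    for foot, items in per_foot.items():
        if items:
            total = np.sum([f for f, _, _ in items], axis=0)
            wsum = sum(fn for _, _, fn in items)
            cop = np.sum([fn * p for _, p, fn in items], axis=0) / wsum
            cop[2] = 0.0
        else:
            total = np.zeros(3)
            cop = np.zeros(3)
        result.grf[foot] = total
        result.cop[foot] = cop
    return result
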
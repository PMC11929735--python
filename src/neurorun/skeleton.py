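"""Articulated-body model description and compilation.

A model is a tree of rigid segments rooted at a floating (6-DOF) pelvis.
Joints are free (6 DOF, root only), spherical (3 DOF, intrinsic Z-X-Y Euler
triplet) or revolute (1 DOF about a fixed local axis).  Internally a spherical
joint is compiled into three stacked single-axis rotations sharing one anchor
point, which keeps the kinematics and Jacobian machinery uniform.

Generalized coordinates ``q`` are laid out as::

    q[0:4]  base orientation quaternion (w, x, y, z)
    q[4:7]  base position (m)
    q[7:]   joint angles (rad), in model joint order (Z,X,Y per spherical)

Generalized velocities ``u``::

    u[0:3]  base angular velocity, world frame (rad/s)
    u[3:6]  base linear velocity, world frame (m/s)
    u[6:]   joint angle rates (rad/s)

Axes: Z up, X forward (direction of travel), Y left; right-handed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._math import euler_zxy_to_mat

JOINT_DOF = {"free6": 6, "spherical3": 3, "revolute1": 1, "weld0": 0}

# local rotation axes of each compiled sub-rotation, per joint type
_SPHERICAL_AXES = (
    np.array([0.0, 0.0, 1.0]),
    np.array([1.0, 0.0, 0.0]),
    np.array([0.0, 1.0, 0.0]),
)
_SPHERICAL_SUFFIX = ("_z", "_x", "_y")


class ModelError(ValueError):
    """Invalid model description."""


class StructuralError(ModelError):
    """Joint graph is not a tree rooted at a free joint."""


class ReferenceError_(ModelError):
    """A label refers to a body/joint that does not exist."""


@dataclass
class BodySpec:
    name: str
    mass: float
    inertia: np.ndarray          # 3x3 about segment COM, body frame, kg m^2
    com_offset: np.ndarray       # COM in the body (parent-joint) frame, m

    def __post_init__(self) -> None:
        self.inertia = np.asarray(self.inertia, dtype=float)
        self.com_offset = np.asarray(self.com_offset, dtype=float)
        if self.mass <= 0:
            raise ModelError(f"body {self.name}: mass must be > 0")
        if not np.allclose(self.inertia, self.inertia.T, atol=1e-12):
            raise ModelError(f"body {self.name}: inertia must be symmetric")
        if np.any(np.linalg.eigvalsh(self.inertia) <= 0):
            raise ModelError(f"body {self.name}: inertia must be positive definite")


@dataclass
class JointSpec:
    name: str
    type: str                    # free6 | spherical3 | revolute1
    parent: str | None           # parent body label (None for the root joint)
    child: str                   # child body label
    translation: np.ndarray      # joint anchor in the parent body frame, m
    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))  # fixed ZXY offset, rad
    axis: np.ndarray | None = None      # revolute only, unit vector in joint frame
    # (min, max) rad for revolute; list of three (min, max) for spherical
    limits: tuple[float, float] | list | None = None

    def __post_init__(self) -> None:
        if self.type not in JOINT_DOF:
            raise ModelError(f"joint {self.name}: unknown type {self.type!r}")
        self.translation = np.asarray(self.translation, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        if self.type == "revolute1":
            if self.axis is None:
                raise ModelError(f"joint {self.name}: revolute joint needs an axis")
            self.axis = np.asarray(self.axis, dtype=float)
            n = np.linalg.norm(self.axis)
            if abs(n - 1.0) > 1e-8:
                raise ModelError(f"joint {self.name}: revolute axis must have unit norm")


@dataclass
class ContactSphere:
    body: str
    offset: np.ndarray           # center in body frame, m
    radius: float
    foot_id: str                 # "left" | "right"

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, dtype=float)
        if self.radius <= 0:
            raise ModelError(f"contact sphere on {self.body}: radius must be > 0")


@dataclass
class SitePoint:
    """A named point fixed to a body (end-effector marker)."""
    name: str
    body: str
    point: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)


@dataclass
class _CompiledBody:
    parent: int                  # index into bodies, -1 for root
    R_fix: np.ndarray            # parent body frame -> joint frame rotation
    t_fix: np.ndarray            # joint anchor in parent body frame
    axes: list[np.ndarray]       # local sub-rotation axes (empty for root)
    q_start: int                 # index into q[7:] block (absolute index into q)
    u_start: int                 # absolute index into u
    n_dof: int


class SkeletonModel:
    """Compiled articulated model with coordinate bookkeeping.

    Attributes of interest: ``n_q``, ``n_u``, ``coord_index`` mapping each
    named joint coordinate to its index in ``u`` (joint angles occupy the same
    relative order in ``q[7:]``), ``bodies``, ``joints``, ``contact_spheres``,
    ``muscles`` (raw dicts; see :mod:`neurorun.muscle`), ``sites``.
    """

    def __init__(self, bodies: list[BodySpec], joints: list[JointSpec],
                 gravity: np.ndarray, contact_spheres: list[ContactSphere],
                 sites: list[SitePoint] | None = None,
                 muscles: list[dict] | None = None):
        self.bodies = bodies
        self.joints = joints
        self.gravity = np.asarray(gravity, dtype=float)
        self.contact_spheres = contact_spheres
        self.sites = sites or []
        self.muscles = muscles or []
        self._compile()

    # -- compilation ----------------------------------------------------
    def _compile(self) -> None:
        body_index = {}
        for i, b in enumerate(self.bodies):
            if b.name in body_index:
                raise ModelError(f"duplicate body name {b.name!r}")
            body_index[b.name] = i
        self.body_index = body_index

        roots = [j for j in self.joints if j.parent is None]
        if len(roots) != 1:
            raise StructuralError("model must have exactly one root joint (parent: null)")
        root = roots[0]
        if any(j.type == "free6" for j in self.joints if j is not root):
            raise StructuralError("free joints are only allowed at the root")
        # a floating-base model has a free root joint; a world-anchored chain
        # (pendulum test rigs and the like) roots at any other joint type
        self.floating_base = root.type == "free6"

        inbound: dict[str, JointSpec] = {}
        for j in self.joints:
            if j.child not in body_index:
                raise ReferenceError_(f"joint {j.name}: unknown child body {j.child!r}")
            if j.parent is not None and j.parent not in body_index:
                raise ReferenceError_(f"joint {j.name}: unknown parent body {j.parent!r}")
            if j.child in inbound:
                raise StructuralError(f"body {j.child!r} has more than one inbound joint")
            inbound[j.child] = j
        for b in self.bodies:
            if b.name not in inbound:
                raise StructuralError(f"body {b.name!r} has no inbound joint")

        # order bodies topologically from the root; detect cycles
        order = [body_index[root.child]]
        placed = {root.child}
        remaining = [j for j in self.joints if j is not root]
        while remaining:
            progressed = False
            for j in list(remaining):
                if j.parent in placed:
                    if j.child in placed:
                        raise StructuralError(f"cycle in joint graph at {j.name!r}")
                    order.append(body_index[j.child])
                    placed.add(j.child)
                    remaining.remove(j)
                    progressed = True
            if not progressed:
                raise StructuralError("cycle in joint graph (unreachable joints: "
                                      + ", ".join(j.name for j in remaining) + ")")

        self.topo_order = order  # body indices, root first
        self._root_body = body_index[root.child]

        compiled: list[_CompiledBody | None] = [None] * len(self.bodies)
        coord_names: list[str] = []
        coord_limits: list[tuple[float, float] | None] = []
        # q layout: [quat(4), pos(3), joint angles] when floating, else just angles
        self.q_offset = 7 if self.floating_base else 0
        self.u_offset = 6 if self.floating_base else 0
        q_cursor, u_cursor = self.q_offset, self.u_offset
        for bi in order:
            bname = self.bodies[bi].name
            j = inbound[bname]
            R_fix = euler_zxy_to_mat(j.rotation)
            if j.type == "free6":
                compiled[bi] = _CompiledBody(-1, R_fix, j.translation, [], 0, 0, 6)
                continue
            if j.type == "spherical3":
                axes = list(_SPHERICAL_AXES)
                names = [j.name + s for s in _SPHERICAL_SUFFIX]
                lims = list(j.limits) if j.limits is not None else [None, None, None]
            elif j.type == "weld0":
                axes, names, lims = [], [], []
            else:
                axes = [j.axis]
                names = [j.name]
                lims = [j.limits]
            parent_idx = body_index[j.parent] if j.parent is not None else -1
            compiled[bi] = _CompiledBody(parent_idx, R_fix, j.translation,
                                         axes, q_cursor, u_cursor, len(axes))
            coord_names.extend(names)
            coord_limits.extend(lims)
            q_cursor += len(axes)
            u_cursor += len(axes)

        self.compiled: list[_CompiledBody] = compiled  # type: ignore[assignment]
        self.coord_names = coord_names
        self.coord_limits = coord_limits
        self.n_q = q_cursor
        self.n_u = u_cursor
        self.n_joint_dof = self.n_u - self.u_offset
        # q index of a joint dof = its u index + _qu_shift
        self._qu_shift = self.q_offset - self.u_offset
        # named joint coordinate -> index into u
        self.coord_index = {n: self.u_offset + k for k, n in enumerate(coord_names)}

        # flat arrays used by the dynamics hot path
        self.masses = np.array([b.mass for b in self.bodies])
        self.inertias = np.stack([b.inertia for b in self.bodies])
        self.com_offsets = np.stack([b.com_offset for b in self.bodies])
        self.total_mass = float(self.masses.sum())

        # per-body list of supported joint-dof u-indices (excluding base 0..5)
        supports: list[np.ndarray] = [np.empty(0, dtype=int)] * len(self.bodies)
        for bi in order:
            cb = compiled[bi]
            own = (np.arange(cb.u_start, cb.u_start + cb.n_dof)
                   if cb.axes else np.empty(0, dtype=int))
            if cb.parent >= 0:
                supports[bi] = np.concatenate([supports[cb.parent], own])
            else:
                supports[bi] = own
        self.supports = supports

        self.site_index = {s.name: s for s in self.sites}

    # -- convenience ----------------------------------------------------
    def q_coord_index(self, name: str) -> int:
        """Index of a named joint coordinate inside ``q``."""
        return self.coord_index[name] + self._qu_shift

    def default_state_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        q = np.zeros(self.n_q)
        if self.floating_base:
            q[0] = 1.0
        return q, np.zeros(self.n_u)


def _parse_inertia(val) -> np.ndarray:
    arr = np.asarray(val, dtype=float)
    if arr.shape == (3,):
        return np.diag(arr)
    if arr.shape == (3, 3):
        return arr
    raise ModelError("inertia must be a length-3 diagonal or a 3x3 matrix")


def build_model(config: dict | str | Path) -> SkeletonModel:
    """Compile a model description (dict, or path to a YAML file).

    Returns a :class:`SkeletonModel` with DOF counts and the coordinate index
    map computed.  Raises :class:`StructuralError` on cycles/multiple roots and
    :class:`ReferenceError_` on dangling body labels.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    assert isinstance(config, dict)

    bodies = [
        BodySpec(b["name"], float(b["mass"]), _parse_inertia(b["inertia"]),
                 np.asarray(b.get("com", [0, 0, 0]), dtype=float))
        for b in config["bodies"]
    ]
    joints = []
    for j in config["joints"]:
        rot = np.deg2rad(np.asarray(j.get("rotation_zxy_deg", [0, 0, 0]), dtype=float))
        lim = j.get("limits_deg")
        if lim is not None:
            arr = np.deg2rad(np.asarray(lim, dtype=float))
            lim = [tuple(p) for p in arr] if arr.ndim == 2 else tuple(arr)
        joints.append(JointSpec(
            name=j["name"], type=j["type"], parent=j.get("parent"), child=j["child"],
            translation=np.asarray(j.get("translation", [0, 0, 0]), dtype=float),
            rotation=rot,
            axis=np.asarray(j["axis"], dtype=float) if "axis" in j else None,
            limits=lim,
        ))
    spheres = [
        ContactSphere(s["body"], np.asarray(s["offset"], dtype=float),
                      float(s["radius"]), s["foot"])
        for s in config.get("contact_spheres", [])
    ]
    sites = [
        SitePoint(s["name"], s["body"], np.asarray(s["point"], dtype=float))
        for s in config.get("sites", [])
    ]
    model = SkeletonModel(
        bodies, joints,
        gravity=np.asarray(config.get("gravity", [0.0, 0.0, -9.81]), dtype=float),
        contact_spheres=spheres, sites=sites,
        muscles=list(config.get("muscles", [])),
    )
    model.source_config = config
    return model
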
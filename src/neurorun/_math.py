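"""Small 3-D rotation/quaternion helpers used by the dynamics core.

Conventions: quaternions are (w, x, y, z) and unit-norm; rotation matrices map
body-frame vectors to world frame; angular velocities are world-frame unless
stated otherwise.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "skew",
    "quat_to_mat",
    "mat_to_quat",
    "quat_normalize",
    "quat_integrate",
    "rot_axis_angle",
    "rot_x",
    "rot_y",
    "rot_z",
    "euler_zxy_to_mat",
    "mat_to_euler_zxy",
]


def cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Fast 3-vector cross product (np.cross has large overhead here)."""
    return np.array([a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]])


def cross_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product of (n,3) arrays (broadcasting allowed)."""
    out = np.empty(a.shape if a.shape == b.shape
                   else np.broadcast_shapes(a.shape, b.shape))
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def skew(v: np.ndarray) -> np.ndarray:
    """Cross-product matrix: skew(v) @ u == v x u."""
    return np.array([
        [0.0, -v[2], v[1]],
        [v[2], 0.0, -v[0]],
        [-v[1], v[0], 0.0],
    ])


def quat_normalize(q: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(q)
    if n == 0.0:
        raise ValueError("zero-norm quaternion")
    return q / n


def quat_to_mat(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def mat_to_quat(R: np.ndarray) -> np.ndarray:
    t = np.trace(R)
    if t > 0:
        s = np.sqrt(t + 1.0) * 2
        w = 0.25 * s
        x = (R[2, 1] - R[1, 2]) / s
        y = (R[0, 2] - R[2, 0]) / s
        z = (R[1, 0] - R[0, 1]) / s
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(R[i, i] - R[j, j] - R[k, k] + 1.0) * 2
        qv = np.empty(3)
        qv[i] = 0.25 * s
        qv[j] = (R[j, i] + R[i, j]) / s
        qv[k] = (R[k, i] + R[i, k]) / s
        w = (R[k, j] - R[j, k]) / s
        x, y, z = qv
    return quat_normalize(np.array([w, x, y, z]))


def quat_mul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array([
        aw * bw - ax * bx - ay * by - az * bz,
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
    ])


def quat_integrate(q: np.ndarray, omega_world: np.ndarray, dt: float) -> np.ndarray:
    """Advance a unit quaternion by a world-frame angular velocity over dt.

    Uses the exact exponential map of the rotation increment, which keeps the
    quaternion on the unit sphere for any dt.
    """
    th = np.linalg.norm(omega_world) * dt
    if th < 1e-14:
        dq = np.array([1.0, *(0.5 * omega_world * dt)])
    else:
        axis = omega_world / np.linalg.norm(omega_world)
        dq = np.array([np.cos(th / 2), *(np.sin(th / 2) * axis)])
    return quat_normalize(quat_mul(dq, q))


def rot_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    # cardinal axes (the common case in compiled joints) get closed forms
    ax, ay, az = axis
    if ay == 0.0 and az == 0.0:
        return rot_x(angle if ax > 0 else -angle)
    if ax == 0.0 and az == 0.0:
        return rot_y(angle if ay > 0 else -angle)
    if ax == 0.0 and ay == 0.0:
        return rot_z(angle if az > 0 else -angle)
    c, s = np.cos(angle), np.sin(angle)
    K = skew(axis)
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def euler_zxy_to_mat(zxy: np.ndarray) -> np.ndarray:
    """Intrinsic Z-X-Y Euler triplet to rotation matrix: R = Rz @ Rx @ Ry."""
    return rot_z(zxy[0]) @ rot_x(zxy[1]) @ rot_y(zxy[2])


def mat_to_euler_zxy(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`euler_zxy_to_mat` on the non-degenerate branch.

    R = Rz(a) Rx(b) Ry(c); b in (-pi/2, pi/2) away from gimbal lock.
    """
    b = np.arcsin(np.clip(R[2, 1], -1.0, 1.0))
    a = np.arctan2(-R[0, 1], R[1, 1])
    c = np.arctan2(-R[2, 0], R[2, 2])
    return np.array([a, b, c])
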
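"""Synthetic periodic running kinematics and motion-file I/O.

The generator stands in for subject motion capture: every joint coordinate is
a truncated Fourier series in stride phase (exactly periodic, C-infinity), the
pelvis advances at the commanded speed with a double-bounce vertical
oscillation, and arms swing out of phase with the ipsilateral leg
(contralateral coordination).  The generator is seed-free and pure: the same
parameters always produce the same motion.

Motion tables are read/written either as plain CSV or in a tab-delimited
header dialect (``nRows``/``nColumns``/``inDegrees`` keys terminated by
``endheader``; time in column 1; angle columns in degrees on disk, radians in
memory; ``*_tx/_ty/_tz`` columns in meters).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._math import euler_zxy_to_mat, mat_to_quat
from .dynamics import GenState, Kinematics
from .skeleton import SkeletonModel

TWO_PI = 2.0 * np.pi


class MotionFileError(ValueError):
    """Malformed motion file."""


@dataclass
class FourierSeries:
    """a0 + sum_k amp_k * sin(2 pi k phi + phase_k) over stride phase phi."""
    a0: float = 0.0
    harmonics: list[tuple[int, float, float]] = field(default_factory=list)  # (k, amp, phase)

    def value(self, phi):
        out = np.full_like(np.asarray(phi, dtype=float), self.a0)
        for k, amp, ph in self.harmonics:
            out = out + amp * np.sin(TWO_PI * k * np.asarray(phi) + ph)
        return out

    def dphi(self, phi):
        """Derivative with respect to phase."""
        out = np.zeros_like(np.asarray(phi, dtype=float))
        for k, amp, ph in self.harmonics:
            out = out + amp * TWO_PI * k * np.cos(TWO_PI * k * np.asarray(phi) + ph)
        return out


@dataclass
class GaitParams:
    """Synthetic running-gait parameters (angles in degrees here; the
    generated motion is radians internally)."""
    speed: float = 3.33            # m/s (12 km/h)
    cadence: float = 1.35          # strides/s
    pelvis_height: float = 0.93    # mean pelvis height, m
    vertical_osc: float = 0.04     # pelvis vertical oscillation amplitude, m
    arm_phase_offset: float = np.pi  # contralateral arm-leg coordination
    torso_lean_deg: float = 5.0
    hip_flexion_mean: float = 10.0
    hip_flexion_amp: float = 35.0
    knee_mean: float = 55.0
    knee_amp: float = 35.0
    ankle_amp: float = 20.0
    shoulder_amp: float = 30.0
    elbow_mean: float = 90.0
    elbow_amp: float = 15.0
    torso_yaw_amp: float = 8.0
    hip_abd_amp: float = 4.0
    coefficients: dict[str, FourierSeries] | None = None  # radians; overrides defaults

    def __post_init__(self) -> None:
        if self.cadence <= 0:
            raise ValueError("cadence must be > 0")


class ReferenceMotion:
    """Periodic reference running motion, evaluable at any time/phase.

    ``joint_series`` maps each model joint coordinate to a Fourier series in
    stride phase; pelvis translation/orientation have their own series; the
    pelvis forward position advances at ``speed`` on average (here: exactly).
    """

    def __init__(self, cycle_T: float, speed: float,
                 joint_series: dict[str, FourierSeries],
                 pelvis_z: FourierSeries,
                 pelvis_euler_zxy: tuple[FourierSeries, FourierSeries, FourierSeries]):
        self.cycle_T = cycle_T
        self.speed = speed
        self.joint_series = joint_series
        self.pelvis_z = pelvis_z
        self.pelvis_euler = pelvis_euler_zxy
        self._tables: dict[int, dict] = {}

    def phase(self, t: float) -> float:
        return float(np.mod(t / self.cycle_T, 1.0))

    def gen_state(self, model: SkeletonModel, t: float) -> GenState:
        """Full generalized state on the reference at time t."""
        phi = self.phase(t)
        dphase_dt = 1.0 / self.cycle_T
        q = np.zeros(model.n_q)
        u = np.zeros(model.n_u)
        eul = np.array([s.value(phi) for s in self.pelvis_euler])
        deul = np.array([s.dphi(phi) for s in self.pelvis_euler]) * dphase_dt
        R = euler_zxy_to_mat(eul)
        q[0:4] = mat_to_quat(R)
        q[4] = self.speed * t
        q[5] = 0.0
        q[6] = self.pelvis_z.value(phi)
        # world angular velocity of the ZXY Euler sequence
        ez = np.array([0.0, 0.0, 1.0])
        ex_p = euler_zxy_to_mat([eul[0], 0, 0]) @ np.array([1.0, 0.0, 0.0])
        ey_pp = euler_zxy_to_mat([eul[0], eul[1], 0]) @ np.array([0.0, 1.0, 0.0])
        u[0:3] = deul[0] * ez + deul[1] * ex_p + deul[2] * ey_pp
        u[3] = self.speed
        u[5] = self.pelvis_z.dphi(phi) * dphase_dt
        for name, series in self.joint_series.items():
            idx = model.coord_index[name]
            q[1 + idx] = series.value(phi)
            u[idx] = series.dphi(phi) * dphase_dt
        return GenState(q, u, t)

    # -- tracking tables ------------------------------------------------
    def tables(self, model: SkeletonModel, n: int = 160) -> dict:
        """Dense per-phase COM and end-effector reference positions.

        Positions are stored with the cycle-start pelvis x subtracted, so a
        caller adds ``speed * t`` to the x component to place the reference
        in the world.
        """
        key = id(model)
        if key in self._tables and self._tables[key]["n"] == n:
            return self._tables[key]
        phases = np.linspace(0.0, 1.0, n, endpoint=False)
        com = np.empty((n, 3))
        sites = {s.name: np.empty((n, 3)) for s in model.sites}
        qjoint = np.empty((n, model.n_joint_dof))
        ujoint = np.empty((n, model.n_joint_dof))
        for i, phi in enumerate(phases):
            st = self.gen_state(model, phi * self.cycle_T)
            st.q[4] = 0.0  # cycle-relative x
            kin = Kinematics(model, st.q, st.u)
            com[i] = kin.com()
            for s in model.sites:
                sites[s.name][i] = kin.point_position(model.body_index[s.body], s.point)
            qjoint[i] = st.q[7:]
            ujoint[i] = st.u[6:]
        tab = {"n": n, "phases": phases, "com": com, "sites": sites,
               "qjoint": qjoint, "ujoint": ujoint}
        self._tables[key] = tab
        return tab

    def sample(self, model: SkeletonModel, dt: float = 0.01,
               n_cycles: int = 1) -> tuple[list[str], np.ndarray]:
        """Sample the motion into a (time + coordinates) table (radians/m)."""
        times = np.arange(0.0, n_cycles * self.cycle_T, dt)
        names = (["pelvis_tx", "pelvis_ty", "pelvis_tz",
                  "pelvis_rz", "pelvis_rx", "pelvis_ry"] + model.coord_names)
        data = np.empty((len(times), 1 + len(names)))
        data[:, 0] = times
        for i, t in enumerate(times):
            st = self.gen_state(model, t)
            phi = self.phase(t)
            eul = [s.value(phi) for s in self.pelvis_euler]
            data[i, 1:4] = st.q[4:7]
            data[i, 4:7] = eul
            data[i, 7:] = st.q[7:]
        return names, data


def default_joint_series(model: SkeletonModel, p: GaitParams) -> dict[str, FourierSeries]:
    """Running-style default Fourier coefficients for the built-in models.

    Signs follow the model conventions: rotation of a distal segment about a
    +Y joint axis swings it backwards, so flexion-forward coordinates on the
    spherical hips/shoulders are the negated series.
    """
    d = np.deg2rad
    series: dict[str, FourierSeries] = {n: FourierSeries() for n in model.coord_names}

    for side, leg_ph in (("r", 0.0), ("l", np.pi)):
        arm_ph = leg_ph + p.arm_phase_offset
        hipflex = FourierSeries(-d(p.hip_flexion_mean),
                                [(1, d(p.hip_flexion_amp), np.pi / 2 + leg_ph)])
        # hip_y: positive swings the thigh backwards; flexion peak mid-swing
        series_name = f"hip_{side}_y"
        if series_name in series:
            series[series_name] = hipflex
        if f"hip_{side}_x" in series:
            series[f"hip_{side}_x"] = FourierSeries(0.0, [(1, d(p.hip_abd_amp), leg_ph)])
        if f"knee_{side}" in series:
            series[f"knee_{side}"] = FourierSeries(
                d(p.knee_mean), [(1, d(p.knee_amp), np.pi / 2 + leg_ph + np.deg2rad(110.0))])
        if f"ankle_{side}" in series:
            series[f"ankle_{side}"] = FourierSeries(
                0.0, [(1, d(p.ankle_amp), leg_ph + np.deg2rad(230.0))])
        if f"shoulder_{side}_y" in series:
            series[f"shoulder_{side}_y"] = FourierSeries(
                0.0, [(1, d(p.shoulder_amp), np.pi / 2 + arm_ph)])
        if f"elbow_{side}" in series:
            series[f"elbow_{side}"] = FourierSeries(
                d(p.elbow_mean), [(1, d(p.elbow_amp), np.pi / 2 + arm_ph)])
        if f"mtp_{side}" in series:
            series[f"mtp_{side}"] = FourierSeries(0.0, [(1, d(10.0), leg_ph)])

    for name in ("thoraco", "thoraco_z"):
        if name in series:
            series[name] = FourierSeries(0.0, [(1, d(p.torso_yaw_amp), np.pi / 2)])
    return series


def generate_reference(params: GaitParams, model: SkeletonModel,
                       fit_ground: bool = True) -> ReferenceMotion:
    """Build a periodic reference running motion for the given model.

    With ``fit_ground`` (default) the mean pelvis height is shifted so the
    lowest foot contact sphere grazes the ground (5 mm penetration) at its
    lowest point over the cycle, making the synthetic kinematics roughly
    consistent with stance on the plane z = 0.
    """
    cycle_T = 1.0 / params.cadence
    if params.coefficients is not None:
        unmatched = [n for n in params.coefficients if n not in model.coord_index]
        if unmatched:
            raise KeyError("coefficient coordinates not in model: " + ", ".join(unmatched))
        series = {n: FourierSeries() for n in model.coord_names}
        series.update(params.coefficients)
    else:
        series = default_joint_series(model, params)
    pelvis_z = FourierSeries(params.pelvis_height,
                             [(2, params.vertical_osc, np.pi / 2 - 4 * np.pi * 0.15 + np.pi)])
    lean = np.deg2rad(params.torso_lean_deg)
    pelvis_euler = (FourierSeries(0.0), FourierSeries(0.0), FourierSeries(lean))
    ref = ReferenceMotion(cycle_T, params.speed, series, pelvis_z, pelvis_euler)
    if fit_ground and model.contact_spheres:
        lowest = np.inf
        for phi in np.linspace(0.0, 1.0, 60, endpoint=False):
            st = ref.gen_state(model, phi * cycle_T)
            kin = Kinematics(model, st.q, st.u)
            for s in model.contact_spheres:
                c = kin.point_position(model.body_index[s.body], s.offset)
                lowest = min(lowest, c[2] - s.radius)
        pelvis_z.a0 -= lowest + 0.005
    return ref


# ---------------------------------------------------------------------------
# motion file I/O
# ---------------------------------------------------------------------------

@dataclass
class MotionFile:
    names: list[str]              # including leading "time"
    data: np.ndarray              # (n_rows, n_cols), SI units (rad, m, s)
    in_degrees_on_disk: bool = True


def _is_linear(name: str) -> bool:
    return name == "time" or name.endswith(("_tx", "_ty", "_tz"))


def write_motion(path: str | Path, names: list[str], data: np.ndarray,
                 in_degrees: bool = True) -> None:
    """Write a motion table (SI units in memory) in the .mot/.sto dialect.

    Angle columns are converted to degrees on disk when ``in_degrees``;
    ``time`` and ``*_tx/_ty/_tz`` columns are passed through.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[1] != len(names):
        raise ValueError("column count does not match names")
    out = data.copy()
    if in_degrees:
        for j, n in enumerate(names):
            if not _is_linear(n):
                out[:, j] = np.rad2deg(out[:, j])
    path = Path(path)
    if path.suffix == ".csv":
        header = ",".join(names)
        np.savetxt(path, out, delimiter=",", header=header, comments="", fmt="%.12g")
        return
    with open(path, "w") as fh:
        fh.write(f"{path.stem}\nversion=1\n")
        fh.write(f"nRows={out.shape[0]}\nnColumns={out.shape[1]}\n")
        fh.write(f"inDegrees={'yes' if in_degrees else 'no'}\nendheader\n")
        fh.write("\t".join(names) + "\n")
        for row in out:
            fh.write("\t".join(f"{v:.12g}" for v in row) + "\n")


def read_motion(path: str | Path) -> MotionFile:
    """Read a .mot/.sto (or .csv) motion table back into SI units."""
    path = Path(path)
    if path.suffix == ".csv":
        import pandas as pd
        df = pd.read_csv(path)
        names = list(df.columns)
        data = df.to_numpy(dtype=float)
        for j, n in enumerate(names):
            if not _is_linear(n):
                data[:, j] = np.deg2rad(data[:, j])
        return MotionFile(names, data, in_degrees_on_disk=True)

    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if line == "endheader":
            break
        if "=" in line:
            k, _, v = line.partition("=")
            meta[k.strip()] = v.strip()
    else:
        raise MotionFileError(f"{path}: no 'endheader' line found")
    if "nRows" not in meta or "nColumns" not in meta:
        raise MotionFileError(f"{path}: header missing nRows/nColumns (line {i})")
    names = lines[i].rstrip("\n").split("\t")
    i += 1
    rows = []
    for ln, line in enumerate(lines[i:], start=i + 1):
        if not line.strip():
            continue
        vals = line.split()
        if len(vals) != len(names):
            raise MotionFileError(f"{path}: line {ln}: expected {len(names)} columns, "
                                  f"got {len(vals)}")
        try:
            rows.append([float(v) for v in vals])
        except ValueError as exc:
            raise MotionFileError(f"{path}: line {ln}: {exc}") from None
    data = np.asarray(rows)
    if data.shape[0] != int(meta["nRows"]) or data.shape[1] != int(meta["nColumns"]):
        raise MotionFileError(
            f"{path}: header declares {meta['nRows']}x{meta['nColumns']} but the "
            f"table is {data.shape[0]}x{data.shape[1]}")
    if meta.get("inDegrees", "yes").lower() == "yes":
        for j, n in enumerate(names):
            if not _is_linear(n):
                data[:, j] = np.deg2rad(data[:, j])
        on_disk_deg = True
    else:
        on_disk_deg = False
    return MotionFile(names, data, in_degrees_on_disk=on_disk_deg)
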
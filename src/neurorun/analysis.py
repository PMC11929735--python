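"""Metabolic-energy accounting and gait analysis.

Metabolic cost follows the classic mechanical-work scheme: positive and
negative fiber work are converted to metabolic energy with distinct
efficiencies (0.25 for positive work, -1.2 for negative work), i.e.

    E = W+ / 0.25 + W- / (-1.2)

and a basal rate of 1.2 W/kg scaled by body mass runs for the whole
simulation.  Cost of transport (CoT) is energy per body mass per distance
(J/kg-m); the gross CoT partitions exactly into upper-limb, torso,
lower-limb and basal components.

Gait analysis covers heel-strike/toe-off detection from vertical GRF,
stance-phase normalization of GRF curves, torso longitudinal (transverse-
plane) rotation relative to the pelvis, and RMS curve differences.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._math import mat_to_euler_zxy
from .muscle import MUSCLE_GROUPS

MARGARIA_POS = 0.25
MARGARIA_NEG = -1.2
BASAL_RATE = 1.2  # W/kg


@dataclass
class MetabolicParams:
    eff_pos: float = MARGARIA_POS
    eff_neg: float = MARGARIA_NEG
    basal_rate: float = BASAL_RATE
    # alternative reading: multiply work by the coefficients instead of
    # dividing by them (kept available behind this switch)
    multiply_coefficients: bool = False

    def __post_init__(self) -> None:
        if self.eff_pos <= 0 or self.eff_neg >= 0 or self.basal_rate < 0:
            raise ValueError("need eff_pos > 0, eff_neg < 0, basal_rate >= 0")


@dataclass
class WorkLedger:
    """Per-muscle accumulated positive/negative fiber work (J)."""
    names: list[str]
    groups: list[str]
    w_pos: np.ndarray
    w_neg: np.ndarray

    @classmethod
    def empty(cls, names: list[str], groups: list[str]) -> "WorkLedger":
        return cls(names, groups, np.zeros(len(names)), np.zeros(len(names)))

    def __add__(self, other: "WorkLedger") -> "WorkLedger":
        assert self.names == other.names
        return WorkLedger(self.names, self.groups,
                          self.w_pos + other.w_pos, self.w_neg + other.w_neg)


def accumulate_work(ledger: WorkLedger, fiber_powers: np.ndarray,
                    dt: float) -> WorkLedger:
    """Add one time slice of fiber power to the ledger (rectangle rule)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    dW = np.asarray(fiber_powers, float) * dt
    return WorkLedger(ledger.names, ledger.groups,
                      ledger.w_pos + np.where(dW > 0, dW, 0.0),
                      ledger.w_neg + np.where(dW < 0, dW, 0.0))


def muscle_energy(w_pos, w_neg, params: MetabolicParams | None = None):
    """Metabolic energy (J) from accumulated positive/negative fiber work."""
    params = params or MetabolicParams()
    w_pos = np.asarray(w_pos, float)
    w_neg = np.asarray(w_neg, float)
    if np.any(w_pos < 0) or np.any(w_neg > 0):
        raise ValueError("need w_pos >= 0 and w_neg <= 0")
    if params.multiply_coefficients:
        E = params.eff_pos * w_pos + params.eff_neg * w_neg
    else:
        E = w_pos / params.eff_pos + w_neg / params.eff_neg
    return E if E.ndim else float(E)


def basal_energy(mass: float, duration: float,
                 params: MetabolicParams | None = None) -> float:
    """Basal metabolic energy over a simulation window (J)."""
    params = params or MetabolicParams()
    if mass <= 0 or duration <= 0:
        raise ValueError("mass and duration must be > 0")
    return params.basal_rate * mass * duration


def basal_cot(speed: float, params: MetabolicParams | None = None) -> float:
    """Basal cost of transport (J/kg-m) at a given running speed."""
    params = params or MetabolicParams()
    if speed <= 0:
        raise ValueError("cost of transport undefined at zero speed")
    return params.basal_rate / speed


def pontzer_cot(speed: float) -> float:
    """Empirical human running cost of transport: -0.06 v + 3.89 (J/kg-m)."""
    return -0.06 * speed + 3.89


@dataclass
class MetabolicReport:
    """Cost-of-transport partition for one simulated run."""
    group_energy: dict[str, float]       # J per muscle group
    group_cot: dict[str, float]          # J/kg-m per muscle group
    basal_cot: float
    gross_cot: float
    distance: float
    duration: float
    mean_speed: float
    body_mass: float

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        out = {f"cot_{g}": round(v, ndigits) for g, v in self.group_cot.items()}
        out["cot_basal"] = round(self.basal_cot, ndigits)
        out["cot_gross"] = round(self.gross_cot, ndigits)
        return out


def cost_of_transport(ledger: WorkLedger, mass: float, distance: float,
                      duration: float,
                      params: MetabolicParams | None = None) -> MetabolicReport:
    """Partitioned cost of transport from a work ledger.

    The gross CoT equals the sum of the per-group CoT plus the basal CoT
    exactly (before any display rounding).
    """
    params = params or MetabolicParams()
    if distance <= 0:
        raise ValueError("distance must be > 0")
    speed = distance / duration
    group_E = {g: 0.0 for g in MUSCLE_GROUPS}
    if len(ledger.names):
        E = np.atleast_1d(muscle_energy(ledger.w_pos, ledger.w_neg, params))
        for g, e in zip(ledger.groups, E):
            group_E[g] += float(e)
    group_cot = {g: e / (mass * distance) for g, e in group_E.items()}
    b_cot = basal_energy(mass, duration, params) / (mass * distance)
    gross = sum(group_cot.values()) + b_cot
    return MetabolicReport(group_E, group_cot, b_cot, gross,
                           distance, duration, speed, mass)


# ---------------------------------------------------------------------------
# gait events and curves
# ---------------------------------------------------------------------------

def detect_gait_events(grf_z: np.ndarray, dt: float, threshold: float = 20.0,
                       debounce: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Heel strikes (upward crossings) and toe-offs (downward crossings).

    A crossing only counts when the signal dwells on the new side of the
    threshold: the median over the following ``debounce`` window must agree
    with the crossing direction.  Events strictly alternate per foot.
    Returned values are sample times (s).
    """
    z = np.asarray(grf_z, float)
    w = max(1, int(round(debounce / dt)))
    above = z >= threshold
    up = np.flatnonzero(~above[:-1] & above[1:]) + 1
    down = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    events = sorted([(int(i), "hs") for i in up] + [(int(i), "to") for i in down])
    hs, to = [], []
    in_stance = bool(above[0])
    for i, kind in events:
        med = float(np.median(z[i:i + w]))
        if kind == "hs" and not in_stance and med >= threshold:
            hs.append(i * dt)
            in_stance = True
        elif kind == "to" and in_stance and med < threshold:
            to.append(i * dt)
            in_stance = False
    return np.asarray(hs), np.asarray(to)


def stance_intervals(hs: np.ndarray, to: np.ndarray) -> list[tuple[float, float]]:
    """Pair each heel strike with the next toe-off."""
    out = []
    for t0 in hs:
        later = to[to > t0]
        if later.size:
            out.append((float(t0), float(later[0])))
    return out


def normalize_stance(trace: np.ndarray, dt: float,
                     interval: tuple[float, float],
                     n_points: int = 101) -> np.ndarray:
    """Resample a trace over a stance interval onto 0-100% stance.

    Linear interpolation; the first/last points coincide with the trace
    values at the interval endpoints.
    """
    trace = np.asarray(trace, float)
    t0, t1 = interval
    times = np.arange(len(trace)) * dt
    if t0 < times[0] - 1e-12 or t1 > times[-1] + 1e-12:
        raise ValueError("stance interval outside the trace")
    if (t1 - t0) < 2 * dt:
        raise ValueError("stance interval shorter than two samples")
    ts = np.linspace(t0, t1, n_points)
    return np.interp(ts, times, trace)


def torso_longitudinal_rotation(model, q_traj: np.ndarray,
                                cycles: list[tuple[float, float]] | None = None,
                                dt: float | None = None) -> tuple[np.ndarray, float]:
    """Thorax-relative-to-pelvis rotation about the pelvis vertical axis.

    Decomposes R_pelvis^T R_torso as an intrinsic Z-X-Y triplet and takes the
    Z (longitudinal) component.  Returns the angle trace in degrees and its
    range (max - min); with ``cycles`` given, the range is the mean of
    per-cycle ranges.
    """
    from .dynamics import Kinematics
    if "torso" not in model.body_index:
        raise ValueError("model has no torso body")
    rb, tb = model._root_body, model.body_index["torso"]
    u0 = np.zeros(model.n_u)
    angles = np.empty(len(q_traj))
    for i, q in enumerate(q_traj):
        kin = Kinematics(model, q, u0)
        R_rel = kin.R[rb].T @ kin.R[tb]
        angles[i] = mat_to_euler_zxy(R_rel)[0]
    angles = np.degrees(angles)
    if cycles and dt:
        ranges = []
        for t0, t1 in cycles:
            i0, i1 = int(round(t0 / dt)), int(round(t1 / dt))
            if i1 - i0 >= 2:
                seg = angles[i0:i1 + 1]
                ranges.append(seg.max() - seg.min())
        rng = float(np.mean(ranges)) if ranges else float(angles.max() - angles.min())
    else:
        rng = float(angles.max() - angles.min()) if len(angles) else 0.0
    return angles, rng


def rms_difference(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Root mean squared pointwise difference of two curves."""
    a = np.asarray(curve_a, float)
    b = np.asarray(curve_b, float)
    if a.shape != b.shape:
        raise ValueError(f"curve shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


# ---------------------------------------------------------------------------
# report assembly from trajectory logs
# ---------------------------------------------------------------------------

@dataclass
class GaitReport:
    heel_strikes: dict[str, np.ndarray]
    toe_offs: dict[str, np.ndarray]
    stance: dict[str, list[tuple[float, float]]]
    grf_curves: dict[str, np.ndarray]     # foot -> (n_curves, 3, 101)
    torso_yaw_trace: np.ndarray           # deg
    torso_yaw_range: float                # deg
    mean_speed: float


def analyze_log(model, log, threshold: float = 20.0,
                debounce: float = 0.05) -> tuple[MetabolicReport, GaitReport]:
    """Full metabolic + gait analysis of one rollout log."""
    ledger = WorkLedger(log.muscle_names, log.muscle_groups,
                        log.work_pos, log.work_neg)
    met = cost_of_transport(ledger, log.total_mass, max(log.distance, 1e-9),
                            log.duration)
    hs, to, stance, curves = {}, {}, {}, {}
    dt = log.dt_control
    for foot, f in log.grf.items():
        hs[foot], to[foot] = detect_gait_events(f[:, 2], dt, threshold, debounce)
        stance[foot] = stance_intervals(hs[foot], to[foot])
        cs = []
        for iv in stance[foot]:
            try:
                cs.append(np.stack([normalize_stance(f[:, k], dt, iv)
                                    for k in range(3)]))
            except ValueError:
                continue
        curves[foot] = np.array(cs) if cs else np.empty((0, 3, 101))
    cyc = None
    if "right" in hs and len(hs["right"]) > 1:
        cyc = list(zip(hs["right"][:-1], hs["right"][1:]))
    trace, yaw_range = torso_longitudinal_rotation(model, log.q, cycles=cyc, dt=dt)
    gait = GaitReport(hs, to, stance, curves, trace, yaw_range, log.mean_speed)
    return met, gait
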
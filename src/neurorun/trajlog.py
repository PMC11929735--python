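"""Trajectory logs: in-memory container plus HDF5 / CSV export."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class TrajectoryLog:
    """Rollout record sampled at the control rate.

    ``q``/``u`` have one more row than the per-step arrays (they include the
    initial state).  ``work_pos``/``work_neg`` are per-muscle fiber work
    integrals accumulated at the physics rate over the whole rollout (J;
    ``work_neg`` is non-positive).
    """
    dt_control: float
    times: np.ndarray                 # (T+1,)
    q: np.ndarray                     # (T+1, n_q)
    u: np.ndarray                     # (T+1, n_u)
    excitations: np.ndarray           # (T, m) commanded, full muscle set
    activations: np.ndarray           # (T, m)
    grf: dict[str, np.ndarray]        # foot -> (T, 3)
    cop: dict[str, np.ndarray]        # foot -> (T, 3)
    rewards: np.ndarray               # (T,)
    fiber_power: np.ndarray           # (T, m) instantaneous, W
    work_pos: np.ndarray              # (m,) J
    work_neg: np.ndarray              # (m,) J, <= 0
    muscle_names: list[str]
    muscle_groups: list[str]
    coord_names: list[str]
    total_mass: float
    fell: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def distance(self) -> float:
        """Forward pelvis displacement, m."""
        return float(self.q[-1, 4] - self.q[0, 4])

    @property
    def mean_speed(self) -> float:
        return self.distance / self.duration if self.duration > 0 else 0.0

    # -- persistence ----------------------------------------------------
    def save_hdf5(self, path: str | Path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            st = f.create_group("states")
            st["times"] = self.times
            st["q"] = self.q
            st["u"] = self.u
            g = f.create_group("grf")
            for foot in self.grf:
                g[f"force_{foot}"] = self.grf[foot]
                g[f"cop_{foot}"] = self.cop[foot]
            a = f.create_group("activations")
            a["activations"] = self.activations
            a["excitations"] = self.excitations
            a["fiber_power"] = self.fiber_power
            a["work_pos"] = self.work_pos
            a["work_neg"] = self.work_neg
            r = f.create_group("rewards")
            r["rewards"] = self.rewards
            f.attrs["dt_control"] = self.dt_control
            f.attrs["total_mass"] = self.total_mass
            f.attrs["fell"] = self.fell
            f.attrs["muscle_names"] = ",".join(self.muscle_names)
            f.attrs["muscle_groups"] = ",".join(self.muscle_groups)
            f.attrs["coord_names"] = ",".join(self.coord_names)
            for k, v in self.meta.items():
                f.attrs[f"meta_{k}"] = v

    @classmethod
    def load_hdf5(cls, path: str | Path) -> "TrajectoryLog":
        import h5py
        with h5py.File(path, "r") as f:
            feet = sorted({k.split("_", 1)[1] for k in f["grf"]})
            meta = {k[5:]: (v.item() if hasattr(v, "item") and getattr(v, "ndim", 0) == 0 else v)
                    for k, v in f.attrs.items() if k.startswith("meta_")}
            return cls(
                dt_control=float(f.attrs["dt_control"]),
                times=f["states/times"][:], q=f["states/q"][:], u=f["states/u"][:],
                excitations=f["activations/excitations"][:],
                activations=f["activations/activations"][:],
                grf={ft: f[f"grf/force_{ft}"][:] for ft in feet},
                cop={ft: f[f"grf/cop_{ft}"][:] for ft in feet},
                rewards=f["rewards/rewards"][:],
                fiber_power=f["activations/fiber_power"][:],
                work_pos=f["activations/work_pos"][:],
                work_neg=f["activations/work_neg"][:],
                muscle_names=str(f.attrs["muscle_names"]).split(","),
                muscle_groups=str(f.attrs["muscle_groups"]).split(","),
                coord_names=str(f.attrs["coord_names"]).split(","),
                total_mass=float(f.attrs["total_mass"]),
                fell=bool(f.attrs["fell"]),
                meta=meta,
            )

    def to_csv(self, path: str | Path) -> None:
        """Flat CSV export of the state trajectory + per-foot GRF."""
        import pandas as pd
        cols = {"time": self.times[:-1]}
        for j, n in enumerate(self.coord_names):
            cols[f"q_{n}"] = self.q[:-1, 7 + j]
        for foot in self.grf:
            for k, ax in enumerate("xyz"):
                cols[f"grf_{foot}_{ax}"] = self.grf[foot][:, k]
        pd.DataFrame(cols).to_csv(path, index=False)
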
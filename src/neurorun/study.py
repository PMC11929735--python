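"""The three-condition arm-swing study pipeline.

Protocol: train a reference (active arm swing) excitation controller by PPO
imitation, warm-start and retrain it for the fixed-arm and passive-arm
conditions (half the reference update budget, mirroring the original
40,000/80,000 split), evaluate each controller with a deterministic rollout,
and compare metabolic cost-of-transport partitions and torso longitudinal
rotation across conditions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .analysis import GaitReport, MetabolicReport, analyze_log
from .conditions import retrain
from .config import Experiment
from .envsim import rollout
from .nets import Controller
from .rl import TrainLog, train
from .trajlog import TrajectoryLog

CONDITION_ORDER = ("active", "fixed", "passive")


@dataclass
class ConditionResult:
    condition: str
    controller: Controller
    train_log: TrainLog
    trajectory: TrajectoryLog
    metabolic: MetabolicReport
    gait: GaitReport


@dataclass
class StudyResult:
    results: dict[str, ConditionResult] = field(default_factory=dict)

    def gross_cot(self) -> dict[str, float]:
        return {c: r.metabolic.gross_cot for c, r in self.results.items()}

    def torso_yaw_range(self) -> dict[str, float]:
        return {c: r.gait.torso_yaw_range for c, r in self.results.items()}

    def mean_speed(self) -> dict[str, float]:
        return {c: r.metabolic.mean_speed for c, r in self.results.items()}


def run_condition_study(base_cfg: dict, seed: int = 0,
                        eval_duration: float | None = None,
                        eval_phase: float = 0.0) -> StudyResult:
    """Run the full three-condition pipeline at the sizes in ``base_cfg``.

    The reference controller trains for ``ppo.n_updates`` updates; each
    condition controller retrains from it for ``retrain_updates``.  Returns
    per-condition trajectories and analyses.
    """
    out = StudyResult()
    reference_ctrl: Controller | None = None
    for cond in CONDITION_ORDER:
        cfg = dict(base_cfg, condition=cond)
        exp = Experiment(cfg)
        ppo = exp.ppo_config(seed=seed + {"active": 0, "fixed": 1, "passive": 2}[cond])
        if cond == "active":
            labels, names = exp.controller_labels()
            ctrl = Controller.create(labels, names, hidden=ppo.hidden,
                                     seed=ppo.seed, meta=exp.meta(seed))
            ctrl, tlog = train(exp.make_env, ctrl, ppo)
            reference_ctrl = ctrl
        else:
            assert reference_ctrl is not None
            import dataclasses
            ppo = dataclasses.replace(ppo, n_updates=exp.retrain_updates)
            ctrl, tlog = retrain(reference_ctrl, exp.make_env, ppo)
        ctrl.meta.update(exp.meta(seed))
        ctrl.meta["condition"] = cond

        env = exp.make_env(seed=seed + 1000)
        dur = eval_duration if eval_duration is not None else float(cfg["duration"])
        traj = rollout(env, ctrl, dur, start_phase=eval_phase)
        met, gait = analyze_log(exp.model, traj)
        out.results[cond] = ConditionResult(cond, ctrl, tlog, traj, met, gait)
    return out
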
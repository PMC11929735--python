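"""Experiment configuration: YAML profiles, overrides, and orchestration.

A run configuration is a nested dict (YAML on disk) with dotted-path CLI
overrides.  :class:`Experiment` ties the pieces together for one arm
condition: model + condition application, muscle system, reference motion,
reward, environment factory and PPO configuration.  Every output artifact
embeds the config fingerprint and seed.
"""
from __future__ import annotations

import copy
import hashlib
import importlib.resources
from pathlib import Path

import yaml

from .bodymodels import builtin_model_config
from .conditions import apply_condition, arm_condition
from .contact import ContactParams
from .controller import RewardWeights
from .envsim import RunningEnv, SimParams, Termination
from .muscle import MuscleSystem
from .reference import GaitParams, generate_reference
from .rl import PPOConfig
from .skeleton import build_model


class ConfigError(ValueError):
    pass


DEFAULTS: dict = {
    "model": "builtin:desk",
    "condition": "active",
    "seed": 0,
    "duration": 20.0,          # evaluation rollout length, s
    "sim": {"dt": 1e-3, "substeps": 33, "joint_damping": 0.5,
            "limit_stiffness": 50.0, "limit_damping": 2.0},
    "contact": {"k_n": 5e5, "c_n": 1.0, "mu": 0.9, "v_reg": 0.05},
    "termination": {"min_height_frac": 0.6, "max_tilt_deg": 60.0},
    "gait": {},                # GaitParams overrides
    "reward": {},              # RewardWeights overrides
    "ppo": {},                 # PPOConfig overrides
    "retrain_updates": None,   # default: half the reference updates
    "output_dir": "runs",
}


def _deep_merge(base: dict, extra: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def _parse_override(expr: str) -> tuple[list[str], object]:
    if "=" not in expr:
        raise ConfigError(f"override {expr!r} must look like key.path=value")
    key, _, raw = expr.partition("=")
    try:
        val = yaml.safe_load(raw)
    except yaml.YAMLError:
        val = raw
    return key.strip().split("."), val


def load_config(source: str | Path | dict | None = None,
                overrides: list[str] = ()) -> dict:
    """Merge defaults <- profile file/dict <- dotted CLI overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if source is not None:
        if isinstance(source, dict):
            user = source
        else:
            p = Path(source)
            if not p.exists():
                raise ConfigError(f"config file not found: {p}")
            with open(p) as fh:
                user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    for expr in overrides:
        path, val = _parse_override(expr)
        node = cfg
        for k in path[:-1]:
            node = node.setdefault(k, {})
            if not isinstance(node, dict):
                raise ConfigError(f"cannot descend into {'.'.join(path)}")
        node[path[-1]] = val
    if cfg["condition"] not in ("active", "fixed", "passive"):
        raise ConfigError(f"invalid condition {cfg['condition']!r}")
    return cfg


def load_profile(name: str) -> dict:
    """Load a packaged profile (``desk`` or ``fullscale``)."""
    ref = importlib.resources.files("neurorun") / "profiles" / f"{name}.yaml"
    with ref.open() as fh:
        return yaml.safe_load(fh)


def fingerprint(cfg: dict) -> str:
    canon = yaml.safe_dump(cfg, sort_keys=True, default_flow_style=True)
    return hashlib.sha1(canon.encode()).hexdigest()[:12]


class Experiment:
    """All objects needed to train/simulate one arm condition."""

    def __init__(self, cfg: dict):
        self.cfg = cfg
        self.fingerprint = fingerprint(cfg)
        spec = cfg["model"]
        if isinstance(spec, str) and spec.startswith("builtin:"):
            model_cfg = builtin_model_config(spec.split(":", 1)[1])
        else:
            if not Path(spec).exists():
                raise ConfigError(f"model file not found: {spec}")
            model_cfg = spec
        base_model = build_model(model_cfg)

        base_weights = RewardWeights(**cfg["reward"])
        cond = arm_condition(cfg["condition"], base_model)
        app = apply_condition(base_model, base_weights, cond)
        self.condition = cond
        self.model = app.model
        self.weights = app.weights
        self.enabled = app.enabled_muscles
        self.muscles = MuscleSystem(self.model)
        self.gait = GaitParams(**cfg["gait"])
        self.reference = generate_reference(self.gait, self.model)
        self.contact = ContactParams(**cfg["contact"])
        self.sim = SimParams(**cfg["sim"])
        self.termination = Termination(**cfg["termination"])

    def make_env(self, seed: int = 0) -> RunningEnv:
        return RunningEnv(self.model, self.muscles, self.reference, self.weights,
                          contact=self.contact, sim=self.sim,
                          termination=self.termination,
                          enabled_muscles=self.enabled, seed=seed)

    def ppo_config(self, seed: int | None = None,
                   n_updates: int | None = None) -> PPOConfig:
        kw = dict(self.cfg["ppo"])
        if "hidden" in kw:
            kw["hidden"] = tuple(kw["hidden"])
        if seed is not None:
            kw["seed"] = seed
        if n_updates is not None:
            kw["n_updates"] = n_updates
        return PPOConfig(**kw)

    @property
    def retrain_updates(self) -> int:
        if self.cfg.get("retrain_updates") is not None:
            return int(self.cfg["retrain_updates"])
        return max(1, self.ppo_config().n_updates // 2)

    def controller_labels(self) -> tuple[list[str], list[str]]:
        env = self.make_env(0)
        labels = env.obs_spec.labels()
        names = [n for n, on in zip(self.muscles.names, self.enabled) if on]
        return labels, names

    def meta(self, seed: int) -> dict:
        return {"fingerprint": self.fingerprint, "seed": int(seed),
                "condition": self.cfg["condition"]}
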
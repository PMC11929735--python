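"""Proximal-policy-optimization training of excitation controllers.

Standard clipped-surrogate PPO with generalized advantage estimation: a batch
of on-policy samples is collected from ``n_envs`` sequentially stepped
environments, advantages are normalized per batch, and the policy/value
networks take several epochs of minibatch Adam updates.  Everything is
deterministic given (seed, single thread).

The full-scale configuration of the source experiments (200 environments,
80,000 samples per update, 80,000 reference updates + 40,000 retraining
updates) is kept available as config values; the shipped desk-scale profile
uses far smaller counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nets import Adam, Controller

__all__ = ["PPOConfig", "gae", "ppo_update", "train", "TrainLog", "clipped_surrogate"]


@dataclass
class PPOConfig:
    n_envs: int = 8
    episode_length: float = 4.0        # s
    samples_per_update: int = 2048
    n_updates: int = 300
    clip_eps: float = 0.2
    gamma: float = 0.99
    gae_lambda: float = 0.95
    learning_rate: float = 3e-4
    minibatch_size: int = 256
    epochs: int = 4
    entropy_coef: float = 1e-3
    hidden: tuple[int, ...] = (256, 256)
    seed: int = 0

    # documentation values of the full-scale experiment
    FULLSCALE: dict = field(default_factory=lambda: {
        "n_envs": 200, "episode_length": 4.0, "samples_per_update": 80000,
        "n_updates": 80000, "retrain_updates": 40000})

    def __post_init__(self) -> None:
        if not (0 < self.gamma <= 1 and 0 < self.gae_lambda <= 1):
            raise ValueError("gamma and gae_lambda must lie in (0, 1]")
        horizon = self.samples_per_update // self.n_envs
        if horizon * self.n_envs != self.samples_per_update:
            raise ValueError("samples_per_update must be divisible by n_envs")
        if self.samples_per_update % self.minibatch_size:
            raise ValueError("samples_per_update must be divisible by minibatch_size")


def gae(rewards: np.ndarray, values: np.ndarray, terminals: np.ndarray,
        gamma: float, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Generalized advantage estimation over one trajectory.

    ``values`` has one more entry than ``rewards`` (bootstrap value of the
    state after the last step); ``terminals[t]`` True means the episode ended
    at step t (the successor value is treated as zero).  Returns
    ``(advantages, returns)`` with ``returns = advantages + values[:-1]``.
    """
    rewards = np.asarray(rewards, float)
    values = np.asarray(values, float)
    terminals = np.asarray(terminals, bool)
    T = len(rewards)
    if len(values) != T + 1 or len(terminals) != T:
        raise ValueError("need len(values) == len(rewards)+1 == len(terminals)+1")
    adv = np.empty(T)
    acc = 0.0
    for t in range(T - 1, -1, -1):
        nonterm = 0.0 if terminals[t] else 1.0
        delta = rewards[t] + gamma * values[t + 1] * nonterm - values[t]
        acc = delta + gamma * lam * nonterm * acc
        adv[t] = acc
    return adv, adv + values[:-1]


def clipped_surrogate(ratio, advantage, eps: float):
    """Per-sample clipped PPO objective: min(r A, clip(r, 1-eps, 1+eps) A)."""
    ratio = np.asarray(ratio, float)
    advantage = np.asarray(advantage, float)
    return np.minimum(ratio * advantage,
                      np.clip(ratio, 1.0 - eps, 1.0 + eps) * advantage)


@dataclass
class UpdateDiagnostics:
    policy_loss: float
    value_loss: float
    clip_fraction: float
    approx_kl: float


def ppo_update(batch: dict, controller: Controller, config: PPOConfig,
               optimizers: tuple[Adam, Adam] | None = None,
               rng: np.random.Generator | None = None) -> UpdateDiagnostics:
    """One PPO update: several epochs of clipped-surrogate minibatch SGD.

    ``batch`` needs keys ``obs`` (N,d), ``raw`` (N,m) pre-squash actions,
    ``logp`` (N,), ``adv`` (N,), ``ret`` (N,).  Advantages are normalized
    per batch.  Raises no update on non-finite gradients (aborts with the
    diagnostics computed so far).
    """
    rng = rng or np.random.default_rng(0)
    pol, val = controller.policy, controller.value
    if optimizers is None:
        optimizers = (Adam(pol.params, lr=config.learning_rate),
                      Adam(val.params, lr=config.learning_rate))
    opt_pol, opt_val = optimizers

    obs, raw = batch["obs"], batch["raw"]
    logp_old, adv, ret = batch["logp"], batch["adv"], batch["ret"]
    N = len(obs)
    if N < config.minibatch_size:
        raise ValueError("batch smaller than minibatch size")
    adv_n = (adv - adv.mean()) / (adv.std() + 1e-8)

    eps = config.clip_eps
    clip_frac = kl = pl = vl = 0.0
    nmb = 0
    for _ in range(config.epochs):
        perm = rng.permutation(N)
        for start in range(0, N - config.minibatch_size + 1, config.minibatch_size):
            idx = perm[start:start + config.minibatch_size]
            o, a, lp0, A, R = obs[idx], raw[idx], logp_old[idx], adv_n[idx], ret[idx]
            n = len(idx)

            mean = pol.mlp.forward(o, cache=True)
            std = np.exp(pol.log_std)
            z = (a - mean) / std
            logp = -0.5 * (z * z).sum(axis=1) - pol.log_std.sum() \
                - 0.5 * pol.act_dim * np.log(2 * np.pi)
            ratio = np.exp(np.clip(logp - lp0, -20, 20))
            pl_mb = -clipped_surrogate(ratio, A, eps).mean()

            # gradient flows only through the active unclipped branch
            active = ((A >= 0) & (ratio <= 1 + eps)) | ((A < 0) & (ratio >= 1 - eps))
            g = np.where(active, ratio * A, 0.0) / n           # dL/dlogp * (-1)
            dmean = -(g[:, None] * z / std)                    # dL/dmean
            dlogstd = -(g[:, None] * (z * z - 1.0)).sum(axis=0)
            dlogstd -= config.entropy_coef                     # entropy bonus
            grads = pol.mlp.backward(dmean) + [dlogstd]
            if all(np.all(np.isfinite(gr)) for gr in grads):
                opt_pol.step(pol.params, grads)

            v = val.forward(o, cache=True)[:, 0]
            vl_mb = float(np.mean((v - R) ** 2))
            dv = (2.0 * (v - R) / n)[:, None]
            vgrads = val.backward(dv)
            if all(np.all(np.isfinite(gr)) for gr in vgrads):
                opt_val.step(val.params, vgrads)

            clip_frac += float(np.mean(np.abs(ratio - 1) > eps))
            kl += float(np.mean(lp0 - logp))
            pl += float(pl_mb)
            vl += vl_mb
            nmb += 1
    nmb = max(nmb, 1)
    return UpdateDiagnostics(pl / nmb, vl / nmb, clip_frac / nmb, kl / nmb)


@dataclass
class TrainLog:
    """Per-update training statistics (one row per update)."""
    rows: list[dict] = field(default_factory=list)

    def append(self, **kw) -> None:
        self.rows.append(kw)

    def column(self, key: str) -> np.ndarray:
        return np.array([r[key] for r in self.rows])

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.rows).to_csv(path, index=False)


def _collect(envs, controller: Controller, config: PPOConfig,
             rng: np.random.Generator):
    """Lockstep on-policy collection across environments."""
    horizon = config.samples_per_update // config.n_envs
    n_envs = len(envs)
    d = len(envs[0].obs_spec)
    m = controller.policy.act_dim
    obs_buf = np.empty((horizon, n_envs, d))
    raw_buf = np.empty((horizon, n_envs, m))
    logp_buf = np.empty((horizon, n_envs))
    rew_buf = np.empty((horizon, n_envs))
    term_buf = np.zeros((horizon, n_envs), dtype=bool)
    val_buf = np.empty((horizon + 1, n_envs))

    obs = np.stack([e._cur_obs for e in envs])
    stats = {"reward": [], "r_track": [], "r_act": [], "speed": [], "ep_len": []}
    for t in range(horizon):
        obs_buf[t] = obs
        exc, raw, logp = controller.policy.sample(obs, rng)
        raw_buf[t], logp_buf[t] = raw, logp
        val_buf[t] = controller.value.forward(obs)[:, 0]
        for k, env in enumerate(envs):
            o2, r, done, info = env.step(exc[k])
            rew_buf[t, k] = r
            stats["reward"].append(r)
            stats["r_track"].append(info.get("r_track", 0.0))
            stats["r_act"].append(info.get("r_act", 0.0))
            stats["speed"].append(info.get("speed", 0.0))
            if done:
                term_buf[t, k] = True
                stats["ep_len"].append(getattr(env, "_ep_time", 0.0))
                o2 = env.reset()
            obs[k] = o2
            env._cur_obs = o2
    val_buf[horizon] = controller.value.forward(obs)[:, 0]

    adv = np.empty((horizon, n_envs))
    ret = np.empty((horizon, n_envs))
    for k in range(n_envs):
        adv[:, k], ret[:, k] = gae(rew_buf[:, k], val_buf[:, k], term_buf[:, k],
                                   config.gamma, config.gae_lambda)
    batch = {
        "obs": obs_buf.reshape(-1, d), "raw": raw_buf.reshape(-1, m),
        "logp": logp_buf.ravel(), "adv": adv.ravel(), "ret": ret.ravel(),
    }
    summary = {k: (float(np.mean(v)) if v else 0.0) for k, v in stats.items()}
    return batch, summary


def train(make_env, controller: Controller, config: PPOConfig,
          log: TrainLog | None = None,
          checkpoint_path=None, checkpoint_every: int = 0) -> tuple[Controller, TrainLog]:
    """PPO training loop.

    ``make_env(seed)`` builds one environment exposing ``reset``/``step`` and
    an ``obs_spec``.  Deterministic given ``config.seed`` and a single
    thread.  With ``n_updates == 0`` the controller is returned untouched.
    """
    log = log or TrainLog()
    rng = np.random.default_rng(config.seed)
    envs = [make_env(int(rng.integers(2 ** 31 - 1))) for _ in range(config.n_envs)]
    for e in envs:
        e.episode_length = config.episode_length
        e._cur_obs = e.reset()
    opts = (Adam(controller.policy.params, lr=config.learning_rate),
            Adam(controller.value.params, lr=config.learning_rate))
    for update in range(config.n_updates):
        batch, summary = _collect(envs, controller, config, rng)
        diag = ppo_update(batch, controller, config, optimizers=opts, rng=rng)
        log.append(update=update, mean_reward=summary["reward"],
                   tracking=summary["r_track"], activation=summary["r_act"],
                   mean_speed=summary["speed"], episode_length=summary["ep_len"],
                   policy_loss=diag.policy_loss, value_loss=diag.value_loss,
                   clip_fraction=diag.clip_fraction, approx_kl=diag.approx_kl)
        if checkpoint_path and checkpoint_every and (update + 1) % checkpoint_every == 0:
            controller.save(checkpoint_path)
    return controller, log
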
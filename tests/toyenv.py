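"""A 1-D LQR-like point-mass task used to smoke-test the PPO machinery."""
from __future__ import annotations

import numpy as np


class _Spec:
    def __init__(self, n):
        self.n = n

    def __len__(self):
        return self.n


class PointMassEnv:
    """State (x, v); action in [0,1] maps to force in [-2, 2]; reward is
    highest when the mass is parked at the origin."""

    def __init__(self, seed: int = 0, horizon: int = 50):
        self.rng = np.random.default_rng(seed)
        self.obs_spec = _Spec(2)
        self.horizon = horizon
        self.episode_length = horizon  # steps, reused by the trainer
        self.dt = 0.1

    def reset(self):
        self.x = float(self.rng.uniform(-1.0, 1.0))
        self.v = 0.0
        self.steps = 0
        return np.array([self.x, self.v])

    def step(self, action):
        force = 4.0 * (float(np.asarray(action).ravel()[0]) - 0.5)
        self.v += force * self.dt
        self.x += self.v * self.dt
        self.steps += 1
        reward = 1.0 - min(self.x * self.x + 0.1 * self.v * self.v, 2.0)
        done = self.steps >= self.horizon
        return np.array([self.x, self.v]), reward, done, {}
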
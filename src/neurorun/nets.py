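"""Minimal dense neural networks with manual backpropagation.

Provides the MLP policy/value function approximators, a diagonal-Gaussian
policy head squashed through a sigmoid (excitations live in [0, 1]; the
Gaussian exploration noise acts in pre-squash space), and an Adam optimizer.
Everything is plain numpy so training is single-threaded and bitwise
reproducible given a seed.
"""
from __future__ import annotations

import io
import json

import numpy as np

_LOG_2PI = float(np.log(2.0 * np.pi))


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class MLP:
    """Tanh MLP with a linear output layer and cached-forward backprop."""

    def __init__(self, sizes: list[int], rng: np.random.Generator | None = None,
                 out_scale: float = 0.01):
        self.sizes = list(sizes)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        rng = rng or np.random.default_rng(0)
        for i, (nin, nout) in enumerate(zip(sizes[:-1], sizes[1:])):
            scale = out_scale if i == len(sizes) - 2 else np.sqrt(2.0 / nin)
            self.W.append(rng.normal(0.0, scale, size=(nin, nout)))
            self.b.append(np.zeros(nout))
        self._cache: list[np.ndarray] | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        h = np.atleast_2d(x)
        acts = [h]
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < last:
                h = np.tanh(h)
            acts.append(h)
        if cache:
            self._cache = acts
        return h

    def backward(self, dy: np.ndarray) -> list[np.ndarray]:
        """Gradients of sum(dy * output) w.r.t. params; call after a cached
        forward pass."""
        assert self._cache is not None, "forward(cache=True) first"
        acts = self._cache
        gW = [np.empty(0)] * len(self.W)
        gb = [np.empty(0)] * len(self.b)
        grad = np.atleast_2d(dy)
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = acts[i].T @ grad
            gb[i] = grad.sum(axis=0)
            if i > 0:
                grad = (grad @ self.W[i].T) * (1.0 - acts[i] ** 2)
        return gW + gb


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 3e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class GaussianPolicy:
    """Diagonal Gaussian over pre-squash actions; excitation = sigmoid(raw)."""

    def __init__(self, obs_dim: int, act_dim: int, hidden: list[int],
                 rng: np.random.Generator | None = None,
                 init_log_std: float = -1.0, init_bias: float = -1.5):
        self.mlp = MLP([obs_dim] + list(hidden) + [act_dim], rng)
        # bias the mean low so initial excitations are gentle
        self.mlp.b[-1][:] = init_bias
        self.log_std = np.full(act_dim, init_log_std)
        self.obs_dim, self.act_dim = obs_dim, act_dim

    @property
    def params(self) -> list[np.ndarray]:
        return self.mlp.params + [self.log_std]

    def sample(self, obs: np.ndarray, rng: np.random.Generator):
        """Returns (excitations, raw actions, log-probabilities)."""
        mean = self.mlp.forward(obs)
        std = np.exp(self.log_std)
        raw = mean + std * rng.standard_normal(mean.shape)
        logp = self.log_prob_given_mean(mean, raw)
        return _sigmoid(raw), raw, logp

    def mean_action(self, obs: np.ndarray) -> np.ndarray:
        return _sigmoid(self.mlp.forward(obs))

    def log_prob_given_mean(self, mean: np.ndarray, raw: np.ndarray) -> np.ndarray:
        z = (raw - mean) / np.exp(self.log_std)
        return (-0.5 * (z * z).sum(axis=-1)
                - self.log_std.sum()
                - 0.5 * self.act_dim * _LOG_2PI)

    def log_prob(self, obs: np.ndarray, raw: np.ndarray,
                 cache: bool = False) -> np.ndarray:
        return self.log_prob_given_mean(self.mlp.forward(obs, cache=cache), raw)


class Controller:
    """Policy + value networks plus the metadata needed to re-wire them.

    ``obs_labels`` name every observation entry and ``muscle_names`` name the
    enabled (excitation-controlled) muscles; warm-start surgery across arm
    conditions matches parameters through these labels.
    """

    def __init__(self, policy: GaussianPolicy, value: MLP,
                 obs_labels: list[str], muscle_names: list[str],
                 meta: dict | None = None):
        if policy.act_dim != len(muscle_names):
            raise ValueError("policy output dimension must equal enabled muscle count")
        self.policy = policy
        self.value = value
        self.obs_labels = list(obs_labels)
        self.muscle_names = list(muscle_names)
        self.meta = dict(meta or {})

    @classmethod
    def create(cls, obs_labels: list[str], muscle_names: list[str],
               hidden: list[int] = (256, 256), seed: int = 0,
               meta: dict | None = None) -> "Controller":
        rng = np.random.default_rng(seed)
        pol = GaussianPolicy(len(obs_labels), len(muscle_names), list(hidden), rng)
        val = MLP([len(obs_labels)] + list(hidden) + [1], rng, out_scale=0.1)
        return cls(pol, val, obs_labels, muscle_names, meta)

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        arch = {
            "format": 1,
            "obs_labels": self.obs_labels,
            "muscle_names": self.muscle_names,
            "hidden": self.policy.mlp.sizes[1:-1],
            "meta": self.meta,
        }
        arrays = {"log_std": self.policy.log_std}
        for i, (W, b) in enumerate(zip(self.policy.mlp.W, self.policy.mlp.b)):
            arrays[f"pW{i}"], arrays[f"pb{i}"] = W, b
        for i, (W, b) in enumerate(zip(self.value.W, self.value.b)):
            arrays[f"vW{i}"], arrays[f"vb{i}"] = W, b
        with open(path, "wb") as fh:
            fh.write(json.dumps(arch).encode() + b"\n")
            buf = io.BytesIO()
            np.savez(buf, **arrays)
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path) -> "Controller":
        with open(path, "rb") as fh:
            arch = json.loads(fh.readline().decode())
            data = np.load(io.BytesIO(fh.read()))
        if arch.get("format") != 1:
            raise ValueError(f"unsupported checkpoint format: {arch.get('format')!r}")
        ctrl = cls.create(arch["obs_labels"], arch["muscle_names"],
                          hidden=arch["hidden"], meta=arch.get("meta"))
        ctrl.policy.log_std[:] = data["log_std"]
        for i in range(len(ctrl.policy.mlp.W)):
            ctrl.policy.mlp.W[i][:] = data[f"pW{i}"]
            ctrl.policy.mlp.b[i][:] = data[f"pb{i}"]
        for i in range(len(ctrl.value.W)):
            ctrl.value.W[i][:] = data[f"vW{i}"]
            ctrl.value.b[i][:] = data[f"vb{i}"]
        return ctrl

    def params_equal(self, other: "Controller") -> bool:
        a, b = self.policy.params + self.value.params, other.policy.params + other.value.params
        return (len(a) == len(b)
                and all(x.shape == y.shape and np.array_equal(x, y) for x, y in zip(a, b)))
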
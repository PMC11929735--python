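"""Independent brute-force/symbolic oracles used by the test suite.

The chain oracle derives the equations of motion of a planar n-link pendulum
(revolute +Y joints, links hanging along -Z) symbolically from the Lagrangian
with sympy, independently of the package's recursive dynamics.
"""
from __future__ import annotations

import numpy as np
import sympy as sp


def chain_config(lengths, masses, coms, iyy, g=9.81):
    """Model-config dict for a world-anchored serial chain of Y-revolutes."""
    bodies, joints = [], []
    for i, (L, m, c, I) in enumerate(zip(lengths, masses, coms, iyy)):
        bodies.append({"name": f"link{i}", "mass": m,
                       "inertia": [I * 0.7 + 1e-6, I, I * 1.3 + 1e-6],
                       "com": [0.0, 0.0, -c]})
        joints.append({"name": f"j{i}", "type": "revolute1",
                       "parent": f"link{i-1}" if i else None, "child": f"link{i}",
                       "translation": [0.0, 0.0, -lengths[i - 1]] if i else [0.0, 0.0, 0.0],
                       "axis": [0.0, 1.0, 0.0]})
    return {"bodies": bodies, "joints": joints, "gravity": [0.0, 0.0, -g]}


class ChainOracle:
    """Symbolic Euler-Lagrange dynamics of the planar chain.

    Provides ``M(q)``, ``c(q, qdot)`` (Coriolis+centrifugal+gravity with the
    sign convention M qddot + c = tau) and ``qddot(q, qdot, tau)``.
    """

    def __init__(self, lengths, masses, coms, iyy, g=9.81):
        n = len(lengths)
        t = sp.symbols("t")
        qf = [sp.Function(f"q{i}")(t) for i in range(n)]
        qs = sp.symbols(f"q:{n}")
        qds = sp.symbols(f"qd:{n}")
        qdds = sp.symbols(f"qdd:{n}")

        theta = [sum(qf[: i + 1]) for i in range(n)]
        jx, jz = sp.Integer(0), sp.Integer(0)
        KE, PE = sp.Integer(0), sp.Integer(0)
        for i in range(n):
            cx = jx - coms[i] * sp.sin(theta[i])
            cz = jz - coms[i] * sp.cos(theta[i])
            vx, vz = sp.diff(cx, t), sp.diff(cz, t)
            w = sp.diff(theta[i], t)
            KE += sp.Rational(1, 2) * masses[i] * (vx ** 2 + vz ** 2) \
                + sp.Rational(1, 2) * iyy[i] * w ** 2
            PE += masses[i] * g * cz
            jx = jx - lengths[i] * sp.sin(theta[i])
            jz = jz - lengths[i] * sp.cos(theta[i])

        Lag = KE - PE
        eoms = []
        for i in range(n):
            eoms.append(sp.diff(sp.diff(Lag, sp.diff(qf[i], t)), t)
                        - sp.diff(Lag, qf[i]))
        subs = {}
        for i in range(n):
            subs[sp.diff(qf[i], t, 2)] = qdds[i]
            subs[sp.diff(qf[i], t)] = qds[i]
            subs[qf[i]] = qs[i]
        eoms = [sp.expand(e.subs(subs)) for e in eoms]
        Msym = sp.Matrix(n, n, lambda i, j: sp.simplify(sp.diff(eoms[i], qdds[j])))
        csym = sp.Matrix([e.subs({qd: 0 for qd in qdds}) for e in eoms])
        self._M = sp.lambdify((qs,), Msym, "numpy")
        self._c = sp.lambdify((qs, qds), csym, "numpy")
        self.n = n

    def M(self, q):
        return np.asarray(self._M(tuple(q)), dtype=float)

    def c(self, q, qd):
        return np.asarray(self._c(tuple(q), tuple(qd)), dtype=float).ravel()

    def qddot(self, q, qd, tau):
        return np.linalg.solve(self.M(q), np.asarray(tau) - self.c(q, qd))


def gae_bruteforce(rewards, values, terminals, gamma, lam):
    """O(T^2) double-sum evaluation of generalized advantage estimation."""
    T = len(rewards)
    deltas = np.empty(T)
    for i in range(T):
        nonterm = 0.0 if terminals[i] else 1.0
        deltas[i] = rewards[i] + gamma * values[i + 1] * nonterm - values[i]
    adv = np.zeros(T)
    for i in range(T):
        decay = 1.0
        for j in range(i, T):
            adv[i] += decay * deltas[j]
            if terminals[j]:
                break
            decay *= gamma * lam
    return adv, adv + np.asarray(values[:-1], dtype=float)
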
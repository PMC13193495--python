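"""No-U-Turn Hamiltonian sampler with dual-averaging step-size adaptation
and windowed diagonal mass-matrix estimation.

The sampler works on an unconstrained parameter vector and a callable
returning (log density, gradient). It records, per retained draw, the
divergence flag and the Hamiltonian at the start of the trajectory (the
"energy" series used by E-BFMI). A trajectory is declared divergent when the
simulated Hamiltonian drifts more than ``MAX_DELTA_H`` below the slice level.

Warmup follows the usual three-phase schedule: an initial step-size-only
buffer, doubling variance-estimation windows (each ending in a metric update
and a step-size re-initialization), and a terminal step-size-only buffer.
All randomness flows through one numpy Generator, so a chain is a pure
function of (initial point, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np

MAX_DELTA_H = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass
class NutsResult:
    draws: np.ndarray  # (n_draws, dim), unconstrained, post-warmup
    divergent: np.ndarray  # (n_draws,) bool
    energy: np.ndarray  # (n_draws,) Hamiltonian at trajectory start
    tree_depth: np.ndarray  # (n_draws,) int
    step_size: float
    inv_mass: np.ndarray  # (dim,) diagonal inverse mass (posterior variances)
    accept_rate: float


def _kinetic(p: np.ndarray, inv_mass: np.ndarray) -> float:
    # exploding momenta overflow to inf, which the divergence checks expect
    with np.errstate(over="ignore"):
        return 0.5 * float(np.dot(p * p, inv_mass))


def _leapfrog(logp_grad, q, p, grad, eps, inv_mass):
    p1 = p + 0.5 * eps * grad
    q1 = q + eps * (inv_mass * p1)
    lp1, g1 = logp_grad(q1)
    p1 = p1 + 0.5 * eps * g1
    return q1, p1, lp1, g1


def _find_initial_step(logp_grad, q, lp, grad, inv_mass, rng) -> float:
    """Heuristic: scale eps by powers of 2 until a single leapfrog step
    crosses 50% acceptance."""
    eps = 1.0
    p = rng.standard_normal(q.shape) / np.sqrt(inv_mass)
    h0 = -lp + _kinetic(p, inv_mass)

    def delta(eps):
        _, p1, lp1, _ = _leapfrog(logp_grad, q, p, grad, eps, inv_mass)
        if not np.isfinite(lp1):
            return -np.inf
        d = h0 - (-lp1 + _kinetic(p1, inv_mass))
        return d if np.isfinite(d) else -np.inf

    direction = 1.0 if delta(eps) > math.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0**direction
        if direction * delta(eps) <= direction * math.log(0.5):
            break
        if eps < 1e-12 or eps > 1e7:
            break
    return float(min(max(eps, 1e-10), 1e6))


class _DualAveraging:
    """Nesterov dual averaging targeting a given acceptance statistic."""

    def __init__(self, eps0: float, target: float, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = math.log(10.0 * eps0)
        self.target = target
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_stat: float) -> float:
        self.count += 1
        m = self.count
        eta = 1.0 / (m + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_stat)
        self.log_eps = self.mu - math.sqrt(m) / self.gamma * self.h_bar
        w = m**-self.kappa
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return math.exp(self.log_eps)

    @property
    def adapted(self) -> float:
        return math.exp(self.log_eps_bar)


def _mass_windows(n_tune: int) -> list[tuple[int, int]]:
    """(start, end) variance-estimation windows within warmup."""
    init_buf, term_buf, base = 75, 50, 25
    if n_tune < init_buf + term_buf + base:
        a, b = n_tune // 4, max(n_tune // 4 + 3, 3 * n_tune // 4)
        return [(a, min(b, n_tune))]
    windows = []
    start, size = init_buf, base
    while True:
        end = start + size
        if end + term_buf >= n_tune or start + 3 * size + term_buf >= n_tune:
            windows.append((start, n_tune - term_buf))
            break
        windows.append((start, end))
        start, size = end, size * 2
    return windows


def nuts_sample(
    logp_grad: Callable[[np.ndarray], Tuple[float, np.ndarray]],
    init: np.ndarray,
    n_tune: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    max_treedepth: int = 10,
) -> NutsResult:
    """Run one chain of NUTS and return post-warmup draws and statistics."""
    q = np.asarray(init, dtype=float).copy()
    dim = q.size
    lp, grad = logp_grad(q)
    if not np.isfinite(lp):
        raise ValueError("non-finite log density at the initial point")

    inv_mass = np.ones(dim)
    eps = _find_initial_step(logp_grad, q, lp, grad, inv_mass, rng)
    da = _DualAveraging(eps, target_accept)
    windows = _mass_windows(n_tune)
    win_idx = 0
    win_buf: list[np.ndarray] = []

    draws = np.empty((n_draws, dim))
    divergent = np.zeros(n_draws, dtype=bool)
    energy = np.empty(n_draws)
    depths = np.zeros(n_draws, dtype=np.int64)
    accepts: list[float] = []

    def build_tree(q, p, lp, grad, log_u, v, j, eps, joint0):
        """Recursive doubling (slice variant). Returns
        (q-, p-, lp-, g-, q+, p+, lp+, g+, q_prop, lp_prop, g_prop,
         n_valid, keep_going, alpha_sum, n_alpha, diverged)."""
        if j == 0:
            q1, p1, lp1, g1 = _leapfrog(logp_grad, q, p, grad, v * eps, inv_mass)
            if np.isfinite(lp1):
                joint = lp1 - _kinetic(p1, inv_mass)
                if not np.isfinite(joint):
                    joint = -np.inf
            else:
                joint = -np.inf
            n_valid = 1 if log_u <= joint else 0
            diverged = (joint - log_u) < -MAX_DELTA_H
            alpha = math.exp(min(joint - joint0, 0.0)) if np.isfinite(joint) else 0.0
            return (q1, p1, lp1, g1, q1, p1, lp1, g1, q1, lp1, g1,
                    n_valid, not diverged, alpha, 1, diverged)
        (qm, pm, lpm, gm, qp, pp, lpp, gp, qq, lpq, gq,
         n1, s1, a1, na1, div1) = build_tree(q, p, lp, grad, log_u, v, j - 1, eps, joint0)
        if not s1:
            return (qm, pm, lpm, gm, qp, pp, lpp, gp, qq, lpq, gq,
                    n1, s1, a1, na1, div1)
        if v == -1:
            (qm, pm, lpm, gm, _, _, _, _, qq2, lpq2, gq2,
             n2, s2, a2, na2, div2) = build_tree(qm, pm, lpm, gm, log_u, v, j - 1, eps, joint0)
        else:
            (_, _, _, _, qp, pp, lpp, gp, qq2, lpq2, gq2,
             n2, s2, a2, na2, div2) = build_tree(qp, pp, lpp, gp, log_u, v, j - 1, eps, joint0)
        total = n1 + n2
        if n2 > 0 and total > 0 and rng.random() < n2 / total:
            qq, lpq, gq = qq2, lpq2, gq2
        dq = qp - qm
        s = (s2 and np.dot(dq, inv_mass * pm) >= 0 and np.dot(dq, inv_mass * pp) >= 0)
        return (qm, pm, lpm, gm, qp, pp, lpp, gp, qq, lpq, gq,
                total, s, a1 + a2, na1 + na2, div1 or div2)

    total_iters = n_tune + n_draws
    for it in range(total_iters):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        k0 = _kinetic(p0, inv_mass)
        joint0 = lp - k0
        log_u = joint0 + math.log(rng.random())
        qm, pm, lpm, gm = q, p0, lp, grad
        qp, pp, lpp, gp = q, p0, lp, grad
        n_valid, s, depth = 1, True, 0
        any_div = False
        alpha_sum, n_alpha = 0.0, 0
        while s and depth < max_treedepth:
            v = 1 if rng.random() < 0.5 else -1
            if v == -1:
                (qm, pm, lpm, gm, _, _, _, _, qq, lpq, gq,
                 n2, s2, a2, na2, div2) = build_tree(qm, pm, lpm, gm, log_u, v, depth, eps, joint0)
            else:
                (_, _, _, _, qp, pp, lpp, gp, qq, lpq, gq,
                 n2, s2, a2, na2, div2) = build_tree(qp, pp, lpp, gp, log_u, v, depth, eps, joint0)
            any_div = any_div or div2
            if s2 and n2 > 0 and rng.random() < min(1.0, n2 / n_valid):
                q, lp, grad = qq, lpq, gq
            n_valid += n2
            dq = qp - qm
            s = (s2 and np.dot(dq, inv_mass * pm) >= 0 and np.dot(dq, inv_mass * pp) >= 0)
            alpha_sum += a2
            n_alpha += na2
            depth += 1

        accept_stat = alpha_sum / max(n_alpha, 1)
        if it < n_tune:
            eps = da.update(accept_stat)
            if win_idx < len(windows):
                a, b = windows[win_idx]
                if a <= it < b:
                    win_buf.append(q.copy())
                if it == b - 1:
                    if len(win_buf) >= 3:
                        n = len(win_buf)
                        var = np.var(np.asarray(win_buf), axis=0, ddof=1)
                        # shrink towards unit scale when the window is short
                        inv_mass = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
                        inv_mass = np.maximum(inv_mass, 1e-10)
                    win_buf = []
                    win_idx += 1
                    eps = _find_initial_step(logp_grad, q, lp, grad, inv_mass, rng)
                    da = _DualAveraging(eps, target_accept)
            if it == n_tune - 1:
                eps = da.adapted
        else:
            k = it - n_tune
            draws[k] = q
            divergent[k] = any_div
            energy[k] = -joint0
            depths[k] = depth
            accepts.append(accept_stat)

    return NutsResult(
        draws=draws,
        divergent=divergent,
        energy=energy,
        tree_depth=depths,
        step_size=eps,
        inv_mass=inv_mass,
        accept_rate=float(np.mean(accepts)) if accepts else float("nan"),
    )
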
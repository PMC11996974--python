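"""Gradient-based MCMC: Hamiltonian Monte Carlo with warmup adaptation.

Stan-style scheme: dual-averaging step-size adaptation targeting a given
acceptance statistic, windowed estimation of a diagonal mass matrix, and
divergence detection via an energy-error threshold of 1000. Trajectory
lengths are jittered to avoid resonance. Seed-deterministic given the
supplied Generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HMCResult", "sample_chain"]

DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class HMCResult:
    draws: np.ndarray  # (n_iter, dim), unconstrained
    divergences: int
    step_size: float
    mass_inv: np.ndarray
    accept_rate: float


class _DualAveraging:
    def __init__(self, eps0, target=0.8, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.t = 0

    def update(self, accept_prob):
        self.t += 1
        frac = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.t) / self.gamma * self.h_bar
        w = self.t ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar

    @property
    def eps(self):
        return float(np.exp(self.log_eps))

    @property
    def eps_final(self):
        return float(np.exp(self.log_eps_bar))


def _leapfrog(logp_grad, x, p, eps, mass_inv, n_steps):
    logp, grad = logp_grad(x)
    for _ in range(n_steps):
        p = p + 0.5 * eps * grad
        x = x + eps * mass_inv * p
        logp, grad = logp_grad(x)
        if not np.isfinite(logp):
            return x, p, -np.inf, grad
        p = p + 0.5 * eps * grad
    return x, p, logp, grad


def _find_initial_step(logp_grad, x, mass_inv, rng):
    eps = 0.1
    logp0, _ = logp_grad(x)
    p = rng.normal(size=x.size) / np.sqrt(mass_inv)
    h0 = logp0 - 0.5 * np.sum(mass_inv * p**2)
    _, p1, logp1, _ = _leapfrog(logp_grad, x, p, eps, mass_inv, 1)
    h1 = logp1 - 0.5 * np.sum(mass_inv * p1**2)
    ratio = h1 - h0
    direction = 1 if ratio > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        _, p1, logp1, _ = _leapfrog(logp_grad, x, p, eps, mass_inv, 1)
        h1 = logp1 - 0.5 * np.sum(mass_inv * p1**2)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction == 1 and h1 - h0 <= np.log(0.5):
            break
        if direction == -1 and h1 - h0 >= np.log(0.5):
            break
    return float(np.clip(eps, 1e-8, 10.0))


def _warmup_windows(n_warmup):
    """(step-size-only init, list of mass windows, step-size-only term)."""
    if n_warmup < 20:
        return n_warmup, [], 0
    init = max(int(0.15 * n_warmup), 10)
    term = max(int(0.10 * n_warmup), 10)
    middle = n_warmup - init - term
    windows = []
    w = max(middle // 15, 10)
    remaining = middle
    while remaining > 0:
        w = min(w, remaining)
        if remaining - w < 10:
            w = remaining
        windows.append(w)
        remaining -= w
        w *= 2
    return init, windows, term


def sample_chain(
    logp_grad,
    init,
    n_warmup,
    n_iter,
    rng,
    target_accept=0.8,
    traj_length=2.5,
    max_steps=96,
    store_fn=None,
):
    """Run one HMC chain; returns an :class:`HMCResult`.

    ``store_fn`` optionally maps each unconstrained draw to the vector that
    is actually stored (e.g. constrained coefficients).
    """
    x = np.asarray(init, dtype=float).copy()
    dim = x.size
    mass_inv = np.ones(dim)
    eps = _find_initial_step(logp_grad, x, mass_inv, rng)
    da = _DualAveraging(eps, target=target_accept)

    logp, grad = logp_grad(x)
    if not np.isfinite(logp):
        raise RuntimeError("non-finite log posterior at the initial value")

    init_buf, windows, term_buf = _warmup_windows(n_warmup)
    schedule = [("step", init_buf)] + [("mass", w) for w in windows] + [("step", term_buf)]

    divergences = 0
    accepts = []

    def one_iteration(eps):
        nonlocal x, logp, grad, divergences
        p = rng.normal(size=dim) / np.sqrt(mass_inv)
        h0 = logp - 0.5 * np.sum(mass_inv * p**2)
        base_steps = int(np.clip(np.ceil(traj_length / eps), 1, max_steps))
        n_steps = int(rng.integers(max(1, base_steps // 2), base_steps + 1))
        x_new, p_new, logp_new, grad_new = _leapfrog(logp_grad, x, p, eps, mass_inv, n_steps)
        with np.errstate(over="ignore"):
            h1 = (
                logp_new - 0.5 * np.sum(mass_inv * p_new**2)
                if np.isfinite(logp_new)
                else -np.inf
            )
        delta = h1 - h0
        divergent = (not np.isfinite(delta)) or (delta < -DIVERGENCE_THRESHOLD)
        accept_prob = 0.0 if divergent else min(1.0, float(np.exp(min(delta, 0.0))))
        if not divergent and np.log(rng.uniform()) < delta:
            x, logp, grad = x_new, logp_new, grad_new
        if divergent:
            divergences += 1
        return accept_prob, divergent

    warm_divergences = 0
    for phase, length in schedule:
        if phase == "mass" and length > 0:
            welford_mean = np.zeros(dim)
            welford_m2 = np.zeros(dim)
            count = 0
        for _ in range(length):
            accept_prob, _ = one_iteration(da.eps)
            da.update(accept_prob)
            if phase == "mass":
                count += 1
                delta_x = x - welford_mean
                welford_mean += delta_x / count
                welford_m2 += delta_x * (x - welford_mean)
        if phase == "mass" and length > 1:
            var = welford_m2 / max(count - 1, 1)
            mass_inv = (count / (count + 5.0)) * var + 1e-3 * (5.0 / (count + 5.0))
            mass_inv = np.clip(mass_inv, 1e-8, 1e8)
            eps_now = da.eps
            da = _DualAveraging(eps_now, target=target_accept)
    warm_divergences = divergences
    divergences = 0

    eps = da.eps_final if n_warmup >= 20 else da.eps
    first = None
    if store_fn is not None:
        first = store_fn(x)
        draws = np.empty((n_iter, first.size))
    else:
        draws = np.empty((n_iter, dim))
    for it in range(n_iter):
        accept_prob, _ = one_iteration(eps)
        accepts.append(accept_prob)
        draws[it] = store_fn(x) if store_fn is not None else x

    return HMCResult(
        draws=draws,
        divergences=divergences,
        step_size=eps,
        mass_inv=mass_inv,
        accept_rate=float(np.mean(accepts)) if accepts else float("nan"),
    )
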
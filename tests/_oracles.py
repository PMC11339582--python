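"""Independent analytic and brute-force oracles used only by tests."""

from __future__ import annotations

import math

import numpy as np


def erlang_c_wait_probability(lam: float, mu: float, c: int) -> float:
    """P(wait > 0) in the stationary M/M/c queue."""
    a = lam / mu
    rho = a / c
    if rho >= 1:
        raise ValueError("unstable queue")
    summ = sum(a**k / math.factorial(k) for k in range(c))
    top = a**c / math.factorial(c) / (1 - rho)
    return top / (summ + top)


def erlang_c_mean_wait(lam: float, mu: float, c: int) -> float:
    """Unconditional mean queue wait E[Wq] in M/M/c."""
    return erlang_c_wait_probability(lam, mu, c) / (c * mu - lam)


def mmc_m_abandon_probability(lam: float, mu: float, theta: float, c: int, n_max: int = 500) -> float:
    """Abandonment probability of the stationary M/M/c+M queue, from the
    truncated birth-death chain: P(ab) = theta * E[(N - c)+] / lam."""
    log_pi = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        death = min(n, c) * mu + max(n - c, 0) * theta
        log_pi[n] = log_pi[n - 1] + math.log(lam) - math.log(death)
    log_pi -= log_pi.max()
    pi = np.exp(log_pi)
    pi /= pi.sum()
    queue = np.maximum(np.arange(n_max + 1) - c, 0)
    return float(theta * (pi * queue).sum() / lam)


def nhpp_by_inversion(rate_fn, t_end: float, rng: np.random.Generator) -> np.ndarray:
    """Exact NHPP sampler via time-rescaling: invert the integrated
    intensity at unit-exponential increments.  Independent of thinning."""
    grid = np.linspace(0.0, t_end, max(int(t_end) * 4, 1024) + 1)
    lam = np.asarray(rate_fn(grid))
    cum = np.concatenate([[0.0], np.cumsum((lam[1:] + lam[:-1]) / 2.0 * np.diff(grid))])
    total = cum[-1]
    times = []
    target = rng.exponential()
    while target < total:
        times.append(float(np.interp(target, cum, grid)))
        target += rng.exponential()
    return np.asarray(times)
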
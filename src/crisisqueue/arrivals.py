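"""Stochastic arrival-stream generators.

Three layers build the arrival process of a crisis-counseling queue:

* :func:`sample_nhpp` — exact nonhomogeneous-Poisson sampling by
  Lewis-Shedler thinning against the dominating constant rate
  ``lambda* = max(lambda(t))``;
* :func:`split_tos` — the Bernoulli terms-of-service gate, which by the
  thinning property leaves the accepted substream NHPP with intensity
  p*lambda(t);
* :func:`sample_hawkes` — a self-exciting cluster process for repeat
  users: NHPP *immigrants* spawn Poisson(eta) *offspring* at exponential
  forward lags, recursively.  Because a counselor serves at most one event
  per cluster, :func:`purge_offspring` restores the independent-increment
  immigrant stream that capacity planning actually needs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .ratefn import RateFunction

__all__ = [
    "ArrivalEvent",
    "HawkesKernel",
    "sample_nhpp",
    "split_tos",
    "sample_hawkes",
    "purge_offspring",
]


@dataclass(frozen=True)
class ArrivalEvent:
    """One arrival: time in minutes from horizon start plus lineage metadata."""

    time: float
    identity: str
    lineage: str = "immigrant"  # or "offspring"
    parent_time: Optional[float] = None
    tos_accepted: Optional[bool] = None
    user_type: Optional[str] = None


@dataclass(frozen=True)
class HawkesKernel:
    """Exponential memory kernel phi(u) = eta * omega * exp(-omega u).

    ``branching_ratio`` (eta) is the expected offspring per event and equals
    the kernel integral; subcriticality (eta < 1) keeps clusters finite.
    ``decay_rate`` (omega) is per minute.
    """

    branching_ratio: float
    decay_rate: float

    def __post_init__(self):
        if not 0.0 <= self.branching_ratio < 1.0:
            raise ValueError("branching ratio must lie in [0, 1) (subcritical)")
        if self.decay_rate <= 0:
            raise ValueError("decay rate must be positive")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _thin_window(
    rng: np.random.Generator, rate_fn: RateFunction, t0: float, t1: float, lam_star: float
) -> np.ndarray:
    """Thin one window: homogeneous candidates at lam_star, keep w.p. lambda/lam*."""
    if lam_star <= 0.0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(lam_star * (t1 - t0))
    times = np.sort(rng.uniform(t0, t1, n))
    if n == 0:
        return times
    accept = rng.random(n) < np.asarray(rate_fn(times)) / lam_star
    return times[accept]


def sample_nhpp(
    rate_fn: RateFunction,
    t_end: float,
    seed=None,
    piecewise: bool = False,
    window_minutes: float = 120.0,
    id_prefix: str = "u",
) -> list[ArrivalEvent]:
    """Sample an NHPP realization on [0, t_end] by thinning.

    With ``piecewise=False`` (the recommended global-maximum strategy) a
    single dominating rate ``rate_fn.max_rate`` is used; ``piecewise=True``
    rederives a local maximum per ``window_minutes`` window, which is
    distributionally equivalent but wastes fewer candidates when the
    intensity swings widely.  Deterministic given the seed.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    rng = _as_rng(seed)
    if not np.isfinite(rate_fn.max_rate):
        raise ValueError("max_rate must be finite")
    if rate_fn.max_rate <= 0:
        return []
    # audit the dominating rate on a coarse grid
    audit = np.linspace(0.0, t_end, 256)
    if np.any(np.asarray(rate_fn(audit)) > rate_fn.max_rate * (1 + 1e-9)):
        raise RuntimeError("rate function exceeds its declared max_rate")

    if piecewise:
        chunks = []
        t0 = 0.0
        while t0 < t_end:
            t1 = min(t0 + window_minutes, t_end)
            grid = np.linspace(t0, t1, 64)
            lam_loc = float(np.max(np.asarray(rate_fn(grid))))
            chunks.append(_thin_window(rng, rate_fn, t0, t1, lam_loc))
            t0 = t1
        times = np.concatenate(chunks) if chunks else np.empty(0)
    else:
        times = _thin_window(rng, rate_fn, 0.0, t_end, rate_fn.max_rate)
    return [
        ArrivalEvent(time=float(t), identity=f"{id_prefix}{i:06d}") for i, t in enumerate(times)
    ]


def split_tos(events: Sequence[ArrivalEvent], p: float, seed=None) -> list[ArrivalEvent]:
    """Mark each event with an i.i.d. Bernoulli(p) TOS acceptance."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    rng = _as_rng(seed)
    draws = rng.random(len(events)) < p
    return [replace(ev, tos_accepted=bool(d)) for ev, d in zip(events, draws)]


def sample_hawkes(
    base_fn: RateFunction,
    kernel: HawkesKernel,
    t_end: float,
    seed=None,
    id_prefix: str = "u",
) -> list[ArrivalEvent]:
    """Sample a Hawkes stream by the cluster (branching) construction.

    Immigrants are an NHPP draw from ``base_fn``; every event then spawns
    Poisson(branching_ratio) children at Exponential(decay_rate) forward
    lags, recursively, until extinction.  Children inherit their root
    immigrant's identity — the field's picture of one agitated repeat user
    re-contacting the service in a short burst.  Events past ``t_end`` are
    discarded (their descendants with them once they fall beyond t_end).
    """
    rng = _as_rng(seed)
    immigrants = sample_nhpp(base_fn, t_end, rng, id_prefix=id_prefix)
    out: list[ArrivalEvent] = list(immigrants)
    # breadth-first growth of each cluster
    frontier: list[ArrivalEvent] = list(immigrants)
    while frontier:
        nxt: list[ArrivalEvent] = []
        for parent in frontier:
            n_children = rng.poisson(kernel.branching_ratio)
            if n_children == 0:
                continue
            lags = rng.exponential(1.0 / kernel.decay_rate, n_children)
            for lag in lags:
                t = parent.time + float(lag)
                if t > t_end:
                    continue
                child = ArrivalEvent(
                    time=t,
                    identity=parent.identity,
                    lineage="offspring",
                    parent_time=parent.time,
                )
                out.append(child)
                nxt.append(child)
        frontier = nxt
    out.sort(key=lambda ev: ev.time)
    return out


def purge_offspring(events: Sequence[ArrivalEvent]) -> list[ArrivalEvent]:
    """Drop offspring, restoring the independent-increment immigrant stream."""
    for ev in events:
        if ev.lineage not in ("immigrant", "offspring"):
            raise ValueError(f"unlabeled event lineage {ev.lineage!r}")
    return [ev for ev in events if ev.lineage == "immigrant"]
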
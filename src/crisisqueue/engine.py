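"""Discrete-event simulator of the counseling floor.

A single FIFO *case queue* feeds counselors working overlapping shifts
with per-counselor simultaneous-chat capacity.  The event loop models:

* arrivals (NHPP / Hawkes / empirical round-robin interarrivals) gated by
  the Bernoulli TOS decision;
* reneging after an exponential patience draw per user type;
* the *zombie* mechanism: when the platform cannot auto-evict reneged
  cases (``zombie_eviction=False``, the historical behaviour) a reneged
  case stays in the case queue and, once a counselor finally opens it,
  consumes only the post-chat-survey overhead;
* zero-wait accounting: pickups within a 60-second window count as served
  immediately (they never really queued);
* risk-dependent scaled-beta service durations followed by the post-chat
  survey, with an optional global ``duration_scale`` (e.g. the
  standardize-to-40-minutes scenario);
* per-slot shift and break windows: no new assignments outside them, but
  chats in progress always finish.

Simultaneous events are ordered completion -> renege -> arrival so that
capacity freed at an instant is available to the assignment decision made
at that same instant, and runs are bit-reproducible given a seed.
"""

from __future__ import annotations

import bisect
import heapq
import math
from dataclasses import dataclass, field as dc_field
from datetime import timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .arrivals import HawkesKernel, sample_hawkes, sample_nhpp
from .params import (
    DurationModel,
    GroundTruthParams,
    PatienceModel,
    RISK_MIX_REFERENCE,
    TOS_P_REFERENCE,
    NONREPEAT_P_REFERENCE,
    default_rate_function,
)
from .ratefn import RateFunction
from .records import ChatRecord, DEFAULT_EPOCH

__all__ = [
    "CounselorSpec",
    "Shift",
    "ScenarioConfig",
    "RepResult",
    "BootstrapResult",
    "run_replication",
    "run_bootstrap",
    "empirical_roundrobin_arrivals",
    "base_case_shifts",
]

#: (concurrent_capacity, cost_weight) defaults per staffing role.
ROLE_DEFAULTS = {
    "duty_officer": (1, 3.0),
    "full_time": (3, 2.0),
    "volunteer": (2, 1.5),
}

_QCAP = 80  # queue-length histogram clip
_RISKS = ("low", "medium", "high_crisis")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CounselorSpec:
    """One staffed seat: role, simultaneous-chat capacity, cost weight."""

    role: str
    concurrent_capacity: Optional[int] = None
    cost_weight: Optional[float] = None

    def resolved(self) -> tuple[int, float]:
        if self.role not in ROLE_DEFAULTS:
            raise ConfigError(f"unknown role {self.role!r}")
        cap, cost = ROLE_DEFAULTS[self.role]
        cap = self.concurrent_capacity if self.concurrent_capacity is not None else cap
        cost = self.cost_weight if self.cost_weight is not None else cost
        if cap < 1:
            raise ConfigError("concurrent capacity must be >= 1")
        return int(cap), float(cost)


@dataclass
class Shift:
    """A daily shift window (minutes of day; end may wrap past midnight)
    with its staff and optional per-slot break windows."""

    start_minute: float
    end_minute: float
    staff: list
    breaks: Optional[list] = None  # list (per staff slot) of (start, end) minute-of-day pairs

    def __post_init__(self):
        if self.breaks is None:
            self.breaks = [[] for _ in self.staff]
        if len(self.breaks) != len(self.staff):
            raise ConfigError("breaks must align with staff slots")
        if not self.staff:
            raise ConfigError("shift has no staff")
        if not 0 <= self.start_minute < 1440 or not 0 <= self.end_minute <= 1440:
            raise ConfigError("shift boundaries must be minutes of day")
        if self.end_minute == self.start_minute:
            raise ConfigError("shift start and end coincide")
        span = self.span_minutes
        if span <= 0 or span > 1440:
            raise ConfigError("shift span must lie in (0, 1440] minutes")

    @property
    def span_minutes(self) -> float:
        end = self.end_minute if self.end_minute > self.start_minute else self.end_minute + 1440
        return end - self.start_minute

    @property
    def capacity(self) -> int:
        return sum(s.resolved()[0] for s in self.staff)

    @property
    def cost(self) -> float:
        return sum(s.resolved()[1] for s in self.staff)


def base_case_shifts() -> list[Shift]:
    """Reconstructed 15-counselor, 4-shift timetable.

    The historical operation ran 15 counselors over 4 parallel shifts; the
    exact timetable is not on record, so this default reconstructs one
    from its documented operating facts: at most 2 counselors on duty in
    the early-morning trough, 3-5 active counselors through the evening
    peak, and regular break cycles in the 11 AM-noon, 7-10 PM, and
    midnight-1 AM slots (staggered so coverage never drops to zero).
    Fully overridable in any ScenarioConfig.
    """
    ft = CounselorSpec("full_time")
    do = CounselorSpec("duty_officer")
    vol = CounselorSpec("volunteer")
    return [
        # overnight 00:00-09:00 (2 on duty; the full-timer doubles as duty
        # officer), staggered rest breaks midnight-1 AM
        Shift(0, 540, [ft, vol], breaks=[[(0, 30)], [(30, 60)]]),
        # day 09:00-14:00 with staggered meal breaks 11:00-12:00
        Shift(540, 840, [do, ft, vol, vol], breaks=[[], [(660, 690)], [(660, 690)], [(690, 720)]]),
        # afternoon 14:00-19:00
        Shift(840, 1140, [do, ft, vol, vol]),
        # evening 19:00-24:00 (peak; 5 staff), staggered breaks 7-10 PM
        Shift(
            1140,
            1440,
            [do, ft, ft, vol, vol],
            breaks=[[(1140, 1176)], [(1176, 1212)], [(1212, 1248)], [(1248, 1284)], [(1284, 1320)]],
        ),
    ]


@dataclass
class ScenarioConfig:
    """Everything one simulated scenario needs."""

    shifts: list
    horizon_minutes: float = 43_200.0
    arrival_source: str = "nhpp"  # 'nhpp' | 'empirical_roundrobin' | 'hawkes'
    rate_fn: Optional[RateFunction] = None
    interarrivals: Optional[np.ndarray] = None
    hawkes_kernel: Optional[HawkesKernel] = None
    tos_p: float = TOS_P_REFERENCE
    user_type_p: float = NONREPEAT_P_REFERENCE
    risk_mix: dict = dc_field(default_factory=lambda: {u: dict(m) for u, m in RISK_MIX_REFERENCE.items()})
    duration_models: dict = dc_field(default_factory=dict)
    patience_models: dict = dc_field(default_factory=dict)
    duration_scale: float = 1.0
    zombie_eviction: bool = False
    zero_wait_window_s: float = 60.0
    survey_minutes: float = 5.0
    replications: int = 1500
    seed: int = 0
    label: str = "scenario"

    def validate(self) -> "ScenarioConfig":
        if self.horizon_minutes <= 0:
            raise ConfigError("horizon must be positive")
        if self.replications < 1:
            raise ConfigError("replications must be >= 1")
        if self.duration_scale <= 0:
            raise ConfigError("duration_scale must be positive")
        if self.arrival_source not in ("nhpp", "empirical_roundrobin", "hawkes"):
            raise ConfigError(f"unknown arrival source {self.arrival_source!r}")
        if self.arrival_source in ("nhpp", "hawkes") and self.rate_fn is None:
            raise ConfigError("rate_fn required for NHPP/Hawkes arrivals")
        if self.arrival_source == "empirical_roundrobin" and self.interarrivals is None:
            raise ConfigError("interarrivals required for round-robin arrivals")
        if self.arrival_source == "hawkes" and self.hawkes_kernel is None:
            raise ConfigError("hawkes_kernel required for Hawkes arrivals")
        for shift in self.shifts:
            for spec in shift.staff:
                spec.resolved()
        return self

    # -- staffing economics ----------------------------------------------

    def total_cost(self) -> float:
        """Sum of cost weights over all scheduled staff (all shifts)."""
        return sum(sh.cost for sh in self.shifts)

    def total_capacity(self) -> int:
        """Sum of concurrent-chat capacities over the shifts."""
        return sum(sh.capacity for sh in self.shifts)

    @classmethod
    def base_case(cls, **overrides) -> "ScenarioConfig":
        """The reconstructed historical operating point: 15 counselors on
        4 shifts, diurnal NHPP arrivals at November-2020 volume, reference
        duration/patience models, zombies not evicted."""
        truth = GroundTruthParams.reference()
        horizon = overrides.pop("horizon_minutes", 43_200.0)
        if horizon <= 0:
            raise ConfigError("horizon must be positive")
        cfg = cls(
            shifts=base_case_shifts(),
            horizon_minutes=horizon,
            arrival_source="nhpp",
            rate_fn=overrides.pop("rate_fn", default_rate_function(horizon)),
            tos_p=truth.tos_p,
            user_type_p=truth.user_type_p,
            risk_mix=truth.risk_mix,
            duration_models=dict(truth.duration),
            patience_models=dict(truth.patience),
            label="base_case",
        )
        for key, value in overrides.items():
            if not hasattr(cfg, key):
                raise ConfigError(f"unknown config field {key!r}")
            setattr(cfg, key, value)
        return cfg.validate()


# ---------------------------------------------------------------------------
# arrival helpers
# ---------------------------------------------------------------------------


def empirical_roundrobin_arrivals(
    interarrivals: Sequence[float], horizon_minutes: float, rng=None, shuffle: bool = True
) -> np.ndarray:
    """Arrival times from cycling an (optionally shuffled) interarrival list.

    The list is recycled round-robin until the cumulative time reaches the
    horizon; times beyond the horizon are excluded.  This reproduces the
    trick of topping a bootstrap replication up with a few extra cases from
    the head of the list so the 30-day horizon is fully covered.
    """
    ia = np.asarray(interarrivals, dtype=float)
    if ia.size == 0:
        raise ValueError("interarrival list is empty")
    if np.any(ia <= 0):
        raise ValueError("interarrivals must be strictly positive")
    if shuffle:
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        ia = rng.permutation(ia)
    total = float(ia.sum())
    n_cycles = int(math.ceil(horizon_minutes / total)) + 1
    times = np.cumsum(np.tile(ia, n_cycles))
    return times[times <= horizon_minutes]


# ---------------------------------------------------------------------------
# runtime objects
# ---------------------------------------------------------------------------


class _Counselor:
    __slots__ = ("idx", "capacity", "load", "starts", "ends")

    def __init__(self, idx: int, capacity: int, intervals: list):
        self.idx = idx
        self.capacity = capacity
        self.load = 0
        self.starts = [s for s, _ in intervals]
        self.ends = [e for _, e in intervals]

    def on_duty(self, t: float) -> bool:
        i = bisect.bisect_right(self.starts, t) - 1
        return i >= 0 and t < self.ends[i]

    def available(self, t: float) -> bool:
        return self.load < self.capacity and self.on_duty(t)


def _subtract_breaks(start: float, end: float, breaks) -> list:
    """Split [start, end) by break windows (absolute minutes)."""
    pieces = [(start, end)]
    for b0, b1 in breaks:
        nxt = []
        for s, e in pieces:
            if b1 <= s or b0 >= e:
                nxt.append((s, e))
                continue
            if b0 > s:
                nxt.append((s, b0))
            if b1 < e:
                nxt.append((b1, e))
        pieces = nxt
    return [(s, e) for s, e in pieces if e > s]


def _build_counselors(config: ScenarioConfig) -> list[_Counselor]:
    horizon = config.horizon_minutes
    n_days = int(math.ceil(horizon / 1440.0))
    out = []
    idx = 0
    for shift in config.shifts:
        wrap = shift.end_minute <= shift.start_minute
        end_of_day = shift.end_minute + (1440 if wrap else 0)
        for slot, spec in enumerate(shift.staff):
            cap, _ = spec.resolved()
            intervals = []
            for day in range(n_days + 1):
                s = day * 1440 + shift.start_minute
                e = day * 1440 + end_of_day
                if s >= horizon + 1440:
                    continue
                abs_breaks = [
                    (day * 1440 + b0 + (1440 if wrap and b0 < shift.start_minute else 0),
                     day * 1440 + b1 + (1440 if wrap and b0 < shift.start_minute else 0))
                    for b0, b1 in shift.breaks[slot]
                ]
                intervals.extend(_subtract_breaks(s, e, abs_breaks))
            out.append(_Counselor(idx, cap, intervals))
            idx += 1
    return out


class _Case:
    __slots__ = (
        "uid", "arrival", "user_type", "status", "duration",
        "pickup", "end", "renege", "risk", "counselor", "zombie_pickup", "zombie_end",
    )

    def __init__(self, uid: str, arrival: float, user_type: str):
        self.uid = uid
        self.arrival = arrival
        self.user_type = user_type
        self.status = "waiting"
        self.duration = None
        self.pickup = None
        self.end = None
        self.renege = None
        self.risk = None
        self.counselor = None
        self.zombie_pickup = None
        self.zombie_end = None


@dataclass
class RepResult:
    """One replication: tallies, hour-of-day aggregates, optional log."""

    tallies: dict
    queue_hist: np.ndarray  # (24, QCAP+1) minutes observed at each queue length
    vacancy_hist: np.ndarray  # (24, maxcap+1) minutes at each unused-capacity level
    dropout_by_hour: np.ndarray  # (24,) renege counts
    wait_hours: np.ndarray  # arrival hour-of-day of each queued-then-served case
    wait_minutes: np.ndarray  # matching waits
    records: Optional[list] = None

    @property
    def conversion(self) -> float:
        t = self.tallies
        if t["arrivals"] == 0:
            return float("nan")
        return (t["served_immediately"] + t["served_after_queue"]) / t["arrivals"]


# ---------------------------------------------------------------------------
# the event loop
# ---------------------------------------------------------------------------

_P_COMPLETE = 0
_P_RENEGE = 1
_P_ARRIVAL = 2


def _draw_arrivals(config: ScenarioConfig, rng: np.random.Generator):
    """Return (times, user_types) for one replication."""
    horizon = config.horizon_minutes
    if config.arrival_source == "nhpp":
        events = sample_nhpp(config.rate_fn, horizon, rng)
        times = np.array([ev.time for ev in events])
        types = np.where(rng.random(times.size) < config.user_type_p, "nonrepeat", "repeat")
    elif config.arrival_source == "hawkes":
        events = sample_hawkes(config.rate_fn, config.hawkes_kernel, horizon, rng)
        times = np.array([ev.time for ev in events])
        offspring = np.array([ev.lineage == "offspring" for ev in events])
        types = np.where(
            offspring, "repeat",
            np.where(rng.random(times.size) < config.user_type_p, "nonrepeat", "repeat"),
        )
    else:
        times = empirical_roundrobin_arrivals(config.interarrivals, horizon, rng)
        types = np.where(rng.random(times.size) < config.user_type_p, "nonrepeat", "repeat")
    return times, types


def _patience_for(config: ScenarioConfig, user_type: str) -> PatienceModel:
    if user_type in config.patience_models:
        return config.patience_models[user_type]
    if "all" in config.patience_models:
        return config.patience_models["all"]
    raise ConfigError(f"no patience model for user type {user_type!r}")


def _duration_for(config: ScenarioConfig, user_type: str, risk: str) -> DurationModel:
    if (user_type, risk) in config.duration_models:
        return config.duration_models[(user_type, risk)]
    if ("all", risk) in config.duration_models:
        return config.duration_models[("all", risk)]
    raise ConfigError(f"no duration model for ({user_type!r}, {risk!r})")


def run_replication(config: ScenarioConfig, seed=None, keep_log: bool = True) -> RepResult:
    """Execute one replication of the scenario; deterministic given seed."""
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    horizon = config.horizon_minutes
    zw = config.zero_wait_window_s / 60.0
    # an unstaffed scenario is a valid degenerate run: every accepted case
    # eventually reneges (or is still in system at the horizon)
    counselors = _build_counselors(config)

    times, types = _draw_arrivals(config, rng)
    tos = rng.random(times.size) < config.tos_p

    heap: list = []
    seq = 0

    def push(t, prio, kind, payload):
        nonlocal seq
        heapq.heappush(heap, (t, prio, seq, kind, payload))
        seq += 1

    for c in counselors:
        for s in c.starts:
            if s <= horizon:
                push(float(s), _P_COMPLETE, "duty", c)
    for i in range(times.size):
        push(float(times[i]), _P_ARRIVAL, "arrival", i)

    queue: list[_Case] = []  # FIFO; lazy removal by status
    qhead = 0
    cases: list[_Case] = []
    live_waiting = 0

    occ_times: list[float] = []
    occ_delta: list[int] = []
    q_times: list[float] = []
    q_delta: list[int] = []

    def note_occ(t, d):
        occ_times.append(t)
        occ_delta.append(d)

    def note_queue(t, d):
        q_times.append(t)
        q_delta.append(d)

    risk_p = {
        ut: np.array([config.risk_mix[ut][r] for r in _RISKS]) for ut in config.risk_mix
    }

    def try_assign(t):
        nonlocal qhead, live_waiting
        if t > horizon:
            return
        while True:
            # skip dead queue entries
            while qhead < len(queue) and queue[qhead].status in ("in_service", "served", "evicted", "zombie_cleared"):
                qhead += 1
            if qhead >= len(queue):
                return
            best = None
            for c in counselors:
                if c.available(t) and (best is None or c.load < best.load):
                    best = c
            if best is None:
                return
            case = queue[qhead]
            qhead += 1
            if case.status == "reneged":  # zombie: survey overhead only
                case.status = "zombie_cleared"
                case.zombie_pickup = t
                case.zombie_end = t + config.survey_minutes
                case.counselor = best.idx
                best.load += 1
                note_occ(t, +1)
                push(t + config.survey_minutes, _P_COMPLETE, "complete", best)
                continue
            # live case: full service (risk applied at service start; the
            # draw itself was made at arrival so that paired-seed scenario
            # comparisons share common random numbers)
            case.status = "in_service"
            case.pickup = t
            case.counselor = best.idx
            live_waiting -= 1
            note_queue(t, -1)
            case.end = t + case.duration
            best.load += 1
            note_occ(t, +1)
            push(case.end + config.survey_minutes, _P_COMPLETE, "complete", best)

    while heap:
        t, prio, _, kind, payload = heapq.heappop(heap)
        if kind == "complete":
            payload.load -= 1
            if t <= horizon:
                note_occ(t, -1)
            try_assign(t)
        elif kind == "duty":
            try_assign(t)
        elif kind == "renege":
            case = payload
            if case.status != "waiting" or t > horizon:
                continue
            case.status = "evicted" if config.zombie_eviction else "reneged"
            case.renege = t
            live_waiting -= 1
            note_queue(t, -1)
        else:  # arrival
            i = payload
            if not tos[i]:
                cases.append(_Case(f"u{i:06d}", t, str(types[i])))
                cases[-1].status = "rejected_tos"
                continue
            case = _Case(f"u{i:06d}", t, str(types[i]))
            # all per-case randomness is drawn here, in arrival order
            patience = float(_patience_for(config, case.user_type).sample(rng))
            p = risk_p[case.user_type] if case.user_type in risk_p else risk_p["all"]
            case.risk = _RISKS[int(rng.choice(3, p=p))]
            case.duration = (
                float(_duration_for(config, case.user_type, case.risk).sample(rng))
                * config.duration_scale
            )
            cases.append(case)
            queue.append(case)
            live_waiting += 1
            note_queue(t, +1)
            if math.isfinite(patience) and t + patience <= horizon:
                push(t + patience, _P_RENEGE, "renege", case)
            try_assign(t)

    # -- tallies ---------------------------------------------------------
    tallies = {
        "arrivals": int(times.size),
        "tos_accepted": 0,
        "served_immediately": 0,
        "served_after_queue": 0,
        "reneged": 0,
        "in_system_at_horizon": 0,
        "zombies_cleared": 0,
    }
    wait_hours: list[int] = []
    wait_minutes: list[float] = []
    dropout = np.zeros(24, dtype=np.int64)
    for case in cases:
        if case.status == "rejected_tos":
            continue
        tallies["tos_accepted"] += 1
        if case.status in ("in_service", "served") or case.pickup is not None:
            w = case.pickup - case.arrival
            if w <= zw:
                tallies["served_immediately"] += 1
            else:
                tallies["served_after_queue"] += 1
                wait_hours.append(int((case.arrival % 1440.0) // 60.0))
                wait_minutes.append(w)
        elif case.status in ("reneged", "evicted", "zombie_cleared"):
            tallies["reneged"] += 1
            dropout[int((case.renege % 1440.0) // 60.0)] += 1
            if case.status == "zombie_cleared":
                tallies["zombies_cleared"] += 1
        else:  # still waiting when the horizon closed
            tallies["in_system_at_horizon"] += 1

    # -- minute-grid series ----------------------------------------------
    n_min = int(horizon)
    grid = np.arange(n_min, dtype=float)
    hours = ((grid % 1440.0) // 60.0).astype(np.int64)

    def series_from(ts, ds):
        if not ts:
            return np.zeros(n_min, dtype=np.int64)
        ts = np.asarray(ts)
        ds = np.asarray(ds)
        order = np.argsort(ts, kind="stable")
        cum = np.cumsum(ds[order])
        pos = np.searchsorted(ts[order], grid, side="right")
        return np.where(pos > 0, cum[pos - 1], 0)

    qseries = np.clip(series_from(q_times, q_delta), 0, _QCAP)
    occ = series_from(occ_times, occ_delta)

    sched = np.zeros(n_min, dtype=np.int64)
    for c in counselors:
        for s, e in zip(c.starts, c.ends):
            i0 = max(int(math.ceil(s)), 0)
            i1 = min(int(math.ceil(e)), n_min)
            if i1 > i0:
                sched[i0:i1] += c.capacity
    vac = np.clip(sched - occ, 0, None)
    maxcap = int(sched.max()) if n_min else 0

    queue_hist = np.zeros((24, _QCAP + 1), dtype=np.int64)
    vac_hist = np.zeros((24, maxcap + 1), dtype=np.int64)
    np.add.at(queue_hist, (hours, qseries), 1)
    np.add.at(vac_hist, (hours, np.clip(vac, 0, maxcap)), 1)

    records = _build_records(cases, config) if keep_log else None
    return RepResult(
        tallies=tallies,
        queue_hist=queue_hist,
        vacancy_hist=vac_hist,
        dropout_by_hour=dropout,
        wait_hours=np.asarray(wait_hours, dtype=np.int64),
        wait_minutes=np.asarray(wait_minutes, dtype=float),
        records=records,
    )


def _build_records(cases, config: ScenarioConfig, epoch=DEFAULT_EPOCH) -> list[ChatRecord]:
    out = []
    for case in cases:
        if case.status == "rejected_tos":
            out.append(
                ChatRecord(case.uid, "web", _ts(epoch, case.arrival), False, case.user_type)
            )
            continue
        pickup = case.pickup if case.pickup is not None else case.zombie_pickup
        end = case.end if case.end is not None else case.zombie_end
        renege = case.renege
        # log resolution guard: a zombie opened in the same second it reneged
        if renege is not None and pickup is not None and pickup - renege < 1 / 60.0:
            pickup = renege + 1 / 60.0
            if end is not None and end < pickup:
                end = pickup
        out.append(
            ChatRecord(
                user_id=case.uid,
                channel="web",
                arrival_ts=_ts(epoch, case.arrival),
                tos_accepted=True,
                user_type=case.user_type,
                pickup_ts=_ts(epoch, pickup) if pickup is not None else None,
                end_ts=_ts(epoch, end) if end is not None else None,
                renege_ts=_ts(epoch, renege) if renege is not None else None,
                # risk is a counselor rating: only chats that actually ran have one
                risk_level=case.risk if case.end is not None else None,
                counselor_id=f"c{case.counselor}" if case.counselor is not None else None,
            )
        )
    return out


def _ts(epoch, minutes):
    return epoch + timedelta(seconds=round(minutes * 60.0))


# ---------------------------------------------------------------------------
# bootstrap replication
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Replication ensemble: per-rep tallies plus pooled hourly aggregates."""

    config: ScenarioConfig
    tallies: pd.DataFrame  # one row per replication
    queue_hist: np.ndarray
    vacancy_hist: np.ndarray
    dropout_by_hour: np.ndarray
    wait_hours: np.ndarray
    wait_minutes: np.ndarray

    def summary(self) -> pd.DataFrame:
        """Mean and 2.5/97.5-percentile envelope of every tally and of the
        conversion rate across replications."""
        df = self.tallies.copy()
        df["conversion"] = (
            df["served_immediately"] + df["served_after_queue"]
        ) / df["arrivals"]
        rows = []
        for col in df.columns:
            x = df[col].to_numpy(dtype=float)
            rows.append(
                {
                    "statistic": col,
                    "mean": float(np.mean(x)),
                    "lower": float(np.percentile(x, 2.5)),
                    "upper": float(np.percentile(x, 97.5)),
                }
            )
        return pd.DataFrame(rows)


def run_bootstrap(
    config: ScenarioConfig,
    replications: Optional[int] = None,
    seed: Optional[int] = None,
    keep_logs: bool = False,
) -> BootstrapResult:
    """Run ``replications`` independent replications with seeds spawned
    deterministically from the master seed; aggregate hour-of-day series by
    pooling and tallies as a per-replication table."""
    config.validate()
    n = replications if replications is not None else config.replications
    if n < 1:
        raise ConfigError("need at least one replication")
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    children = master.spawn(n)
    reps = []
    for ss in children:
        reps.append(run_replication(config, np.random.default_rng(ss), keep_log=keep_logs))
    tallies = pd.DataFrame([r.tallies for r in reps])
    maxvac = max(r.vacancy_hist.shape[1] for r in reps)
    vac = np.zeros((24, maxvac), dtype=np.int64)
    for r in reps:
        vac[:, : r.vacancy_hist.shape[1]] += r.vacancy_hist
    return BootstrapResult(
        config=config,
        tallies=tallies,
        queue_hist=np.sum([r.queue_hist for r in reps], axis=0),
        vacancy_hist=vac,
        dropout_by_hour=np.sum([r.dropout_by_hour for r in reps], axis=0),
        wait_hours=np.concatenate([r.wait_hours for r in reps]) if reps else np.empty(0),
        wait_minutes=np.concatenate([r.wait_minutes for r in reps]) if reps else np.empty(0),
    )
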
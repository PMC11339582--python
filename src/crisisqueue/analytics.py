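"""Decision surfaces computed from simulation results.

Turns replication ensembles into the quantities a service manager acts
on: the conversion-rate decomposition (TOS gate x pickup share), hourly
queue-length and waiting-time probability profiles with service-pledge
conformity flags, the hour-of-day dropout density, counselor vacancy
distributions, normalized cost-vs-failure curves with their intersection
(the cost-effectiveness optimum), and the forecast-vs-actual repeat-share
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import BootstrapResult, RepResult
from .records import ChatRecord

__all__ = [
    "ConversionDecomposition",
    "decompose_conversion",
    "conversion_from_log",
    "hourly_queue_profiles",
    "pledge_check",
    "dropout_density",
    "window_dropout",
    "vacancy_distribution",
    "CostEffectivenessPoint",
    "CostEffectivenessResult",
    "cost_effectiveness_curves",
    "saturation_scenarios",
    "repeat_share",
    "RepeatShare",
    "contingency_proportions",
]


def _round2(x: float) -> float:
    """Half-up rounding to 2 decimals, applied only at the reporting boundary."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# conversion decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConversionDecomposition:
    """Overall conversion = P(TOS) x (immediate + queued-served shares).

    The shares are fractions of TOS-accepting users; ``overall`` is the
    fraction of *all* visitors ultimately served by a counselor.
    """

    p_tos: float
    frac_immediate: float
    frac_queued_served: float
    frac_reneged: float
    frac_in_system: float
    overall: float

    @classmethod
    def from_fractions(
        cls, p_tos: float, frac_immediate: float, frac_queued_served: float,
        frac_reneged: float = float("nan"), frac_in_system: float = float("nan"),
    ) -> "ConversionDecomposition":
        return cls(
            p_tos=p_tos,
            frac_immediate=frac_immediate,
            frac_queued_served=frac_queued_served,
            frac_reneged=frac_reneged,
            frac_in_system=frac_in_system,
            overall=p_tos * (frac_immediate + frac_queued_served),
        )


def decompose_conversion(source) -> ConversionDecomposition:
    """Decompose conversion from tallies, a RepResult, or a BootstrapResult
    (summed over replications)."""
    if isinstance(source, RepResult):
        t = source.tallies
    elif isinstance(source, BootstrapResult):
        t = source.tallies.sum().to_dict()
    elif isinstance(source, dict):
        t = source
    else:
        raise TypeError("source must be tallies, RepResult, or BootstrapResult")
    arrivals = t["arrivals"]
    if arrivals <= 0:
        raise ValueError("conversion undefined with zero arrivals")
    acc = t["tos_accepted"]
    if acc == 0:
        return ConversionDecomposition(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    return ConversionDecomposition.from_fractions(
        p_tos=acc / arrivals,
        frac_immediate=t["served_immediately"] / acc,
        frac_queued_served=t["served_after_queue"] / acc,
        frac_reneged=t["reneged"] / acc,
        frac_in_system=t.get("in_system_at_horizon", 0) / acc,
    )


def conversion_from_log(
    records: Sequence[ChatRecord], zero_wait_window_s: float = 60.0
) -> ConversionDecomposition:
    """Recompute the decomposition straight from an event log — an
    independent code path from the tally-based one, used as a consistency
    check."""
    window = zero_wait_window_s / 60.0
    arrivals = len(records)
    if arrivals == 0:
        raise ValueError("empty log")
    acc = imm = queued = reneged = 0
    for r in records:
        if not r.tos_accepted:
            continue
        acc += 1
        if r.is_served:
            if r.wait_minutes <= window:
                imm += 1
            else:
                queued += 1
        elif r.renege_ts is not None:
            reneged += 1
    if acc == 0:
        return ConversionDecomposition(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    return ConversionDecomposition.from_fractions(
        p_tos=acc / arrivals,
        frac_immediate=imm / acc,
        frac_queued_served=queued / acc,
        frac_reneged=reneged / acc,
        frac_in_system=(acc - imm - queued - reneged) / acc,
    )


# ---------------------------------------------------------------------------
# hourly queue / wait profiles and the service pledge
# ---------------------------------------------------------------------------


def hourly_queue_profiles(
    boot: BootstrapResult,
    queue_lengths: Sequence[int] = (0, 1, 2, 3, 5, 10),
    wait_limits: Sequence[float] = (1, 2, 5, 10, 15, 30),
) -> pd.DataFrame:
    """Per-hour P(queue length <= k) and P(wait <= w), pooled over
    replications.  Queue probabilities are minute-weighted; wait
    probabilities are over users who queued and were eventually served."""
    if boot.queue_hist.sum() == 0:
        raise ValueError("no hourly series present")
    rows = []
    for hour in range(24):
        qrow = boot.queue_hist[hour].astype(float)
        qtot = qrow.sum()
        waits = boot.wait_minutes[boot.wait_hours == hour]
        row = {"hour": hour}
        for k in queue_lengths:
            row[f"p_queue_le_{k}"] = float(qrow[: k + 1].sum() / qtot) if qtot else np.nan
        for w in wait_limits:
            row[f"p_wait_le_{int(w)}"] = (
                float(np.mean(waits <= w)) if waits.size else np.nan
            )
        row["n_queued_served"] = int(waits.size)
        rows.append(row)
    return pd.DataFrame(rows)


def pledge_check(
    boot: BootstrapResult,
    wait_limit_minutes: float = 10.0,
    queue_limit: int = 1,
    prob: float = 0.85,
) -> pd.DataFrame:
    """Service-pledge conformity per hour: at least an 85% chance of service
    within 10 minutes, and an 85% chance of at most 1 person in line.

    Hours with no queued-served users pass the wait pledge vacuously (no
    one waited past the zero-wait window).
    """
    prof = hourly_queue_profiles(
        boot, queue_lengths=(queue_limit,), wait_limits=(wait_limit_minutes,)
    )
    wait_col = f"p_wait_le_{int(wait_limit_minutes)}"
    queue_col = f"p_queue_le_{queue_limit}"
    out = prof[["hour", wait_col, queue_col, "n_queued_served"]].copy()
    out["wait_pledge_pass"] = out[wait_col].fillna(1.0) >= prob
    out["queue_pledge_pass"] = out[queue_col] >= prob
    return out


# ---------------------------------------------------------------------------
# dropout density and vacancy
# ---------------------------------------------------------------------------


def dropout_density(boot: BootstrapResult) -> pd.DataFrame:
    """Hour-of-day discrete dropout probability density over all reneges in
    all replications; sums to 1 over the 24 bins."""
    counts = np.asarray(boot.dropout_by_hour, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("no reneged cases across replications; density undefined")
    return pd.DataFrame({"hour": np.arange(24), "count": counts, "density": counts / total})


def window_dropout(density: pd.DataFrame, start_hour: int, end_hour: int) -> dict:
    """Cumulative dropout probability over the closed-open window
    [start_hour, end_hour), with the mean and SD of its hourly densities."""
    hours = np.arange(start_hour, end_hour) % 24
    d = density.set_index("hour").loc[hours, "density"].to_numpy()
    return {
        "cumulative": float(d.sum()),
        "hourly_mean": float(d.mean()),
        "hourly_sd": float(d.std(ddof=0)),
    }


def vacancy_distribution(boot: BootstrapResult) -> pd.DataFrame:
    """Per-hour probability distribution of unused concurrent capacity,
    minute-weighted and pooled across replications."""
    hist = boot.vacancy_hist.astype(float)
    rows = []
    for hour in range(24):
        tot = hist[hour].sum()
        for vac in range(hist.shape[1]):
            if hist[hour, vac] or vac == 0:
                rows.append(
                    {
                        "hour": hour,
                        "vacancy": vac,
                        "probability": float(hist[hour, vac] / tot) if tot else np.nan,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cost-effectiveness curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CostEffectivenessPoint:
    """One evaluated staffing scenario on the cost/effectiveness chart."""

    label: str
    total_cost: float
    total_capacity: float
    failure_rate: float  # 1 - overall conversion

    def __post_init__(self):
        if self.total_cost <= 0 or self.total_capacity <= 0:
            raise ValueError("staffed scenarios need positive cost and capacity")


@dataclass
class CostEffectivenessResult:
    curves: pd.DataFrame  # capacity, cost, failure, cost_norm, failure_norm
    intersection_capacity: Optional[float]
    nearest_label: Optional[str]


def cost_effectiveness_curves(points: Sequence[CostEffectivenessPoint]) -> CostEffectivenessResult:
    """Normalize the rising cost curve and the falling failure-rate curve to
    a shared [0, 1] axis over capacity and locate their intersection.

    The two curves carry unlike units, so min-max normalization over the
    evaluated capacity range makes the crossing well-defined.  Piecewise
    -linear interpolation between scenarios; bisection on the difference.
    Curves that never cross yield ``intersection_capacity=None``.
    """
    if len(points) < 2:
        raise ValueError("need at least two scenarios")
    pts = sorted(points, key=lambda p: p.total_capacity)
    cap = np.array([p.total_capacity for p in pts], dtype=float)
    if np.unique(cap).size < 2:
        raise ValueError("scenarios must span at least two distinct capacities")
    cost = np.array([p.total_cost for p in pts], dtype=float)
    fail = np.array([p.failure_rate for p in pts], dtype=float)

    def norm(x):
        lo, hi = float(np.min(x)), float(np.max(x))
        return np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)

    cost_n, fail_n = norm(cost), norm(fail)
    grid = np.linspace(cap[0], cap[-1], 2049)
    diff = np.interp(grid, cap, cost_n) - np.interp(grid, cap, fail_n)
    crossing = None
    sign = np.sign(diff)
    idx = np.where(np.diff(sign) != 0)[0]
    exact = np.where(sign == 0)[0]
    if exact.size:
        crossing = float(grid[exact[0]])
    elif idx.size:
        i = idx[0]  # linear bracket -> solve the segment analytically
        x0, x1, d0, d1 = grid[i], grid[i + 1], diff[i], diff[i + 1]
        crossing = float(x0 - d0 * (x1 - x0) / (d1 - d0))
    nearest = None
    if crossing is not None:
        nearest = pts[int(np.argmin(np.abs(cap - crossing)))].label
    curves = pd.DataFrame(
        {
            "capacity": cap,
            "cost": cost,
            "failure_rate": fail,
            "cost_norm": cost_n,
            "failure_norm": fail_n,
            "label": [p.label for p in pts],
        }
    )
    return CostEffectivenessResult(curves, crossing, nearest)


def saturation_scenarios(
    points: Sequence[CostEffectivenessPoint], threshold_pp_per_counselor: float = 0.5
) -> list[str]:
    """Labels of scenarios past the saturation knee: where the failure-rate
    improvement per added unit of capacity falls below the threshold (in
    percentage points)."""
    pts = sorted(points, key=lambda p: p.total_capacity)
    out = []
    for prev, cur in zip(pts, pts[1:]):
        dcap = cur.total_capacity - prev.total_capacity
        if dcap <= 0:
            continue
        gain_pp = (prev.failure_rate - cur.failure_rate) * 100.0 / dcap
        if gain_pp < threshold_pp_per_counselor:
            out.append(cur.label)
    return out


# ---------------------------------------------------------------------------
# repeat share and contingency proportions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepeatShare:
    """Share of traffic attributed to repeat users: the gap between actual
    arrivals and the de-excited (immigrant-only) forecast."""

    share: float
    actual: float
    forecast: float
    warning: Optional[str] = None


def repeat_share(actual_arrivals: float, forecast_expected: float) -> RepeatShare:
    """(actual - forecast) / actual.  A forecast above the actual count is
    returned with a warning status rather than raising."""
    if actual_arrivals <= 0:
        raise ValueError("actual arrivals must be positive")
    if forecast_expected < 0:
        raise ValueError("forecast must be nonnegative")
    share = (actual_arrivals - forecast_expected) / actual_arrivals
    warning = "forecast-exceeds-actual" if forecast_expected > actual_arrivals else None
    return RepeatShare(share=share, actual=actual_arrivals, forecast=forecast_expected, warning=warning)


def contingency_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise percentages of a labeled contingency table, rounded
    half-up to 2 decimals at the reporting boundary.  Columns with a zero
    total come back as NaN (flagged undefined)."""
    table = pd.DataFrame(table)
    if (table.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    out = {}
    for col in table.columns:
        total = table[col].sum()
        if total == 0:
            out[col] = [float("nan")] * len(table)
        else:
            out[col] = [_round2(100.0 * v / total) for v in table[col]]
    return pd.DataFrame(out, index=table.index)
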
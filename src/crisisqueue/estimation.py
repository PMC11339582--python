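"""Estimators that turn an event log into simulator inputs.

The pipeline mirrors how the operating statistics of a 24/7 text
counseling service are actually derived:

* TOS acceptance is a Bernoulli probability (accepted / total) with a
  binomial confidence interval;
* chat durations, after 1.5xIQR outlier removal per stratum, follow a
  scaled beta fitted by the method of moments (the reproducible surface is
  the stratum mean and SD);
* queue *patience* (time to renege) and *virtual waiting time* (wait of an
  infinitely patient user) are latent and estimated by right-censored
  exponential maximum likelihood: for patience, reneges are events and
  pickups are censored observations, and vice versa for the virtual wait.
  Pickups within the 60-second zero-wait window never queued and are
  excluded;
* arrivals are aggregated into 2-hour bins — counting only the first
  instance of each identifier per bin, a proxy for purging self-excited
  repeat re-contacts — giving the mean-interarrival series whose
  reciprocal is the arrival rate lambda(t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .params import DurationModel, ParameterSet, PatienceModel
from .records import ChatRecord

__all__ = [
    "EstimationError",
    "TosEstimate",
    "estimate_tos_probability",
    "iqr_filter",
    "fit_scaled_beta",
    "fit_duration_model",
    "fit_censored_exponential",
    "fit_patience",
    "logrank_test",
    "RateSeries",
    "aggregate_interarrivals",
    "boxcox",
    "inverse_boxcox_bias_adjusted",
    "choose_boxcox_lambda",
    "tally_valid_cases",
    "estimate_all",
]


class EstimationError(ValueError):
    """Raised when an estimator's preconditions are not met."""


# ---------------------------------------------------------------------------
# TOS probability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TosEstimate:
    p: float
    ci_low: float
    ci_high: float
    n_accepted: int
    n_total: int


def estimate_tos_probability(records: Sequence[ChatRecord], alpha: float = 0.05) -> TosEstimate:
    """Point estimate accepted/total with a normal-approximation binomial CI."""
    n = len(records)
    if n == 0:
        raise EstimationError("empty log")
    k = sum(1 for r in records if r.tos_accepted)
    p = k / n
    half = stats.norm.ppf(1 - alpha / 2) * math.sqrt(max(p * (1 - p), 0.0) / n)
    return TosEstimate(p, max(p - half, 0.0), min(p + half, 1.0), k, n)


# ---------------------------------------------------------------------------
# chat durations: IQR filter + scaled-beta method of moments
# ---------------------------------------------------------------------------


def iqr_filter(x: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Drop values outside [Q1 - k*IQR, Q3 + k*IQR], iterated to a fixed
    point so the filter is idempotent (a single pass is not: refiltering a
    heavy-tailed sample recomputes tighter fences).  For light-tailed data
    the first pass already converges."""
    x = np.asarray(x, dtype=float)
    while True:
        q1, q3 = np.percentile(x, [25, 75])
        iqr = q3 - q1
        kept = x[(x >= q1 - k * iqr) & (x <= q3 + k * iqr)]
        if kept.size == x.size:
            return kept
        x = kept


def fit_scaled_beta(
    durations: np.ndarray,
    user_type: str = "all",
    risk_level: str = "low",
    scale: Optional[float] = None,
    iqr_k: float = 1.5,
) -> DurationModel:
    """IQR-filter then moment-match a beta on [0, scale].

    ``scale`` defaults to the maximum retained duration, preserving the
    observed range and keeping the moment fit well-posed.
    """
    x = np.asarray(durations, dtype=float)
    if x.size < 10:
        raise EstimationError(
            f"only {x.size} completed chats in stratum ({user_type}, {risk_level}); pool strata"
        )
    q1, q3 = np.percentile(x, [25, 75])
    if q3 - q1 <= 0:
        raise EstimationError("degenerate sample: IQR is zero")
    kept = iqr_filter(x, iqr_k)
    mean = float(kept.mean())
    sd = float(kept.std(ddof=1))
    if sd <= 0:
        raise EstimationError("retained durations have zero variance")
    if scale is None:
        scale = float(kept.max())
        if scale <= mean:  # happens only for pathological two-point samples
            scale = mean + 4.0 * sd
        # nudge the support out if the sample is too concentrated at the max
        m = mean / scale
        if (sd / scale) ** 2 >= m * (1 - m):
            scale = mean + 4.0 * sd
    return DurationModel.from_moments(
        mean, sd, scale=scale, user_type=user_type, risk_level=risk_level, n_used=int(kept.size)
    )


def fit_duration_model(
    records: Sequence[ChatRecord],
    user_type: str = "all",
    risk_level: str = "low",
    scale: Optional[float] = None,
) -> DurationModel:
    """Fit the (user type, risk level) stratum's duration model from a log.

    ``user_type='all'`` pools both user types; served chats only (zombie
    survey pickups carry a renege stamp and are excluded).
    """
    durs = [
        r.service_minutes
        for r in records
        if r.is_served
        and r.end_ts is not None
        and (user_type == "all" or r.user_type == user_type)
        and r.risk_level == risk_level
    ]
    return fit_scaled_beta(np.array(durs, dtype=float), user_type, risk_level, scale=scale)


# ---------------------------------------------------------------------------
# patience / virtual waiting time: censored exponential MLE
# ---------------------------------------------------------------------------


def fit_censored_exponential(
    times: np.ndarray, observed: np.ndarray, user_type: str = "all"
) -> PatienceModel:
    """Right-censored exponential MLE: mean = sum(all times) / n_events.

    ``observed`` flags event times (uncensored); the rest are censored at
    their recorded time.  The standard error is mean/sqrt(n_events).
    """
    times = np.asarray(times, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    if times.shape != observed.shape:
        raise ValueError("times and observed flags must align")
    n_events = int(observed.sum())
    if n_events == 0:
        raise EstimationError("no uncensored events: exponential MLE undefined")
    mean = float(times.sum() / n_events)
    return PatienceModel(
        user_type=user_type,
        mean_minutes=mean,
        se_minutes=mean / math.sqrt(n_events),
        n_events=n_events,
        n_censored=int(times.size - n_events),
    )


def _queue_waits(
    records: Sequence[ChatRecord],
    user_type: str,
    zero_wait_window_s: float,
):
    """Waits of queued users: (time, reneged?) pairs; zero-wait pickups excluded."""
    window_min = zero_wait_window_s / 60.0
    times, reneged = [], []
    for r in records:
        if not r.tos_accepted or (user_type != "all" and r.user_type != user_type):
            continue
        if r.renege_ts is not None:
            times.append(r.renege_wait_minutes)
            reneged.append(True)
        elif r.pickup_ts is not None:
            w = r.wait_minutes
            if w is not None and w > window_min:
                times.append(w)
                reneged.append(False)
    return np.array(times, dtype=float), np.array(reneged, dtype=bool)


def fit_patience(
    records: Sequence[ChatRecord],
    user_type: str = "all",
    censoring: str = "patience",
    zero_wait_window_s: float = 60.0,
) -> PatienceModel:
    """Censored-exponential fit of patience or virtual waiting time.

    ``censoring='patience'``: reneges are observed events, pickups are
    right-censored (the user would have waited longer).
    ``censoring='virtual_wait'``: the reverse — pickups observe the offered
    wait, reneges censor it.
    """
    if censoring not in ("patience", "virtual_wait"):
        raise ValueError("censoring must be 'patience' or 'virtual_wait'")
    times, reneged = _queue_waits(records, user_type, zero_wait_window_s)
    if times.size == 0:
        raise EstimationError("no queued cases to analyze")
    observed = reneged if censoring == "patience" else ~reneged
    return fit_censored_exponential(times, observed, user_type=user_type)


def logrank_test(
    times_a: np.ndarray,
    observed_a: np.ndarray,
    times_b: np.ndarray,
    observed_b: np.ndarray,
):
    """Two-group log-rank test; returns (statistic, p_value).

    Used to decide whether repeat and nonrepeat users need separate
    patience models.
    """
    from lifelines.statistics import logrank_test as _lr

    observed_a = np.asarray(observed_a, dtype=bool)
    observed_b = np.asarray(observed_b, dtype=bool)
    if len(times_a) == 0 or len(times_b) == 0:
        raise EstimationError("both groups must be nonempty")
    if observed_a.sum() == 0 or observed_b.sum() == 0:
        raise EstimationError("a group with zero events has no log-rank contribution")
    res = _lr(times_a, times_b, event_observed_A=observed_a, event_observed_B=observed_b)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# interarrival aggregation (2-hour bins, first-identifier-per-bin)
# ---------------------------------------------------------------------------


@dataclass
class RateSeries:
    """Binned mean-interarrival series at fixed spacing.

    ``mean_interarrival_minutes[i]`` is bin_width / (deduplicated arrival
    count in bin i); its reciprocal is the bin's arrival rate per minute.
    """

    bin_start: pd.DatetimeIndex
    mean_interarrival_minutes: np.ndarray
    bin_width_minutes: float
    imputed: np.ndarray = field(default=None)  # bool mask of interpolated bins
    boxcox_lambda: Optional[float] = None

    def __post_init__(self):
        if self.imputed is None:
            self.imputed = np.zeros(len(self.mean_interarrival_minutes), dtype=bool)
        if np.any(self.mean_interarrival_minutes <= 0):
            raise ValueError("mean interarrivals must be strictly positive")

    @property
    def rate_per_min(self) -> np.ndarray:
        return 1.0 / self.mean_interarrival_minutes

    @property
    def bin_mid_minutes(self) -> np.ndarray:
        """Bin midpoints in minutes from the first bin start."""
        offs = (self.bin_start - self.bin_start[0]).total_seconds() / 60.0
        return np.asarray(offs) + self.bin_width_minutes / 2.0


def aggregate_interarrivals(
    records: Sequence[ChatRecord], bin_width_minutes: float = 120.0
) -> RateSeries:
    """Aggregate arrivals into fixed bins and return mean interarrivals.

    Only the first arrival of each identifier within a bin is counted
    (offspring purging proxy).  Bins with fewer than 2 arrivals get a
    NaN mean, are neighbor-interpolated, and flagged in ``imputed``.
    Bins are anchored at the midnight preceding the first arrival so a
    2-hour width yields the 12 standard time-of-day slots.
    """
    arrivals = pd.DataFrame(
        {
            "identifier": [r.user_id for r in records],
            "ts": [r.arrival_ts for r in records],
        }
    )
    if len(arrivals) < 2:
        raise EstimationError("need at least two arrivals to aggregate")
    arrivals = arrivals.sort_values("ts")
    width = pd.Timedelta(minutes=bin_width_minutes)
    origin = arrivals["ts"].iloc[0].normalize()
    binned = (arrivals["ts"] - origin) // width
    arrivals = arrivals.assign(bin=binned)
    deduped = arrivals.drop_duplicates(subset=["identifier", "bin"])
    first_bin, last_bin = int(binned.iloc[0]), int(binned.iloc[-1])
    idx = np.arange(first_bin, last_bin + 1)
    counts = deduped.groupby("bin").size().reindex(idx, fill_value=0)
    mean_ia = np.where(counts.to_numpy() >= 2, bin_width_minutes / counts.to_numpy(), np.nan)
    imputed = ~np.isfinite(mean_ia)
    if imputed.all():
        raise EstimationError("no bin holds two or more arrivals")
    mean_ia = (
        pd.Series(mean_ia).interpolate(limit_direction="both").to_numpy()
    )
    starts = pd.DatetimeIndex([origin + int(b) * width for b in idx])
    return RateSeries(
        bin_start=starts,
        mean_interarrival_minutes=mean_ia,
        bin_width_minutes=float(bin_width_minutes),
        imputed=imputed,
    )


# ---------------------------------------------------------------------------
# Box-Cox transform with bias-adjusted inverse
# ---------------------------------------------------------------------------


_LAM_EPS = 1e-8  # below this the power form is numerically indistinguishable from log


def boxcox(x, lam: float):
    """Forward Box-Cox: (x^lam - 1)/lam, or log x at lam ~ 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive data")
    if abs(lam) < _LAM_EPS:
        return np.log(x)
    return (np.power(x, lam) - 1.0) / lam


def inverse_boxcox_bias_adjusted(mean, variance, lam: float):
    """Back-transform a (mean, variance) on the transformed scale to an
    *expected value* on the original scale, not a median.

    At lam = 0 the exact lognormal mean exp(m + v/2) is used; for other
    lam the second-order variance correction applies.  With zero variance
    both reduce to the plain inverse transform.
    """
    mean = np.asarray(mean, dtype=float)
    variance = np.asarray(variance, dtype=float)
    if np.any(variance < 0):
        raise ValueError("variance must be nonnegative")
    if abs(lam) < _LAM_EPS:
        return np.exp(mean) * np.exp(variance / 2.0)
    base = lam * mean + 1.0
    if np.any(base <= 0):
        raise ValueError("back-transform domain violated (lam*mean + 1 <= 0)")
    plain = np.power(base, 1.0 / lam)
    return plain * (1.0 + variance * (1.0 - lam) / (2.0 * base**2))


def choose_boxcox_lambda(x) -> float:
    """Profile-MLE Box-Cox lambda for a positive series."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive data")
    _, lam = stats.boxcox(x)
    return float(lam)


# ---------------------------------------------------------------------------
# valid-case tally
# ---------------------------------------------------------------------------


def tally_valid_cases(records: Sequence[ChatRecord], threshold_minutes: float = 7.5) -> int:
    """Count served chats lasting at least ``threshold_minutes`` (inclusive).

    7.5 minutes is the median duration of invalid cases and serves as a
    ballpark proxy for the >=4-exchange definition of a valid case, which
    cannot itself be simulated.
    """
    n = 0
    for r in records:
        if r.is_served and r.end_ts is not None:
            if r.service_minutes >= threshold_minutes:
                n += 1
    return n


# ---------------------------------------------------------------------------
# one-shot pipeline
# ---------------------------------------------------------------------------


def estimate_all(records: Sequence[ChatRecord], zero_wait_window_s: float = 60.0) -> ParameterSet:
    """Fit every simulator input from a log; strata too small to fit a
    duration model fall back to the pooled ('all') fit for that risk level."""
    tos = estimate_tos_probability(records)
    accepted = [r for r in records if r.tos_accepted]
    if not accepted:
        raise EstimationError("no TOS-accepting records")
    n_nonrepeat = sum(1 for r in accepted if r.user_type == "nonrepeat")
    user_type_p = n_nonrepeat / len(accepted)

    risk_mix: dict = {}
    for ut in ("nonrepeat", "repeat"):
        served = [r for r in accepted if r.user_type == ut and r.is_served and r.risk_level]
        if served:
            counts = pd.Series([r.risk_level for r in served]).value_counts()
            total = counts.sum()
            risk_mix[ut] = {
                lvl: float(counts.get(lvl, 0) / total) for lvl in ("low", "medium", "high_crisis")
            }

    duration: dict = {}
    pooled: dict = {}
    for risk in ("low", "medium", "high_crisis"):
        try:
            pooled[risk] = fit_duration_model(records, "all", risk)
        except EstimationError:
            pass
    # last resort for rare strata: pool every served chat regardless of risk
    all_durations = np.array(
        [r.service_minutes for r in records if r.is_served and r.end_ts is not None]
    )
    global_model = None
    if all_durations.size >= 10:
        try:
            global_model = fit_scaled_beta(all_durations, "all", "low")
        except EstimationError:
            pass
    for ut in ("nonrepeat", "repeat"):
        for risk in ("low", "medium", "high_crisis"):
            try:
                duration[(ut, risk)] = fit_duration_model(records, ut, risk)
            except EstimationError:
                if risk in pooled:
                    duration[(ut, risk)] = pooled[risk]
                elif global_model is not None:
                    duration[(ut, risk)] = global_model

    patience: dict = {}
    virtual: dict = {}
    for ut in ("nonrepeat", "repeat", "all"):
        try:
            patience[ut] = fit_patience(records, ut, "patience", zero_wait_window_s)
            virtual[ut] = fit_patience(records, ut, "virtual_wait", zero_wait_window_s)
        except EstimationError:
            pass

    return ParameterSet(
        tos_p=tos.p,
        tos_ci=(tos.ci_low, tos.ci_high),
        user_type_p=user_type_p,
        risk_mix=risk_mix,
        duration=duration,
        patience=patience,
        virtual_wait=virtual,
        meta={"n_records": len(records)},
    )
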
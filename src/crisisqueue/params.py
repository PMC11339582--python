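"""Fitted input models and parameter containers for the simulator.

Service (chat) durations follow a scaled beta law: tau_c ~ scale * Beta(a, b)
on [0, scale] minutes, stratified by user type (nonrepeat vs repeat) and the
counselor-rated risk level.  Queue patience is exponential per user type.
The TOS consent gate is Bernoulli(p) and independent of time.

``reference()`` builds a complete parameter set mirroring the published
operating statistics of a 24-hour web-based crisis counseling platform
(Dec 2019 - Nov 2020): TOS acceptance 74.78%, low/medium/high-crisis risk
mix near 89/10/1, mean chat durations of roughly 50/72/92 minutes by rising
risk level, and mean patience of 3.455 min (nonrepeat) and 5.2895 min
(repeat).  These are the study conditions every estimator and the simulator
are exercised against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

from .ratefn import RateFunction

__all__ = [
    "DurationModel",
    "PatienceModel",
    "GroundTruthParams",
    "ParameterSet",
    "TOS_P_REFERENCE",
    "NONREPEAT_P_REFERENCE",
    "DURATION_MOMENTS_REFERENCE",
    "RISK_MIX_REFERENCE",
    "PATIENCE_MEAN_REFERENCE",
    "VIRTUAL_WAIT_MEAN_REFERENCE",
    "default_hourly_profile",
    "default_rate_function",
]


class ModelInvariantError(ValueError):
    """A fitted model violates one of its structural invariants."""


# ---------------------------------------------------------------------------
# reference operating statistics (observed service data, Dec 2019 - Nov 2020)
# ---------------------------------------------------------------------------

TOS_P_REFERENCE = 0.7478  # 62,081 of 83,013 visitors accepted the TOS
NONREPEAT_P_REFERENCE = 0.7108  # 44,125 of 62,081 accepted users were first-timers

#: (mean, sd) of chat duration in minutes, after 1.5xIQR outlier removal,
#: keyed by (user_type, risk_level); 'all' pools both user types.
DURATION_MOMENTS_REFERENCE = {
    ("nonrepeat", "low"): (50.07, 30.97),
    ("nonrepeat", "medium"): (70.85, 36.80),
    ("nonrepeat", "high_crisis"): (89.45, 44.18),
    ("repeat", "low"): (51.2, 34.49),
    ("repeat", "medium"): (75.25, 45.78),
    ("repeat", "high_crisis"): (121.29, 83.30),
    ("all", "low"): (50.21, 31.65),
    ("all", "medium"): (71.95, 38.87),
    ("all", "high_crisis"): (92.01, 47.32),
}

#: P(risk level | user type) over (low, medium, high_crisis).
RISK_MIX_REFERENCE = {
    "nonrepeat": {"low": 0.8905, "medium": 0.1033, "high_crisis": 0.0062},
    "repeat": {"low": 0.8880, "medium": 0.1042, "high_crisis": 0.0078},
}

#: Exponential patience mean (minutes) from censored survival estimation.
PATIENCE_MEAN_REFERENCE = {"nonrepeat": 3.4550, "repeat": 5.2895, "all": 4.0617}
#: Virtual waiting time mean (minutes), the reverse-censoring estimate.
VIRTUAL_WAIT_MEAN_REFERENCE = {"nonrepeat": 3.1682, "repeat": 5.0100, "all": 3.6759}


@dataclass
class DurationModel:
    """Scaled-beta chat-duration model for one (user type, risk level) stratum.

    The support is [0, scale_minutes] and the shape parameters come from a
    method-of-moments fit, so ``scale * a / (a + b)`` equals the sample mean
    by construction.
    """

    user_type: str
    risk_level: str
    alpha: float
    beta: float
    scale_minutes: float
    n_used: int
    mean_minutes: float
    sd_minutes: float

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0 or self.scale_minutes <= 0:
            raise ModelInvariantError("beta shapes and scale must be positive")
        implied = self.scale_minutes * self.alpha / (self.alpha + self.beta)
        if abs(implied - self.mean_minutes) > 1e-9 * max(1.0, self.mean_minutes):
            raise ModelInvariantError(
                f"implied mean {implied} != recorded mean {self.mean_minutes}"
            )
        if not 0 < self.mean_minutes < self.scale_minutes:
            raise ModelInvariantError("mean must lie strictly inside (0, scale)")

    @classmethod
    def from_moments(
        cls,
        mean: float,
        sd: float,
        scale: Optional[float] = None,
        user_type: str = "all",
        risk_level: str = "low",
        n_used: int = 0,
    ) -> "DurationModel":
        """Moment-match a scaled beta to (mean, sd) on [0, scale].

        When ``scale`` is omitted it defaults to mean + 4*sd, which covers
        the observed range of IQR-filtered chat durations and always yields
        a valid beta (it requires only sd < 4*mean).
        """
        if mean <= 0 or sd <= 0:
            raise ValueError("mean and sd must be positive")
        if scale is None:
            scale = mean + 4.0 * sd
        m = mean / scale
        v = (sd / scale) ** 2
        if not 0 < m < 1 or v >= m * (1 - m):
            raise ValueError(
                f"moments (mean={mean}, sd={sd}) not attainable by a beta on [0, {scale}]"
            )
        common = m * (1 - m) / v - 1.0
        return cls(
            user_type=user_type,
            risk_level=risk_level,
            alpha=m * common,
            beta=(1 - m) * common,
            scale_minutes=float(scale),
            n_used=n_used,
            mean_minutes=float(mean),
            sd_minutes=float(sd),
        )

    def sample(self, rng: np.random.Generator, size=None):
        """Draw durations in minutes."""
        return self.scale_minutes * rng.beta(self.alpha, self.beta, size=size)


@dataclass
class PatienceModel:
    """Exponential queue-patience (or virtual-wait) model.

    ``mean_minutes`` may be ``inf`` to represent infinitely patient users
    (useful for analytic-oracle configurations).
    """

    user_type: str
    mean_minutes: float
    se_minutes: float = float("nan")
    n_events: int = 0
    n_censored: int = 0

    def __post_init__(self):
        if not self.mean_minutes > 0:
            raise ModelInvariantError("patience mean must be positive")

    def sample(self, rng: np.random.Generator, size=None):
        if math.isinf(self.mean_minutes):
            return np.full(size if size is not None else (), np.inf) if size is not None else math.inf
        return rng.exponential(self.mean_minutes, size=size)


# ---------------------------------------------------------------------------
# ground truth for the synthetic-log generator
# ---------------------------------------------------------------------------


def default_hourly_profile() -> np.ndarray:
    """Relative hour-of-day arrival profile of a 24/7 crisis line.

    Trough between 5 AM and 9 AM (a handful of requests per hour), steady
    daytime build-up, and a 7 PM-midnight peak of 13-16 requests per hour.
    Used as a shape only; callers normalize it to a target monthly volume.
    """
    return np.array(
        [12, 10, 8, 6, 5, 4, 4, 4, 5, 7, 8, 9, 10, 10, 11, 11, 12, 12, 13, 15, 16, 16, 15, 14],
        dtype=float,
    )


def default_rate_function(
    horizon_minutes: float = 43_200.0, total_arrivals: float = 9_175.0
) -> RateFunction:
    """Diurnal intensity normalized to the observed November 2020 traffic
    (9,175 visitors over a 30-day horizon) by default."""
    return RateFunction.from_hourly_profile(
        default_hourly_profile(), horizon_minutes, total_events=total_arrivals
    )


@dataclass
class GroundTruthParams:
    """Known-truth parameters driving the synthetic-log generator."""

    tos_p: float
    user_type_p: float  # probability of 'nonrepeat'
    risk_mix: dict
    duration: dict  # (user_type, risk_level) -> DurationModel
    patience: dict  # user_type -> PatienceModel
    rate_fn: RateFunction

    def validate(self) -> "GroundTruthParams":
        for p in (self.tos_p, self.user_type_p):
            if not 0.0 <= p <= 1.0:
                raise ModelInvariantError(f"probability {p} outside [0, 1]")
        for ut, mix in self.risk_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ModelInvariantError(f"risk mix for {ut} sums to {total}, not 1")
            if any(p < 0 for p in mix.values()):
                raise ModelInvariantError("negative risk probability")
        return self

    @classmethod
    def reference(
        cls,
        horizon_minutes: float = 43_200.0,
        total_arrivals: float = 9_175.0,
        rate_fn: Optional[RateFunction] = None,
    ) -> "GroundTruthParams":
        """Ground truth mirroring the observed service statistics."""
        duration = {
            key: DurationModel.from_moments(m, s, user_type=key[0], risk_level=key[1])
            for key, (m, s) in DURATION_MOMENTS_REFERENCE.items()
            if key[0] != "all"
        }
        patience = {
            ut: PatienceModel(ut, PATIENCE_MEAN_REFERENCE[ut]) for ut in ("nonrepeat", "repeat")
        }
        return cls(
            tos_p=TOS_P_REFERENCE,
            user_type_p=NONREPEAT_P_REFERENCE,
            risk_mix={ut: dict(mix) for ut, mix in RISK_MIX_REFERENCE.items()},
            duration=duration,
            patience=patience,
            rate_fn=rate_fn or default_rate_function(horizon_minutes, total_arrivals),
        ).validate()


# ---------------------------------------------------------------------------
# fitted parameter bundle (estimation output, simulator input)
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    """Everything the simulator needs, as fitted from an event log."""

    tos_p: float
    tos_ci: tuple
    user_type_p: float
    risk_mix: dict
    duration: dict  # (user_type, risk_level) -> DurationModel
    patience: dict  # user_type -> PatienceModel (patience censoring mode)
    virtual_wait: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        payload = {
            "tos_p": float(self.tos_p),
            "tos_ci": [float(x) for x in self.tos_ci],
            "user_type_p": float(self.user_type_p),
            "risk_mix": {ut: {k: float(v) for k, v in mix.items()} for ut, mix in self.risk_mix.items()},
            "duration": {
                f"{ut}/{risk}": {k: (float(v) if isinstance(v, float) else v) for k, v in asdict(dm).items()}
                for (ut, risk), dm in self.duration.items()
            },
            "patience": {ut: asdict(pm) for ut, pm in self.patience.items()},
            "virtual_wait": {ut: asdict(pm) for ut, pm in self.virtual_wait.items()},
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        duration = {}
        for key, kw in payload["duration"].items():
            ut, risk = key.split("/")
            duration[(ut, risk)] = DurationModel(**kw)
        return cls(
            tos_p=payload["tos_p"],
            tos_ci=tuple(payload["tos_ci"]),
            user_type_p=payload["user_type_p"],
            risk_mix=payload["risk_mix"],
            duration=duration,
            patience={ut: PatienceModel(**kw) for ut, kw in payload["patience"].items()},
            virtual_wait={ut: PatienceModel(**kw) for ut, kw in payload.get("virtual_wait", {}).items()},
            meta=payload.get("meta", {}),
        )
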
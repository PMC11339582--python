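"""Synthetic event-log generator with known ground truth.

No public dataset of crisis-line chat logs exists, so every estimator in
this package is validated against logs generated here: NHPP arrivals with
a diurnal intensity, an i.i.d. Bernoulli TOS gate, a categorical risk mix,
scaled-beta chat durations, and exponential queue patience, all under a
deliberately simple greedy occupancy emulation (a fixed bank of
single-chat servers, no shifts).  The generator's job is estimator
testing with recoverable truth, not operational realism — the discrete
-event engine in :mod:`crisisqueue.engine` owns that.
"""

from __future__ import annotations

from datetime import timedelta

import numpy as np

from .arrivals import sample_nhpp
from .params import GroundTruthParams
from .records import ChatRecord, DEFAULT_EPOCH

__all__ = ["generate_synthetic_log"]


def _to_ts(epoch, minutes: float):
    return epoch + timedelta(seconds=round(minutes * 60.0))


def generate_synthetic_log(
    params: GroundTruthParams,
    horizon_minutes: float,
    n_counselors: int = 4,
    seed: int | None = 0,
    epoch=DEFAULT_EPOCH,
) -> list[ChatRecord]:
    """Generate a complete synthetic chat log over ``horizon_minutes``.

    Occupancy emulation: ``n_counselors`` identical servers each handling
    one chat at a time.  An accepted arrival is picked up at the earliest
    server-free time; if that exceeds the user's exponential patience draw,
    the user reneges instead.  Timestamps are rounded to whole seconds.
    """
    if horizon_minutes <= 0:
        raise ValueError("horizon must be positive")
    params.validate()
    rng = np.random.default_rng(seed)
    arrivals = sample_nhpp(params.rate_fn, horizon_minutes, rng)

    free_at = np.zeros(max(int(n_counselors), 1))
    risk_levels = ("low", "medium", "high_crisis")
    records: list[ChatRecord] = []
    for ev in arrivals:
        t = ev.time
        accepted = rng.random() < params.tos_p
        user_type = "nonrepeat" if rng.random() < params.user_type_p else "repeat"
        if not accepted:
            records.append(
                ChatRecord(
                    user_id=ev.identity,
                    channel="web",
                    arrival_ts=_to_ts(epoch, t),
                    tos_accepted=False,
                    user_type=user_type,
                )
            )
            continue
        patience = float(params.patience[user_type].sample(rng))
        j = int(np.argmin(free_at))
        start = max(t, float(free_at[j]))
        if start - t > patience:
            records.append(
                ChatRecord(
                    user_id=ev.identity,
                    channel="web",
                    arrival_ts=_to_ts(epoch, t),
                    tos_accepted=True,
                    user_type=user_type,
                    renege_ts=_to_ts(epoch, t + patience),
                )
            )
            continue
        mix = params.risk_mix[user_type]
        risk = rng.choice(risk_levels, p=[mix[r] for r in risk_levels])
        duration = float(params.duration[(user_type, risk)].sample(rng))
        free_at[j] = start + duration
        records.append(
            ChatRecord(
                user_id=ev.identity,
                channel="web",
                arrival_ts=_to_ts(epoch, t),
                tos_accepted=True,
                user_type=user_type,
                pickup_ts=_to_ts(epoch, start),
                end_ts=_to_ts(epoch, start + duration),
                risk_level=str(risk),
                counselor_id=f"c{j}",
            )
        )
    return records
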
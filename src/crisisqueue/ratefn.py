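"""Time-varying arrival intensity lambda(t).

A :class:`RateFunction` wraps a monotone piecewise-cubic Hermite (PCHIP)
interpolant through (time, rate) knots, the standard shape-preserving
choice for downsampling a binned rate series: it never overshoots below
zero between positive knots.  Time is measured in minutes from the start
of the horizon and rates are events per minute.

``max_rate`` is the supremum of lambda over the domain, evaluated on a
1-minute audit grid (plus the knots); the Lewis-Shedler thinning sampler
uses it as its dominating constant rate.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = ["RateFunction"]


class RateFunction:
    """Nonnegative intensity lambda(t) [events/min] over a finite horizon.

    Parameters
    ----------
    knots_minutes : array-like
        Strictly increasing knot locations in minutes.
    rates_per_min : array-like
        Intensity at each knot; negative values are clipped to zero.
    floor : float
        Lower clamp applied pointwise on evaluation.  Zero by default;
        forecast-derived functions use a tiny positive floor so the
        thinning acceptance ratio stays well-defined.
    """

    def __init__(self, knots_minutes, rates_per_min, floor: float = 0.0):
        knots = np.asarray(knots_minutes, dtype=float)
        values = np.clip(np.asarray(rates_per_min, dtype=float), 0.0, None)
        if knots.ndim != 1 or knots.size < 2:
            raise ValueError("need at least two knots")
        if not np.all(np.diff(knots) > 0):
            raise ValueError("knots must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("rates must be finite")
        self.knots = knots
        self.values = values
        self.floor = float(floor)
        self._interp = PchipInterpolator(knots, values, extrapolate=False)
        grid = np.union1d(np.arange(knots[0], knots[-1], 1.0), knots)
        self._grid = grid
        self.max_rate = float(np.max(self(grid))) if grid.size else float(values.max())

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])

    def __call__(self, t):
        """Evaluate lambda(t); t outside the knot span is clamped to the ends."""
        t = np.asarray(t, dtype=float)
        tc = np.clip(t, self.knots[0], self.knots[-1])
        out = np.clip(self._interp(tc), self.floor, None)
        if out.ndim == 0:
            return float(out)
        return out

    def integral(self, t0: float, t1: float) -> float:
        """Approximate integral of lambda over [t0, t1] (trapezoid, 1-min grid)."""
        if t1 <= t0:
            return 0.0
        grid = np.linspace(t0, t1, max(int(np.ceil(t1 - t0)), 2) + 1)
        return float(np.trapezoid(self(grid), grid))

    # -- constructors ----------------------------------------------------

    @classmethod
    def constant(cls, rate: float, t_end: float) -> "RateFunction":
        """Flat intensity over [0, t_end]."""
        return cls([0.0, float(t_end)], [rate, rate])

    @classmethod
    def from_hourly_profile(
        cls,
        hourly_counts,
        horizon_minutes: float,
        total_events: float | None = None,
        floor: float = 0.0,
    ) -> "RateFunction":
        """Daily-periodic intensity from a 24-entry hour-of-day arrival profile.

        ``hourly_counts[h]`` is the (relative) number of arrivals in hour h of
        any day; knots are placed at hour midpoints, repeated over every day
        of the horizon.  If ``total_events`` is given the profile is rescaled
        so the intensity integrates to that count over the horizon.
        """
        prof = np.asarray(hourly_counts, dtype=float)
        if prof.shape != (24,):
            raise ValueError("hourly profile must have 24 entries")
        horizon = float(horizon_minutes)
        n_days = int(np.ceil(horizon / 1440.0))
        mids = np.concatenate(
            [d * 1440.0 + np.arange(24) * 60.0 + 30.0 for d in range(n_days)]
        )
        vals = np.tile(prof / 60.0, n_days)  # arrivals/hour -> per minute
        # extend to the horizon edges so the domain covers [0, horizon]
        knots = np.concatenate([[0.0], mids, [n_days * 1440.0]])
        edge = 0.5 * (prof[0] + prof[-1]) / 60.0
        vals = np.concatenate([[edge], vals, [edge]])
        keep = knots <= horizon
        if knots[keep][-1] < horizon:
            knots = np.append(knots[keep], horizon)
            vals = np.append(vals[keep], vals[~keep][0] if (~keep).any() else vals[keep][-1])
        else:
            knots, vals = knots[keep], vals[keep]
        fn = cls(knots, vals, floor=floor)
        if total_events is not None:
            scale = total_events / fn.integral(0.0, horizon)
            fn = cls(knots, vals * scale, floor=floor)
        return fn
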
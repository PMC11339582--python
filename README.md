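# crisisqueue

Discrete-event simulation and demand forecasting for 24/7 **text-based
crisis counseling operations** — the queueing problem faced by services
such as Hong Kong's Open Up platform, where anonymous visitors arrive
around the clock, accept (or reject) a terms-of-service gate, wait in a
single FIFO chat queue, and either reach a counselor or give up within
minutes. The package is written for operations analysts and service
managers at such platforms who need to answer: *how many counselors, on
which shifts, at what cost, to meet a service pledge?*

## The models

- **Arrivals.** Visitors form a nonhomogeneous Poisson process with
  intensity λ(t) (per minute), the reciprocal of the mean interarrival
  time aggregated into 2-hour bins. Sampling uses Lewis–Shedler thinning
  against λ\* = max λ(t). The TOS gate is an i.i.d. Bernoulli(p) split,
  so the accepted stream is again NHPP with intensity p·λ(t). Bursty
  re-contacts by *repeat* users follow a self-exciting Hawkes process
  λ(t) = λ₀(t) + Σᵢ φ(t − Tᵢ) with exponential kernel; purging *offspring*
  restores the *immigrant* base process λ₀ that capacity planning needs.
- **Service.** Chat durations are scaled-beta, τ_c ∼ scale·Beta(α_c, β_c),
  fitted by method of moments per (user type × risk level) stratum after
  1.5×IQR outlier removal.
- **Patience.** The time a queued user waits before abandoning is
  exponential and latent; it is estimated by right-censored maximum
  likelihood (reneges are events, pickups are censored — and vice versa
  for the *virtual waiting time* of an infinitely patient user). Pickups
  within a 60-second window are *zero-wait* cases that never queued.
- **Demand forecasting.** The Box-Cox-transformed binned interarrival
  series is decomposed by an unobserved-components state-space model
  z_t = μ_t + γ_t + x_t′β + ε_t (local level, trigonometric seasonal of
  period 12 with harmonic cutoff κ, campaign dummies, AR(1) irregular),
  estimated by Kalman-filter MLE. Forecasts return to the rate scale
  through the *bias-adjusted* inverse Box-Cox, so they estimate the mean
  rather than the median.
- **The floor.** A discrete-event engine simulates overlapping shifts,
  per-counselor simultaneous-chat capacity, breaks, reneging, post-chat
  surveys and *zombies* — reneged cases the platform cannot auto-evict,
  which sit in the case queue until a counselor opens them just to file
  the survey. Bootstrap replication yields mean and 2.5/97.5-percentile
  envelopes for every statistic.

## Worked example

Simulate the reconstructed historical operating point (15 counselors on
4 shifts, ~9,175 visitors over 30 days) with 100 bootstrap replications:

```python
from crisisqueue.engine import ScenarioConfig, run_bootstrap
from crisisqueue import analytics as an

boot = run_bootstrap(ScenarioConfig.base_case(), replications=100, seed=11)
conv = an.decompose_conversion(boot)
print(f"overall conversion : {100*conv.overall:.2f}%")
print(f"  = P(TOS) {100*conv.p_tos:.2f}% x (immediate {100*conv.frac_immediate:.2f}%"
      f" + queued-served {100*conv.frac_queued_served:.2f}%)")
ev = an.window_dropout(an.dropout_density(boot), 19, 24)
print(f"evening (7pm-midnight) dropout share: {100*ev['cumulative']:.1f}%")
```

prints

```
overall conversion : 48.99%
  = P(TOS) 74.74% x (immediate 57.33% + queued-served 8.22%)
evening (7pm-midnight) dropout share: 31.2%
```

Read: 74.74% of visitors accept the TOS; of those, 57.33% are picked up
within a minute and another 8.22% after queueing, so 48.99% of all
visitors reach a counselor. Dropout concentrates in the evening peak —
the hours where extra staffing buys the most. `analytics.pledge_check`
flags, per hour, whether the service pledge (an 85% chance of service
within 10 minutes, and of at most one person in line) holds, and
`analytics.cost_effectiveness_curves` locates the staffing level where
the normalized cost and failure-rate curves intersect.

A CLI wraps the same pipeline: `crisisqueue fixtures | estimate |
forecast | simulate | compare` (see `--help`).

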
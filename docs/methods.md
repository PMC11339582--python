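# Methods

This note documents the modeling assumptions, default parameters, and
numerical choices behind `crisisqueue`, and what its synthetic-data
validation does and does not establish about real service logs.

## Arrival processes

Visitor arrivals are modeled as a nonhomogeneous Poisson process (NHPP)
whose intensity λ(t), in events per minute, is the reciprocal of the mean
interarrival time aggregated into fixed 2-hour bins. A bin's mean
interarrival is `bin_width / count`, where only the **first arrival of
each identifier per bin** is counted — a pragmatic proxy for removing
self-excited repeat re-contacts, which would otherwise violate the
independent-increment property the NHPP needs. Bins with fewer than two
arrivals get no estimate of their own; they are linearly interpolated
from neighbors and flagged.

Sampling uses Lewis–Shedler thinning with the dominating constant rate
λ\* = max λ(t), evaluated on a 1-minute audit grid. A per-window local
maximum (`piecewise=True`) is available and distributionally equivalent;
a property test asserts the equivalence. The candidate layer draws a
Poisson count and sorted uniforms, which realizes the same homogeneous
process as sequential exponential gaps but vectorizes.

Repeat-user burstiness is modeled by a Hawkes cluster process with
exponential kernel φ(u) = η·ω·e^(−ωu): immigrants arrive as NHPP(λ₀);
every event spawns Poisson(η) offspring at Exponential(ω) forward lags,
recursively; η < 1 keeps clusters finite. The kernel *shape* is a package
choice — only the branching ratio enters the purged-rate identity
E[rate] = λ₀/(1 − η), and only the purged immigrant stream feeds
capacity planning. No Hawkes parameters are estimated from data; defaults
used in examples (η = 0.5, ω = 0.2/min) are illustrative.

The built-in diurnal profile places the trough at 5–9 AM (~4–5 arrivals
per hour) and the peak at 7 PM–midnight (~13–16 per hour), normalized so
a 30-day horizon integrates to 9,175 visitors — the observed November
2020 traffic of the reference service. Rate functions are monotone PCHIP
interpolants through bin-midpoint knots, clipped at zero (forecast-derived
ones floored at 1e-9/min so the thinning acceptance ratio stays defined),
with `max_rate` computed on a 1-minute grid.

## Service durations

Chat durations within a (user type × risk level) stratum follow a scaled
beta, τ_c ∼ scale·Beta(α, β) on [0, scale] minutes, fitted by method of
moments after removing values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]. Two
deliberate choices:

- **The IQR filter iterates to a fixed point.** A single pass is not
  idempotent on heavy-tailed samples (refiltering recomputes tighter
  fences); iterating makes idempotence hold by construction. On a clean
  scaled-beta sample the rule trims ~0.5–1% of the legitimate upper tail,
  biasing fitted shapes upward by a few percent — the fitted moments
  still match the retained sample exactly, which is the quantity the
  simulator consumes.
- **The support is not observable.** When fitting from data, scale
  defaults to the maximum retained duration; when moment-matching from
  published (mean, SD) summaries, scale defaults to mean + 4·SD, which
  always yields a valid beta (it needs only SD < 4·mean) and covers the
  observed range. Method of moments is used rather than beta MLE because
  stratum means and SDs are the reproducible surface of the reference
  statistics.

Reference moments (minutes, outliers removed): pooled low risk
50.21 (31.65), medium 71.95 (38.87), high/crisis 92.01 (47.32), with
per-user-type values close by; the risk mix is ~89/10/1 percent for both
user types (high/crisis 0.62% nonrepeat, 0.78% repeat).

## Patience and virtual waiting time

Queue patience τ_r is exponential. It is latent — a picked-up user's
patience is only known to exceed their wait — so the fit is right-censored
exponential maximum likelihood: mean = Σ(all observed and censored
times) / (number of events), with SE mean/√n_events. `patience` mode
treats reneges as events and pickups as censored; `virtual_wait` mode is
the reverse and estimates the wait an infinitely patient user would see.
Pickups within the 60-second zero-wait window are excluded in both modes:
those users never really queued. (Whether the reference fits applied the
window first is not on record; the package applies it consistently.)
Reference means: patience 3.4550 min (nonrepeat) and 5.2895 min (repeat);
a log-rank test utility justifies keeping the two user types separate.
The parametric exponential fit is primary; a nonparametric check via
`lifelines` appears only in the test suite.

## Demand forecasting

The Box-Cox-transformed binned mean-interarrival series is decomposed as

    z_t = μ_t + γ_t + x_t′β + ε_t

with a stochastic local level μ, a trigonometric (frequency-domain)
seasonal γ of period s = 12 bins (one day of 2-hour bins) truncated at κ
harmonics, optional campaign dummy regressors x, and an AR(1) irregular
ε. Estimation is Gaussian MLE via the Kalman filter (statsmodels'
unobserved-components machinery); missing bins are handled natively as
missing observations, not imputed. Choices:

- Seasonal disturbances default to zero (deterministic seasonal) for
  parsimony; a flag makes them stochastic.
- κ is selected by corrected AIC over 1..s/2 when unspecified; AICc
  rather than AIC because the binned series can be short relative to the
  parameter count.
- The Box-Cox λ is chosen by profile maximum likelihood on the series
  unless supplied.
- Holiday regressors are excluded by default; campaign dummies are
  user-supplied dated intervals.
- Residual diagnostics report the Ljung-Box Q (lag 1) and a White-type
  heteroskedasticity statistic H = n·R² from regressing squared one-step
  residuals on fitted values and their squares (χ² with 2 df). Diffuse
  burn-in observations are discarded first.

Forecast means and variances are mapped back to the original scale with
the **bias-adjusted inverse Box-Cox**, so the result estimates E[τ_a],
not its median. At λ = 0 the exact lognormal mean exp(m + v/2) is used;
for other λ the second-order variance correction
(λm+1)^{1/λ}·[1 + v(1−λ)/(2(λm+1)²)] applies; both reduce to the plain
inverse at v = 0. The forecast rate per bin is 1/E[τ_a].

## The discrete-event engine

A single FIFO case queue feeds counselors organized in daily shifts.
Roles carry default simultaneous-chat capacities and cost weights:
duty officer 1 chat / cost 3, full-time counselor 3 chats / cost 2,
volunteer 2 chats / cost 1.5 — capacities are package defaults (only
"multiple concurrent chats" for full-timers is on record), cost weights
are the reference service's published values. All are configurable.

Event semantics:

- Pickups within the zero-wait window (default 60 s) count as served
  immediately; later pickups as served-after-queue, with their waits
  recorded against the **arrival** hour of day.
- A queued user reneges after an exponential patience draw. Under the
  historical behaviour (`zombie_eviction=False`) the reneged case stays
  in the case queue; when a counselor finally opens it, it consumes only
  the post-chat-survey overhead (default 5 minutes — not on record,
  configurable and sensitivity-tested) before the slot frees. With
  eviction on, reneged cases vanish from the queue.
- Risk level is a counselor rating applied at service start and does not
  affect patience. The *draw* of each case's patience, risk, and duration
  happens at arrival time in arrival order, which leaves the dynamics
  unchanged but gives paired-seed scenario comparisons common random
  numbers — zombie-eviction dominance and staffing monotonicity then hold
  replication by replication.
- Counselors accept no new cases outside their shift/break windows;
  in-progress chats always finish. Simultaneous events are ordered
  completion → renege → arrival, then by insertion sequence, so capacity
  freed at an instant is visible to the assignment made at that instant.
- An unstaffed scenario is a valid degenerate run: every accepted case
  reneges or remains in system at the horizon.
- Time is continuous minutes from horizon start; hour-of-day statistics
  derive from t mod 1440. Queue-length and vacancy distributions are
  sampled on a 1-minute grid reconstructed from change-point series.
  Unused capacity is clipped at zero when chats run past shift end.

Conservation — accepted = served-immediately + served-after-queue +
reneged + in-system-at-horizon — is asserted per replication in tests.

Bootstrap replication spawns per-replication seeds deterministically from
a master seed and reports each statistic's mean and 2.5/97.5-percentile
envelope; hourly histograms pool across replications.

## The reconstructed base case

The reference operation ran 15 counselors over 4 parallel shifts, but no
timetable survives, and its statements are not mutually consistent at
desk resolution ("at least 8 simultaneous cases per shift" vs "at most 2
counselors on duty" in the early morning). The shipped default follows
the head-count and break-cycle statements:

| shift | window | staff | concurrent slots |
|---|---|---|---|
| overnight | 00:00–09:00 | 1 full-time + 1 volunteer | 5 |
| day | 09:00–14:00 | duty officer + full-time + 2 volunteers | 8 |
| afternoon | 14:00–19:00 | duty officer + full-time + 2 volunteers | 8 |
| evening | 19:00–24:00 | duty officer + 2 full-time + 2 volunteers | 11 |

with staggered breaks in the three documented break cycles (meal breaks
11 AM–noon; rest breaks 7–10 PM and midnight–1 AM). The overnight
full-timer doubles as duty officer, a documented practice. At ~9,175
visitors/30 days this reconstruction converts ≈49% of visitors, higher
than the historically simulated ≈37%: the historical run used
bootstrapped *actual* (overdispersed, bursty) interarrival times and an
unprinted schedule, while the smooth NHPP profile here congests less.
The package treats the base case as a structurally faithful operating
point, not an exact replica; its conversion is gated only to a wide
plausibility band in the acceptance suite.

The 40-minute processing-time scenario is `duration_scale = 40 / 50.21`
applied uniformly to all strata.

## Cost-effectiveness comparison

Each scenario contributes (total capacity, total cost, failure rate =
1 − overall conversion), where cost and capacity sum role weights and
concurrent slots over the shifts. Cost and failure curves carry unlike
units, so both are min-max normalized to [0, 1] over the evaluated
capacity range before intersecting; the crossing is found by sign change
on a dense grid with the bracketing segment solved analytically
(piecewise-linear curves make this exact). Curves that never cross
return no intersection rather than an error. Scenarios whose marginal
failure-rate improvement falls below 0.5 percentage points per added
slot are flagged as saturated.

## Synthetic data: what it shows and what it does not

The generator emulates the reference service's stochastic structure —
NHPP arrivals with the diurnal profile, Bernoulli TOS (p = 0.7478),
user-type split (71.08% nonrepeat), per-type risk mixes, scaled-beta
durations, exponential patience — under a deliberately simple greedy
occupancy emulation (fixed bank of single-chat servers, no shifts). That
is enough to give every estimator a recoverable ground truth and the
round-trip serialization tests realistic payloads. It does **not**
reproduce overdispersed day-to-day volumes, within-cluster dependence of
repeat re-contacts, transfers between counselors, multi-device identity
drift, or counselor-side behaviour (fatigue, coaching); passing tests
therefore establish estimator correctness under the stated model, not
model adequacy for any particular real log. Timestamps round to whole
seconds, so sub-second queueing effects are out of scope by design.

## Numerical details and edge cases

- Box-Cox |λ| < 1e-8 is treated as the log case.
- Degenerate inputs raise typed errors: empty logs, strata under 10
  chats (with advice to pool), zero-IQR samples, zero-event censored
  fits, nonpositive interarrivals, supercritical Hawkes kernels,
  malformed shift windows.
- `estimate_all` falls back per risk level to the pooled-across-types
  fit, and as a last resort to a global pooled duration model, so a
  sparse log still yields a complete, runnable parameter set.
- Percentages are rounded half-up to two decimals only at reporting
  boundaries; internal math is full precision.
- All samplers are bit-reproducible given a seed; bootstrap seeds come
  from a spawned seed sequence.
- Test problem sizes (6,000-minute oracle horizons with 1,500-minute
  warmup, 200–500 seed ensembles, 10⁶-draw moment checks, a 100-
  replication 30-day bootstrap) were chosen to keep Monte-Carlo error
  well inside the asserted tolerances.

## Known limitations

- No priority queueing or triage-based dequeuing (the reference service
  suspended triage), no language/skill routing, no transfer modeling.
- Hawkes parameters are not estimable from logs in this version.
- The UCM assumes Gaussian disturbances on the transformed scale; heavy
  campaign shocks belong in the dummy regressors, not the irregular.
- Forecast rates are 1/E[τ_a], the convention of the rate-decomposition
  pipeline, which is not the same as E[1/τ_a].
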
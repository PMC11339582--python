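from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crisisqueue import estimation as est
from crisisqueue.params import DurationModel
from crisisqueue.records import ChatRecord

T0 = datetime(2020, 11, 1)


def _arrival(uid, minutes, accepted=True, user_type="nonrepeat"):
    return ChatRecord(uid, "web", T0 + timedelta(minutes=minutes), accepted, user_type)


# ---------------------------------------------------------------------------
# TOS probability
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "n_accepted,n_total,expected",
    [(3, 4, 0.75), (4, 4, 1.0), (62_081, 83_013, 0.7478)],
)
def test_tos_point_estimate(n_accepted, n_total, expected):
    records = [_arrival(f"u{i}", 0.0, accepted=i < n_accepted) for i in range(n_total)]
    out = est.estimate_tos_probability(records)
    assert out.p == pytest.approx(expected, abs=5e-5)
    assert out.ci_low <= out.p <= out.ci_high


def test_tos_empty_log_rejected():
    with pytest.raises(est.EstimationError):
        est.estimate_tos_probability([])


# ---------------------------------------------------------------------------
# durations
# ---------------------------------------------------------------------------


def test_iqr_filter_idempotent(rng):
    for _ in range(20):
        x = rng.gamma(2.0, 20.0, size=rng.integers(50, 2000))
        once = est.iqr_filter(x)
        twice = est.iqr_filter(once)
        assert np.array_equal(once, twice)


def test_beta_moment_fit_recovers_parameters():
    """Average fit over a few samples isolates systematic recovery from
    single-draw noise; the 1.5xIQR trim of a clean beta tail costs a few
    percent of upward shape bias, well inside the 10% band."""
    fits = []
    for seed in range(5):
        x = 180.0 * np.random.default_rng(seed).beta(2.0, 5.0, size=5000)
        model = est.fit_scaled_beta(x, scale=180.0)
        # moment identity holds exactly by construction
        assert model.scale_minutes * model.alpha / (
            model.alpha + model.beta
        ) == pytest.approx(model.mean_minutes, abs=1e-9)
        fits.append((model.alpha, model.beta))
    a, b = np.mean(fits, axis=0)
    assert a == pytest.approx(2.0, rel=0.10)
    assert b == pytest.approx(5.0, rel=0.10)


def test_identical_durations_rejected():
    with pytest.raises(est.EstimationError, match="IQR"):
        est.fit_scaled_beta(np.full(50, 42.0))


def test_small_stratum_advises_pooling():
    with pytest.raises(est.EstimationError, match="pool"):
        est.fit_scaled_beta(np.arange(5, dtype=float))


def test_low_risk_reference_moments_reproduced():
    """Moment-matching the pooled low-risk row (mean 50.21, SD 31.65)
    reproduces those moments exactly in the fitted model."""
    model = DurationModel.from_moments(50.21, 31.65)
    a, b, s = model.alpha, model.beta, model.scale_minutes
    assert s * a / (a + b) == pytest.approx(50.21, abs=1e-12)
    var = s**2 * a * b / ((a + b) ** 2 * (a + b + 1))
    assert np.sqrt(var) == pytest.approx(31.65, abs=1e-9)


def test_fit_duration_model_from_log(reference_log, reference_truth):
    model = est.fit_duration_model(reference_log, "nonrepeat", "low")
    truth = reference_truth.duration[("nonrepeat", "low")]
    # IQR filtering trims the beta tail slightly; moments stay close
    assert model.mean_minutes == pytest.approx(truth.mean_minutes, rel=0.05)
    assert model.sd_minutes == pytest.approx(truth.sd_minutes, rel=0.15)


# ---------------------------------------------------------------------------
# patience / virtual waiting time
# ---------------------------------------------------------------------------


def _censored_sample(rng, n, true_mean=3.455, offered_mean=5.0):
    patience = rng.exponential(true_mean, n)
    offered = rng.exponential(offered_mean, n)
    times = np.minimum(patience, offered)
    reneged = patience < offered
    return times, reneged


def test_censored_mle_recovers_truth(rng):
    times, reneged = _censored_sample(rng, 5000)
    model = est.fit_censored_exponential(times, reneged)
    assert abs(model.mean_minutes - 3.455) < 2 * model.se_minutes
    assert model.n_events + model.n_censored == 5000


def test_censored_mle_consistency():
    """Bias shrinks with n; estimates stay within 3 SEs at every size."""
    rng = np.random.default_rng(7)
    ses = []
    for n in (500, 5_000, 50_000):
        times, reneged = _censored_sample(rng, n)
        model = est.fit_censored_exponential(times, reneged)
        assert abs(model.mean_minutes - 3.455) < 3 * model.se_minutes
        ses.append(model.se_minutes)
    assert ses[0] > ses[1] > ses[2]


def test_no_censoring_reduces_to_sample_mean(rng):
    waits = rng.exponential(4.0, 200)
    model = est.fit_censored_exponential(waits, np.ones(200, dtype=bool))
    assert model.mean_minutes == pytest.approx(waits.mean())


def test_censored_mle_matches_lifelines(rng):
    from lifelines import ExponentialFitter

    times, reneged = _censored_sample(rng, 2000)
    ours = est.fit_censored_exponential(times, reneged)
    theirs = ExponentialFitter().fit(times, event_observed=reneged)
    assert ours.mean_minutes == pytest.approx(float(theirs.lambda_), rel=1e-6)


def test_zero_events_undefined():
    with pytest.raises(est.EstimationError):
        est.fit_censored_exponential(np.ones(10), np.zeros(10, dtype=bool))


def test_fit_patience_modes_from_log(reference_log):
    pat = est.fit_patience(reference_log, "nonrepeat", "patience")
    vw = est.fit_patience(reference_log, "nonrepeat", "virtual_wait")
    assert pat.n_events + pat.n_censored == vw.n_events + vw.n_censored
    assert pat.n_events == vw.n_censored
    assert pat.mean_minutes > 0 and vw.mean_minutes > 0


def test_logrank_identical_groups(rng):
    t = rng.exponential(3.0, 500)
    e = np.ones(500, dtype=bool)
    stat, p = est.logrank_test(t, e, t, e)
    assert stat == pytest.approx(0.0, abs=1e-9)
    assert p > 0.99


def test_logrank_separates_user_types(rng):
    """Patience means 3.455 vs 5.290 at n=2000 with ~30% censoring are
    overwhelmingly distinguishable."""
    for _ in range(5):
        ta = rng.exponential(3.455, 2000)
        tb = rng.exponential(5.290, 2000)
        ea = rng.random(2000) > 0.3
        eb = rng.random(2000) > 0.3
        _, p = est.logrank_test(ta, ea, tb, eb)
        assert p < 1e-3


def test_logrank_low_power_at_tiny_n(rng):
    ps = []
    for _ in range(20):
        ta = rng.exponential(3.0, 20)
        tb = rng.exponential(3.0, 20) + 0.01
        _, p = est.logrank_test(ta, np.ones(20, bool), tb, np.ones(20, bool))
        ps.append(p)
    assert np.median(ps) > 0.05


# ---------------------------------------------------------------------------
# interarrival aggregation
# ---------------------------------------------------------------------------


def test_aggregate_regular_arrivals():
    records = [_arrival(f"u{i}", 5.0 * i) for i in range(48 * 5)]  # 20 hours, every 5 min
    series = est.aggregate_interarrivals(records, 120.0)
    assert np.allclose(series.mean_interarrival_minutes, 5.0)
    assert not series.imputed.any()


def test_aggregate_dedups_identifier_per_bin():
    records = [_arrival("same", 10.0 * k) for k in range(6)] + [_arrival("other", 70.0)]
    # second bin holds two fresh arrivals so the series is fittable
    records += [_arrival("x1", 130.0), _arrival("x2", 140.0)]
    series = est.aggregate_interarrivals(records, 120.0)
    assert series.mean_interarrival_minutes[0] == pytest.approx(60.0)  # 2 counted, not 7


def test_aggregate_counts_bounded_by_records(reference_log):
    series = est.aggregate_interarrivals(reference_log, 120.0)
    counted = np.nansum(120.0 / series.mean_interarrival_minutes[~series.imputed])
    assert counted <= len(reference_log)


def test_aggregate_single_arrival_rejected():
    with pytest.raises(est.EstimationError):
        est.aggregate_interarrivals([_arrival("u0", 0.0)])


def test_aggregate_nhpp_recovers_intensity(rng):
    """Binned mean interarrivals track 1/lambda for a sinusoidal intensity."""
    from crisisqueue.arrivals import sample_nhpp
    from crisisqueue.ratefn import RateFunction

    t_end = 1440.0 * 10
    knots = np.arange(0, t_end + 60, 60.0)
    vals = 0.3 + 0.2 * np.sin(2 * np.pi * knots / 1440.0)
    fn = RateFunction(knots, vals)
    events = sample_nhpp(fn, t_end, seed=9)
    records = [_arrival(ev.identity, ev.time) for ev in events]
    series = est.aggregate_interarrivals(records, 120.0)
    mids = series.bin_mid_minutes
    lam_true = np.asarray(fn(mids))
    rate_hat = series.rate_per_min
    # each bin holds ~24-60 events; compare in aggregate
    rel = np.abs(rate_hat - lam_true) / lam_true
    assert np.mean(rel) < 0.25
    assert np.abs(np.mean(rate_hat - lam_true) / np.mean(lam_true)) < 0.05


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------


def test_boxcox_linear_case():
    x = np.array([1.0, 2.0, 5.0])
    assert np.allclose(est.boxcox(x, 1.0), x - 1.0)
    assert np.allclose(est.inverse_boxcox_bias_adjusted(x - 1.0, 0.0, 1.0), x)


def test_boxcox_log_case_closed_form():
    m, v = 7.0, 0.3
    out = est.inverse_boxcox_bias_adjusted(np.log(m), v, 0.0)
    assert out == pytest.approx(m * np.exp(v / 2.0))


@given(
    lam=st.one_of(st.just(0.0), st.floats(-1.5, -1e-3), st.floats(1e-3, 1.5)),
    x=st.floats(0.1, 50.0),
)
@settings(max_examples=100, deadline=None)
def test_boxcox_roundtrip_zero_variance(lam, x):
    z = est.boxcox(np.array([x]), lam)[0]
    back = est.inverse_boxcox_bias_adjusted(z, 0.0, lam)
    assert back == pytest.approx(x, rel=1e-12, abs=1e-12)


def test_boxcox_rejects_nonpositive():
    with pytest.raises(ValueError):
        est.boxcox(np.array([0.0, 1.0]), 0.5)


# ---------------------------------------------------------------------------
# valid-case tally
# ---------------------------------------------------------------------------


def test_tally_boundary_inclusive():
    recs = []
    for i, dur in enumerate((7.4, 7.5, 7.6)):
        recs.append(
            ChatRecord(
                f"u{i}", "web", T0, True, "nonrepeat",
                pickup_ts=T0, end_ts=T0 + timedelta(minutes=dur), risk_level="low",
            )
        )
    assert est.tally_valid_cases(recs) == 2
    assert est.tally_valid_cases([_arrival("u", 0.0)]) == 0


def test_tally_matches_brute_force(reference_log):
    brute = sum(
        1
        for r in reference_log
        if r.is_served and r.end_ts is not None and r.service_minutes >= 7.5
    )
    assert est.tally_valid_cases(reference_log) == brute


# ---------------------------------------------------------------------------
# end-to-end ParameterSet
# ---------------------------------------------------------------------------


def test_estimate_all_roundtrip(reference_log, reference_truth, tmp_path):
    pset = est.estimate_all(reference_log)
    tol = 3 * np.sqrt(0.75 * 0.25 / len(reference_log))
    assert abs(pset.tos_p - reference_truth.tos_p) < tol
    assert ("nonrepeat", "low") in pset.duration
    pat = pset.patience["nonrepeat"]
    truth_mean = reference_truth.patience["nonrepeat"].mean_minutes
    assert abs(pat.mean_minutes - truth_mean) < 4 * pat.se_minutes
    path = tmp_path / "params.yaml"
    pset.to_yaml(path)
    from crisisqueue.params import ParameterSet

    back = ParameterSet.from_yaml(path)
    assert back.tos_p == pytest.approx(pset.tos_p)
    assert back.duration[("nonrepeat", "low")].alpha == pytest.approx(
        pset.duration[("nonrepeat", "low")].alpha
    )
    assert back.patience["repeat"].mean_minutes == pytest.approx(
        pset.patience["repeat"].mean_minutes
    )
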
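import numpy as np
import pandas as pd
import pytest

from crisisqueue.estimation import RateSeries
from crisisqueue.forecast import (
    ForecastResult,
    UCMSpec,
    build_rate_function,
    fit_ucm,
    forecast_rate,
    white_test,
)
from crisisqueue.ratefn import RateFunction


def _series(y, width=120.0):
    starts = pd.date_range("2020-04-01", periods=len(y), freq=f"{int(width)}min")
    return RateSeries(bin_start=starts, mean_interarrival_minutes=np.asarray(y, float), bin_width_minutes=width)


def _simulate_ucm(n, seed, level0=2.0, sig_level=0.02, ar=0.5, sig_ar=0.1, amp=0.3):
    rng = np.random.default_rng(seed)
    level = np.cumsum(rng.normal(0, sig_level, n)) + level0
    seas = amp * np.sin(2 * np.pi * np.arange(n) / 12.0)
    e = np.zeros(n)
    for t in range(1, n):
        e[t] = ar * e[t - 1] + rng.normal(0, sig_ar)
    return level + seas + e


def test_noiseless_sinusoid_recovered():
    """A pure sinusoid of period 12 plus a constant is absorbed exactly by
    the deterministic seasonal + level; components sum back to the data."""
    n = 120
    z = 3.0 + 0.5 * np.sin(2 * np.pi * np.arange(n) / 12.0)
    series = _series(np.exp(z))
    fit = fit_ucm(series, UCMSpec(harmonics=1, boxcox_lambda=0.0))
    comp = fit.components()
    total = comp.sum(axis=1).to_numpy()
    burn = 13
    assert np.allclose(total[burn:], z[burn:], atol=1e-4)
    seas_hat = comp["seasonal"].to_numpy()[burn:]
    seas_true = 0.5 * np.sin(2 * np.pi * np.arange(n) / 12.0)[burn:]
    assert np.max(np.abs(seas_hat - seas_true)) < 1e-3
    assert np.allclose(comp["level"].to_numpy()[burn:], 3.0, atol=1e-3)


def test_parameter_recovery_within_two_se():
    """MLE on a 720-bin series simulated from a known UCM recovers the
    level variance, AR variance, and AR coefficient within 2 SEs."""
    z = _simulate_ucm(720, seed=42)
    series = _series(np.exp(z))
    fit = fit_ucm(series, UCMSpec(harmonics=2, boxcox_lambda=0.0))
    names = list(fit.results.param_names)
    est = dict(zip(names, np.asarray(fit.results.params)))
    se = dict(zip(names, np.asarray(fit.results.bse)))
    truth = {"sigma2.level": 0.02**2, "sigma2.ar": 0.1**2, "ar.L1": 0.5}
    for name, true_val in truth.items():
        assert abs(est[name] - true_val) <= 2 * se[name], (name, est[name], se[name])


def test_white_noise_has_negligible_seasonal():
    rng = np.random.default_rng(3)
    z = rng.normal(0.0, 1.0, 240) + 5.0
    series = _series(np.exp(z))
    fit = fit_ucm(series, UCMSpec(boxcox_lambda=0.0))  # AICc-selected harmonics
    comp = fit.components()
    assert comp["seasonal"].to_numpy()[24:].std() < 0.3  # well under the noise SD
    assert fit.selection is not None and len(fit.selection) >= 1


def test_deterministic_model_forecasts_constant():
    """With every disturbance variance fixed at zero and AR coefficient 0,
    the forecast of a constant level c is c in every bin with a zero-width
    interval."""
    series = _series(np.full(96, np.exp(2.0)))
    fixed = {"sigma2.irregular": 0.0, "sigma2.level": 0.0, "sigma2.ar": 0.0, "ar.L1": 0.0}
    fit = fit_ucm(series, UCMSpec(harmonics=1, boxcox_lambda=0.0, fixed_params=fixed))
    res = forecast_rate(fit, 12)
    assert np.allclose(res.table["point"], 2.0, atol=1e-8)
    # zero up to the approximate-diffuse initialization tolerance
    widths = res.table["upper95"] - res.table["lower95"]
    assert np.all(widths < 1e-3)
    assert np.all(res.table["lower95"] <= res.table["point"] + 1e-12)
    assert np.all(res.table["point"] <= res.table["upper95"] + 1e-12)


def test_forecast_intervals_widen_with_horizon():
    z = _simulate_ucm(360, seed=9)
    fit = fit_ucm(_series(np.exp(z)), UCMSpec(harmonics=1, boxcox_lambda=0.0))
    res = forecast_rate(fit, 60)
    se = res.table["se"].to_numpy()
    assert np.all(np.diff(se) >= -1e-9)
    assert set(res.diagnostics) >= {"ljung_box_q", "ljung_box_p"}


def test_forecast_recovers_long_run_mean():
    """Mean forecast over 360 bins of a stationary simulated UCM stays
    within 5% of the simulation's long-run mean (transformed scale)."""
    z = _simulate_ucm(720, seed=15, sig_level=0.0)  # stationary about level0
    fit = fit_ucm(_series(np.exp(z)), UCMSpec(harmonics=1, boxcox_lambda=0.0))
    res = forecast_rate(fit, 360)
    assert np.mean(res.table["point"]) == pytest.approx(np.mean(z), rel=0.05)


def test_short_series_rejected():
    with pytest.raises(ValueError):
        fit_ucm(_series(np.full(20, 2.0)), UCMSpec(harmonics=1))


def test_bias_adjustment_jensen_direction():
    """For lam < 1 and positive variance the bias-adjusted back-transform
    exceeds the naive inverse (Jensen direction)."""
    from crisisqueue.estimation import inverse_boxcox_bias_adjusted

    from crisisqueue.estimation import boxcox

    rng = np.random.default_rng(1)
    for _ in range(200):
        lam = rng.uniform(-0.5, 0.99)
        x = rng.uniform(0.5, 20.0)
        m = float(boxcox(np.array([x]), lam)[0])  # stays in the valid domain
        v = rng.uniform(1e-4, 0.2)
        naive = inverse_boxcox_bias_adjusted(m, 0.0, lam)
        adjusted = inverse_boxcox_bias_adjusted(m, v, lam)
        assert adjusted > naive


# ---------------------------------------------------------------------------
# White test
# ---------------------------------------------------------------------------


def test_white_test_size():
    """Rejection rate of i.i.d. Gaussian residuals near the nominal 5%."""
    rng = np.random.default_rng(12)
    rejections = 0
    n_seeds = 400
    for _ in range(n_seeds):
        fitted = rng.normal(0, 1, 500)
        resid = rng.normal(0, 1, 500)
        _, p = white_test(resid, fitted)
        rejections += p < 0.05
    assert 0.02 <= rejections / n_seeds <= 0.09


def test_white_test_power_under_heteroskedasticity():
    rng = np.random.default_rng(13)
    rejections = 0
    for _ in range(100):
        fitted = rng.uniform(0.5, 3.0, 500)
        resid = rng.normal(0, np.sqrt(fitted))
        _, p = white_test(resid, fitted)
        rejections += p < 0.05
    assert rejections >= 90


def test_white_test_small_sample_no_crash():
    rng = np.random.default_rng(2)
    h, p = white_test(rng.normal(size=5), rng.normal(size=5))
    assert 0.0 <= p <= 1.0


def test_white_test_degenerate_rejected():
    with pytest.raises(ValueError):
        white_test(np.ones(50), np.arange(50.0))


# ---------------------------------------------------------------------------
# rate-function construction
# ---------------------------------------------------------------------------


def test_rate_function_interpolates_knots_exactly():
    series = _series([4.0, 5.0, 2.5, 8.0])
    fn = build_rate_function(series)
    mids = series.bin_mid_minutes
    assert np.allclose(fn(mids), series.rate_per_min)


def test_two_equal_knots_give_constant():
    fn = RateFunction([0.0, 100.0], [0.3, 0.3])
    grid = np.linspace(0, 100, 50)
    assert np.allclose(fn(grid), 0.3)
    assert fn.max_rate == pytest.approx(0.3)


def test_no_negative_overshoot_between_positive_knots():
    rng = np.random.default_rng(21)
    for _ in range(50):
        k = rng.integers(3, 12)
        knots = np.sort(rng.uniform(0, 1000, k))
        knots += np.arange(k) * 1e-3  # ensure strictly increasing
        vals = rng.uniform(0, 2.0, k)
        fn = RateFunction(knots, vals)
        grid = np.linspace(knots[0], knots[-1], 2000)
        assert np.all(np.asarray(fn(grid)) >= 0.0)
        assert np.max(np.asarray(fn(grid))) <= fn.max_rate * (1 + 1e-6)


def test_nonfinite_rate_rejected():
    series = _series([4.0, 5.0, 2.5])
    bad = ForecastResult(
        table=pd.DataFrame({"rate_per_min": [0.1, np.inf]}),
        boxcox_lambda=0.0,
        bin_width_minutes=120.0,
    )
    with pytest.raises(ValueError):
        build_rate_function(bad)
    assert build_rate_function(series) is not None


# ---------------------------------------------------------------------------
# end-to-end: simulate -> aggregate -> fit -> forecast
# ---------------------------------------------------------------------------


def test_end_to_end_rate_recovery():
    """NHPP from a known diurnal intensity, aggregated and fitted, then
    forecast 30 days ahead: MAPE of the expected rate under 15%."""
    from datetime import datetime, timedelta

    from crisisqueue.arrivals import sample_nhpp
    from crisisqueue.estimation import aggregate_interarrivals
    from crisisqueue.records import ChatRecord

    hourly = np.array(
        [12, 10, 8, 6, 5, 4, 4, 4, 5, 7, 8, 9, 10, 10, 11, 11, 12, 12, 13, 15, 16, 16, 15, 14],
        float,
    )
    train_days = 60
    fn = RateFunction.from_hourly_profile(hourly, train_days * 1440.0)
    events = sample_nhpp(fn, train_days * 1440.0, seed=77)
    t0 = datetime(2020, 4, 1)
    records = [
        ChatRecord(ev.identity, "web", t0 + timedelta(minutes=ev.time), True, "nonrepeat")
        for ev in events
    ]
    series = aggregate_interarrivals(records, 120.0)
    fit = fit_ucm(series, UCMSpec(harmonics=3))
    res = forecast_rate(fit, 360)  # 30 days of 2-hour bins
    # the pattern is daily-periodic, so truth at a forecast bin is the
    # intensity at the same time of day
    mids = series.bin_mid_minutes[-1] + 120.0 * (np.arange(360) + 1)
    lam_true = np.asarray(fn(mids % 1440.0 + 1440.0))  # same clock time, day 2
    lam_hat = res.table["rate_per_min"].to_numpy()
    mape = np.mean(np.abs(lam_hat - lam_true) / lam_true)
    assert mape < 0.15
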
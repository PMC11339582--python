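"""State-space demand forecasting for the arrival rate.

The Box-Cox-transformed 2-hour mean-interarrival series is decomposed by
an unobserved-components model (UCM):

    z_t = mu_t + gamma_t + x_t' beta + eps_t

with a stochastic local level mu, a trigonometric (frequency-domain)
seasonal gamma of period s = 12 bins (one day) truncated at kappa
harmonics, optional campaign dummy regressors, and an AR(1) irregular
eps.  The seasonal disturbances default to zero (deterministic seasonal,
the parsimonious choice); kappa is selected by corrected AIC when not
given.  Estimation is Gaussian MLE via the Kalman filter, with missing
bins handled natively as missing observations.

Multistep forecasts come back to the original scale through the
bias-adjusted inverse Box-Cox using the forecast variance, so the result
estimates the *expected* mean interarrival; the rate fed to the simulator
is its reciprocal, downsampled through a monotone PCHIP interpolant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import acorr_ljungbox
from statsmodels.tsa.statespace.structural import UnobservedComponents

from .estimation import (
    RateSeries,
    boxcox,
    choose_boxcox_lambda,
    inverse_boxcox_bias_adjusted,
)
from .ratefn import RateFunction

__all__ = [
    "UCMSpec",
    "UCMFit",
    "ForecastResult",
    "fit_ucm",
    "forecast_rate",
    "white_test",
    "build_rate_function",
]


@dataclass
class UCMSpec:
    """Model specification: level + trigonometric seasonal + AR(1) irregular."""

    period: int = 12
    harmonics: Optional[int] = None  # None -> select by corrected AIC over 1..period//2
    stochastic_seasonal: bool = False
    ar_order: int = 1
    exog: Optional[np.ndarray] = None  # campaign dummy design matrix
    boxcox_lambda: Optional[float] = None
    #: fix named state-space parameters instead of estimating them
    #: (e.g. {"sigma2.level": 0.0}); parameters not listed are estimated,
    #: and if all are fixed no optimization runs at all.
    fixed_params: Optional[dict] = None

    def validate(self):
        if self.harmonics is not None and not 1 <= self.harmonics <= self.period // 2:
            raise ValueError("harmonics must lie in [1, period/2]")


@dataclass
class UCMFit:
    results: object  # statsmodels UnobservedComponentsResults
    boxcox_lambda: float
    spec: UCMSpec
    series: RateSeries
    harmonics: int
    selection: Optional[pd.DataFrame] = None

    def components(self) -> pd.DataFrame:
        """Smoothed level / seasonal / autoregressive components."""
        r = self.results
        out = {"level": r.level.smoothed}
        if r.freq_seasonal:
            out["seasonal"] = r.freq_seasonal[0].smoothed
        if getattr(r, "autoregressive", None) is not None:
            out["autoregressive"] = r.autoregressive.smoothed
        return pd.DataFrame(out)

    def fitted_transformed(self) -> np.ndarray:
        return np.asarray(self.results.fittedvalues)

    def residuals(self) -> np.ndarray:
        return np.asarray(self.results.resid)


@dataclass
class ForecastResult:
    """Multistep forecast table plus residual diagnostics.

    ``table`` columns: bin_start, point, lower95, upper95 (transformed
    scale), mean_interarrival_minutes and rate_per_min (original scale,
    bias-adjusted).
    """

    table: pd.DataFrame
    boxcox_lambda: float
    bin_width_minutes: float
    diagnostics: dict = field(default_factory=dict)


def _aicc(res) -> float:
    n = res.nobs
    k = res.params.size
    if n - k - 1 <= 0:
        return np.inf
    return float(res.aic + 2 * k * (k + 1) / (n - k - 1))


def _fit_one(z: np.ndarray, spec: UCMSpec, harmonics: int):
    model = UnobservedComponents(
        z,
        level="local level",
        freq_seasonal=[{"period": spec.period, "harmonics": harmonics}],
        stochastic_freq_seasonal=[spec.stochastic_seasonal],
        autoregressive=spec.ar_order or None,
        exog=spec.exog,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if spec.fixed_params:
            unknown = set(spec.fixed_params) - set(model.param_names)
            if unknown:
                raise ValueError(f"unknown fixed parameters {sorted(unknown)}")
            if set(spec.fixed_params) == set(model.param_names):
                vector = np.array([spec.fixed_params[n] for n in model.param_names])
                res = model.smooth(vector)
            else:
                with model.fix_params(spec.fixed_params):
                    res = model.fit(disp=0, maxiter=200)
        else:
            res = model.fit(disp=0, maxiter=200)
    return res


def fit_ucm(series: RateSeries, spec: Optional[UCMSpec] = None) -> UCMFit:
    """Fit the UCM to the Box-Cox-transformed mean-interarrival series."""
    spec = spec or UCMSpec()
    spec.validate()
    y = np.asarray(series.mean_interarrival_minutes, dtype=float)
    finite = y[np.isfinite(y)]
    if np.any(finite <= 0):
        raise ValueError("mean interarrivals must be positive before transforming")
    if finite.size < 4 * spec.period:
        raise EstimationShortSeriesError(
            f"need at least {4 * spec.period} bins, got {finite.size}"
        )
    lam = spec.boxcox_lambda
    if lam is None:
        lam = choose_boxcox_lambda(finite)
    z = np.where(np.isfinite(y), boxcox(np.where(np.isfinite(y), y, 1.0), lam), np.nan)

    selection = None
    if spec.harmonics is None:
        rows = []
        best = None
        for k in range(1, spec.period // 2 + 1):
            try:
                res_k = _fit_one(z, spec, k)
            except Exception:  # numerical failure for this cutoff
                continue
            score = _aicc(res_k)
            rows.append({"harmonics": k, "aicc": score, "aic": float(res_k.aic)})
            if best is None or score < best[1]:
                best = (k, score, res_k)
        if best is None:
            raise RuntimeError("UCM estimation failed for every harmonic cutoff")
        harmonics, _, res = best[0], best[1], best[2]
        selection = pd.DataFrame(rows)
    else:
        harmonics = spec.harmonics
        res = _fit_one(z, spec, harmonics)
    if getattr(res, "mle_retvals", None) and not res.mle_retvals.get("converged", True):
        warnings.warn(f"UCM optimizer did not report convergence: {res.mle_retvals}")
    return UCMFit(
        results=res,
        boxcox_lambda=float(lam),
        spec=spec,
        series=series,
        harmonics=harmonics,
        selection=selection,
    )


class EstimationShortSeriesError(ValueError):
    pass


def forecast_rate(
    fit: UCMFit, horizon_bins: int, exog_future: Optional[np.ndarray] = None
) -> ForecastResult:
    """Multistep forecast with 95% intervals and bias-adjusted rates.

    The expected arrival rate per bin is 1 / E[tau_a], with E[tau_a]
    recovered by the bias-adjusted inverse Box-Cox at the forecast
    variance of each step.
    """
    if horizon_bins < 1:
        raise ValueError("horizon_bins must be >= 1")
    kwargs = {}
    if fit.spec.exog is not None:
        if exog_future is None:
            raise ValueError("model has regressors; exog_future required")
        kwargs["exog"] = exog_future
    pred = fit.results.get_forecast(steps=horizon_bins, **kwargs)
    mean = np.asarray(pred.predicted_mean, dtype=float)
    se = np.asarray(pred.se_mean, dtype=float)
    var = se**2
    if not np.all(np.isfinite(var)):
        raise RuntimeError("forecast variance overflowed; shorten the horizon")
    ci = np.asarray(pred.conf_int(alpha=0.05), dtype=float)
    lam = fit.boxcox_lambda
    ia = inverse_boxcox_bias_adjusted(mean, var, lam)
    rate = 1.0 / ia

    width = pd.Timedelta(minutes=fit.series.bin_width_minutes)
    start = fit.series.bin_start[-1] + width
    bins = pd.DatetimeIndex([start + i * width for i in range(horizon_bins)])
    table = pd.DataFrame(
        {
            "bin_start": bins,
            "point": mean,
            "lower95": ci[:, 0],
            "upper95": ci[:, 1],
            "se": se,
            "mean_interarrival_minutes": ia,
            "rate_per_min": rate,
        }
    )

    resid = fit.residuals()
    fitted = fit.fitted_transformed()
    # discard the diffuse burn-in before computing diagnostics
    burn = fit.results.loglikelihood_burn
    resid_d, fitted_d = resid[burn:], fitted[burn:]
    mask = np.isfinite(resid_d) & np.isfinite(fitted_d)
    lb = acorr_ljungbox(resid_d[mask], lags=[1], return_df=True)
    diagnostics = {
        "ljung_box_q": float(lb["lb_stat"].iloc[0]),
        "ljung_box_p": float(lb["lb_pvalue"].iloc[0]),
    }
    try:
        h, p = white_test(resid_d[mask], fitted_d[mask])
        diagnostics["white_h"] = h
        diagnostics["white_p"] = p
    except ValueError:
        pass
    return ForecastResult(
        table=table,
        boxcox_lambda=lam,
        bin_width_minutes=fit.series.bin_width_minutes,
        diagnostics=diagnostics,
    )


def white_test(residuals: np.ndarray, fitted: np.ndarray) -> tuple[float, float]:
    """Heteroskedasticity test: regress squared residuals on the fitted
    values and their squares; H = n*R^2 ~ chi2(2) under homoskedasticity."""
    residuals = np.asarray(residuals, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if residuals.size < 10:
        if residuals.size < 5:
            raise ValueError("need at least 5 residuals")
    if np.ptp(residuals) == 0:
        raise ValueError("degenerate (constant) residuals")
    u2 = residuals**2
    X = np.column_stack([np.ones_like(fitted), fitted, fitted**2])
    beta, *_ = np.linalg.lstsq(X, u2, rcond=None)
    u2_hat = X @ beta
    ss_res = float(np.sum((u2 - u2_hat) ** 2))
    ss_tot = float(np.sum((u2 - u2.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("squared residuals are constant")
    r2 = 1.0 - ss_res / ss_tot
    h = residuals.size * r2
    p = float(stats.chi2.sf(h, df=2))
    return float(h), p


def build_rate_function(source, floor: float = 1e-9) -> RateFunction:
    """Monotone PCHIP rate interpolant from a forecast or a binned series.

    Knots sit at bin midpoints; the interpolant is clipped at zero with a
    tiny positive floor so the thinning sampler's acceptance ratio stays
    well-defined, and ``max_rate`` is computed on a 1-minute grid.
    """
    if isinstance(source, ForecastResult):
        rates = source.table["rate_per_min"].to_numpy(dtype=float)
        width = source.bin_width_minutes
    elif isinstance(source, RateSeries):
        rates = source.rate_per_min
        width = source.bin_width_minutes
    else:
        raise TypeError("source must be a ForecastResult or RateSeries")
    if not np.all(np.isfinite(rates)):
        raise ValueError("nonfinite rate in source")
    if rates.size < 2:
        raise ValueError("need at least two bins")
    mids = width / 2.0 + width * np.arange(rates.size)
    return RateFunction(mids, rates, floor=floor)
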
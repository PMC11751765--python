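"""Daily anomaly construction: seasonal-cycle and long-term-trend removal.

Anomalies are built in two passes: the per-calendar-month climatology is
subtracted first, then a LOWESS trend (neighbourhood fraction 0.4 by default)
fitted to the deseasonalised residual is removed.  Removing the seasonal cycle
before the local trend fit keeps the annual cycle from leaking into the
smoother.  A final re-centering pass subtracts the residual per-month means so
that both properties -- zero monthly means and a flat long-term trend -- hold
simultaneously.  The order of the two removals can be switched.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "monthly_climatology",
    "lowess_trend",
    "compute_anomalies",
    "DailyAnomalizer",
]


def monthly_climatology(values, months):
    """Per-calendar-month means, ignoring NaNs.

    Parameters
    ----------
    values : array of daily values (NaN = missing)
    months : array of calendar month numbers (1..12), same length

    Returns
    -------
    clim : ndarray shape (12,); NaN where a calendar month has no valid day.
    """
    values = np.asarray(values, dtype=float)
    months = np.asarray(months)
    if values.shape != months.shape:
        raise ValueError("values and months must have equal length")
    clim = np.full(12, np.nan)
    for m in range(1, 13):
        sel = values[months == m]
        sel = sel[np.isfinite(sel)]
        if sel.size:
            clim[m - 1] = sel.mean()
    return clim


def lowess_trend(values, frac=0.4, it=0, delta_frac=0.0):
    """LOWESS (tricube-weighted local linear regression) trend of a daily series.

    The smoothing parameter ``frac`` is the fraction of the series length used
    in each local neighbourhood; ``it`` robustness iterations (0 by default).
    Missing days are excluded from the fit and filled by linear interpolation
    of the fitted trend.  ``delta_frac`` > 0 enables the standard linear-
    interpolation shortcut between nearby abscissae (speed optimisation for
    multi-thousand-point series; 0 computes every local fit exactly).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if not 0.0 < frac <= 1.0:
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    t = np.arange(n, dtype=float)
    valid = np.isfinite(values)
    if valid.sum() < 10:
        raise ValueError("lowess_trend needs at least 10 valid points")
    delta = delta_frac * (t[valid][-1] - t[valid][0])
    fitted = _sm_lowess(
        values[valid], t[valid], frac=frac, it=it, delta=delta, return_sorted=False
    )
    trend = np.full(n, np.nan)
    trend[valid] = fitted
    if not valid.all():
        trend[~valid] = np.interp(t[~valid], t[valid], fitted)
    return trend


def compute_anomalies(
    values,
    dates,
    frac=0.4,
    it=0,
    delta_frac=0.0,
    order="climatology_first",
):
    """Daily anomalies: seasonal cycle and LOWESS trend removed.

    Parameters
    ----------
    values : daily series (NaN = missing)
    dates : ``pd.DatetimeIndex`` (or convertible), strictly daily
    order : 'climatology_first' (default) or 'trend_first'

    Returns
    -------
    anomalies : ndarray, NaN where the input was missing or where a calendar
        month had no valid observation.
    """
    dates = pd.DatetimeIndex(dates)
    values = np.asarray(values, dtype=float)
    if len(dates) != values.size:
        raise ValueError("dates and values must align")
    if len(dates) > 1:
        step = np.diff(dates.values).astype("timedelta64[D]")
        if not (step == np.timedelta64(1, "D")).all():
            raise ValueError("dates must be consecutive calendar days")
    months = dates.month.values

    def _deseason(v):
        clim = monthly_climatology(v, months)
        return v - clim[months - 1]

    if order == "climatology_first":
        resid = _deseason(values)
        resid = resid - lowess_trend(resid, frac=frac, it=it, delta_frac=delta_frac)
    elif order == "trend_first":
        resid = values - lowess_trend(values, frac=frac, it=it, delta_frac=delta_frac)
        resid = _deseason(resid)
    else:
        raise ValueError(f"unknown order {order!r}")
    # final exact re-centering of calendar-month means
    return _deseason(resid)


class DailyAnomalizer(TransformerMixin, BaseEstimator):
    """Transformer turning daily series into deseasonalised, detrended anomalies.

    Operates column-wise on a ``pandas.DataFrame`` with a daily
    ``DatetimeIndex`` (or a 2-D array plus ``dates`` passed to :meth:`fit`).

    Parameters
    ----------
    frac : float, LOWESS neighbourhood fraction (default 0.4).
    it : int, LOWESS robustness iterations (default 0).
    delta_frac : float, LOWESS interpolation shortcut as a fraction of the
        time-axis range (0 = exact).
    order : 'climatology_first' or 'trend_first'.

    Attributes
    ----------
    climatology_ : DataFrame (12 x n_columns) of per-calendar-month means.
    trend_ : DataFrame of the fitted LOWESS trend, aligned to the input.
    """

    def __init__(self, frac=0.4, it=0, delta_frac=0.0, order="climatology_first"):
        self.frac = frac
        self.it = it
        self.delta_frac = delta_frac
        self.order = order

    def _to_frame(self, X, dates):
        if isinstance(X, pd.DataFrame):
            return X
        if dates is None:
            raise ValueError("array input requires dates=")
        return pd.DataFrame(np.asarray(X, dtype=float), index=pd.DatetimeIndex(dates))

    def fit(self, X, y=None, dates=None):
        df = self._to_frame(X, dates)
        months = df.index.month.values
        clim = {}
        trend = {}
        for col in df.columns:
            v = df[col].to_numpy(dtype=float)
            c = monthly_climatology(v, months)
            clim[col] = c
            if self.order == "climatology_first":
                resid = v - c[months - 1]
                trend[col] = lowess_trend(
                    resid, frac=self.frac, it=self.it, delta_frac=self.delta_frac
                )
            else:
                trend[col] = lowess_trend(
                    v, frac=self.frac, it=self.it, delta_frac=self.delta_frac
                )
        self.climatology_ = pd.DataFrame(clim, index=np.arange(1, 13))
        self.trend_ = pd.DataFrame(trend, index=df.index)
        self.n_features_in_ = df.shape[1]
        return self

    def transform(self, X, dates=None):
        df = self._to_frame(X, dates)
        out = {}
        for col in df.columns:
            out[col] = compute_anomalies(
                df[col].to_numpy(dtype=float),
                df.index,
                frac=self.frac,
                it=self.it,
                delta_frac=self.delta_frac,
                order=self.order,
            )
        return pd.DataFrame(out, index=df.index)

    def fit_transform(self, X, y=None, dates=None):
        return self.fit(X, dates=dates).transform(X, dates=dates)
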
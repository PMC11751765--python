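"""Soil-moisture / VPD coupling: lagged partial correlation in a moving window.

The coupling statistic for day *d* is the partial correlation between the
soil-moisture anomaly at *d − lag* and the VPD anomaly at *d*, controlling for
the VPD anomaly at *d − lag* (which absorbs VPD temporal autocorrelation so
the soil-moisture feedback is isolated):

    rho(x, y | z) = (r_xy − r_xz r_yz) / sqrt((1 − r_xz²)(1 − r_yz²))

with x = SM(t − lag), y = VPD(t), z = VPD(t − lag) and Pearson correlations r
computed over all days t in a 30-day window centred on d.  Daily values are
aggregated to months and filtered to growing-season (monthly temperature not
below 5 °C), dry-anomaly (negative monthly SM anomaly) months with less than
20% missing daily values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "partial_correlation",
    "rolling_coupling",
    "monthly_aggregate",
    "apply_filters",
    "couple_series",
]

_EPS = 1e-12


def partial_correlation(x, y, z):
    """Partial correlation of x and y controlling for z.

    Pairs with any missing value are dropped.  Returns NaN when fewer than 4
    complete triples remain, when any series is constant, or when a control
    correlation is (numerically) perfect so the denominator vanishes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape):
        raise ValueError("x, y, z must have equal length")
    m = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[m], y[m], z[m]
    if x.size < 4:
        return float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0 or np.ptp(z) == 0:
        return float("nan")
    r = np.corrcoef(np.vstack([x, y, z]))
    r_xy, r_xz, r_yz = r[0, 1], r[0, 2], r[1, 2]
    den = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if den <= _EPS:
        return float("nan")
    return float(np.clip((r_xy - r_xz * r_yz) / np.sqrt(den), -1.0, 1.0))


def _window_sums(a, lo, hi):
    """Sum of a[d+lo .. d+hi] for every d, edges truncated."""
    n = a.size
    c = np.concatenate([[0.0], np.cumsum(a)])
    d = np.arange(n)
    upper = np.clip(d + hi + 1, 0, n)
    lower = np.clip(d + lo, 0, n)
    return c[upper] - c[lower]


def rolling_coupling(sm_anom, vpd_anom, lag=7, window=30, min_pairs=24):
    """Daily lagged partial-correlation series.

    Parameters
    ----------
    sm_anom, vpd_anom : daily anomaly arrays on the same date axis.
    lag : days the VPD response trails the SM anomaly.
    window : moving-window length in days, centred on the focal day
        (offsets −window//2 .. window − window//2 − 1, truncated at edges).
    min_pairs : minimum number of complete (SM(t−lag), VPD(t), VPD(t−lag))
        triples required; windows below it give NaN.

    Returns
    -------
    pcor : ndarray of daily partial correlations (NaN where undefined).
    n_pairs : ndarray of valid-triple counts per window.
    """
    y = np.asarray(vpd_anom, dtype=float)
    sm = np.asarray(sm_anom, dtype=float)
    if y.shape != sm.shape:
        raise ValueError("anomaly series must share the date axis")
    if lag < 0 or window < 3:
        raise ValueError("lag must be >= 0 and window >= 3")
    n = y.size
    x = np.full(n, np.nan)
    z = np.full(n, np.nan)
    if lag:
        x[lag:] = sm[:-lag]
        z[lag:] = y[:-lag]
    else:
        x, z = sm.copy(), y.copy()

    valid = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    xv = np.where(valid, x, 0.0)
    yv = np.where(valid, y, 0.0)
    zv = np.where(valid, z, 0.0)

    lo = -(window // 2)
    hi = window - window // 2 - 1
    cnt = _window_sums(valid.astype(float), lo, hi)
    sx = _window_sums(xv, lo, hi)
    sy = _window_sums(yv, lo, hi)
    sz = _window_sums(zv, lo, hi)
    sxx = _window_sums(xv * xv, lo, hi)
    syy = _window_sums(yv * yv, lo, hi)
    szz = _window_sums(zv * zv, lo, hi)
    sxy = _window_sums(xv * yv, lo, hi)
    sxz = _window_sums(xv * zv, lo, hi)
    syz = _window_sums(yv * zv, lo, hi)

    with np.errstate(invalid="ignore", divide="ignore"):
        vx = sxx - sx * sx / cnt
        vy = syy - sy * sy / cnt
        vz = szz - sz * sz / cnt
        cxy = sxy - sx * sy / cnt
        cxz = sxz - sx * sz / cnt
        cyz = syz - sy * sz / cnt
        r_xy = cxy / np.sqrt(vx * vy)
        r_xz = cxz / np.sqrt(vx * vz)
        r_yz = cyz / np.sqrt(vy * vz)
        den = (1.0 - r_xz**2) * (1.0 - r_yz**2)
        pcor = (r_xy - r_xz * r_yz) / np.sqrt(den)

    # variance guard uses a scale-relative tolerance against cancellation
    bad = (
        (cnt < min_pairs)
        | (vx <= _EPS * np.maximum(sxx, 1.0))
        | (vy <= _EPS * np.maximum(syy, 1.0))
        | (vz <= _EPS * np.maximum(szz, 1.0))
        | (den <= _EPS)
        | ~np.isfinite(pcor)
    )
    pcor = np.clip(pcor, -1.0, 1.0)
    pcor[bad] = np.nan
    return pcor, cnt.astype(int)


def monthly_aggregate(dates, pcor, max_missing=0.2):
    """Aggregate the daily coupling series to calendar months.

    A month is *eligible* when the fraction of missing daily coupling values
    is strictly below ``max_missing``; the monthly value is the arithmetic
    mean of the defined daily values.
    """
    dates = pd.DatetimeIndex(dates)
    pcor = np.asarray(pcor, dtype=float)
    df = pd.DataFrame({"pcor": pcor}, index=dates)
    grp = df.groupby(df.index.to_period("M"))["pcor"]
    out = pd.DataFrame(
        {
            "pcor_monthly": grp.mean(),
            "n_valid_days": grp.count(),
            "n_days": grp.size(),
        }
    )
    out["frac_missing"] = (out["n_days"] - out["n_valid_days"]) / out["n_days"]
    out["eligible"] = out["frac_missing"] < max_missing
    return out


def apply_filters(
    monthly,
    monthly_temperature,
    monthly_sm_anomaly,
    temp_threshold=5.0,
    require_negative_sm=True,
    require_negative_pcor=False,
):
    """Growing-season / dry-anomaly retention flags.

    ``growing_season`` keeps months whose mean temperature is not below the
    threshold (a month at exactly 5 °C is retained; the exclusion rule is
    strictly *below* 5 °C).  ``sm_anomaly_negative`` keeps months with a
    negative monthly-mean SM anomaly.  ``retained`` is the conjunction with
    the missing-data eligibility.  ``require_negative_pcor`` additionally
    drops months with non-negative coupling (off by default).
    """
    monthly = monthly.copy()
    t = pd.Series(monthly_temperature)
    s = pd.Series(monthly_sm_anomaly)
    if not monthly.index.equals(t.index) or not monthly.index.equals(s.index):
        raise ValueError("monthly axes are misaligned")
    monthly["growing_season"] = t.values >= temp_threshold
    monthly["sm_anomaly_negative"] = s.values < 0.0
    retained = (
        monthly["eligible"] & monthly["growing_season"] & monthly["sm_anomaly_negative"]
    )
    if require_negative_pcor:
        retained &= monthly["pcor_monthly"] < 0.0
    monthly["retained"] = retained & np.isfinite(monthly["pcor_monthly"])
    return monthly


def couple_series(
    dates,
    sm_anom,
    vpd_anom,
    temperature_daily,
    lag=7,
    window=30,
    min_pairs=24,
    max_missing=0.2,
    temp_threshold=5.0,
    require_negative_sm=True,
    require_negative_pcor=False,
):
    """Full per-cell chain: rolling coupling -> monthly aggregate -> filters."""
    dates = pd.DatetimeIndex(dates)
    pcor, _ = rolling_coupling(
        sm_anom, vpd_anom, lag=lag, window=window, min_pairs=min_pairs
    )
    monthly = monthly_aggregate(dates, pcor, max_missing=max_missing)
    per = dates.to_period("M")
    t_m = pd.Series(temperature_daily, index=dates).groupby(per).mean()
    s_m = pd.Series(np.asarray(sm_anom, dtype=float), index=dates).groupby(per).mean()
    return apply_filters(
        monthly,
        t_m,
        s_m,
        temp_threshold=temp_threshold,
        require_negative_sm=require_negative_sm,
        require_negative_pcor=require_negative_pcor,
    )
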
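"""Lagged moving-window partial-correlation coupling statistic."""

import numpy as np
import pandas as pd
import pytest

from smvpd import (
    apply_filters,
    monthly_aggregate,
    partial_correlation,
    rolling_coupling,
)
from smvpd.benchmarks import residual_partial_correlation


class TestPartialCorrelation:
    def test_uncorrelated_controls_give_raw_correlation(self, rng):
        # z orthogonalised in-sample against x and y: r_xz = r_yz = 0,
        # so the partial correlation reduces to the raw correlation
        n = 200
        x = rng.normal(size=n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=n)
        z = rng.normal(size=n)
        A = np.column_stack([np.ones(n), x, y])
        z = z - A @ np.linalg.lstsq(A, z, rcond=None)[0]
        pc = partial_correlation(x, y, z)
        assert pc == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_perfect_correlation_preserved(self, rng):
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        assert partial_correlation(x, x, z) == pytest.approx(1.0, abs=1e-12)

    def test_matches_residual_oracle(self, rng):
        worst = 0.0
        for _ in range(1000):
            cov = rng.normal(size=(3, 3))
            cov = cov @ cov.T + 0.3 * np.eye(3)
            s = rng.multivariate_normal(np.zeros(3), cov, size=30)
            a = partial_correlation(s[:, 0], s[:, 1], s[:, 2])
            b = residual_partial_correlation(s[:, 0], s[:, 1], s[:, 2])
            worst = max(worst, abs(a - b))
        assert worst < 1e-10

    def test_degenerate_inputs_return_nan(self, rng):
        x = rng.normal(size=30)
        assert np.isnan(partial_correlation(x, x * 0 + 1.0, rng.normal(size=30)))
        assert np.isnan(partial_correlation(x, rng.normal(size=30), x))  # |r_xz|=1
        assert np.isnan(partial_correlation(x[:3], x[:3], x[:3]))  # too short


class TestRollingCoupling:
    def test_exact_negative_relation_gives_minus_one(self, rng):
        n = 400
        sm = rng.normal(size=n)
        lag = 7
        vpd = np.zeros(n)
        vpd[lag:] = -sm[:-lag]
        vpd[:lag] = rng.normal(size=lag)
        pcor, npairs = rolling_coupling(sm, vpd, lag=lag)
        full = npairs >= 24
        assert np.all(np.isfinite(pcor[full]))
        assert np.allclose(pcor[full & (np.arange(n) >= 2 * lag + 15)], -1.0)

    def test_null_mean_near_zero(self, rng):
        vals = []
        for _ in range(200):
            pcor, _ = rolling_coupling(rng.normal(size=365), rng.normal(size=365), lag=7)
            vals.append(np.nanmean(pcor))
        assert abs(np.mean(vals)) < 0.02

    def test_missing_day_is_local(self, rng):
        n = 300
        sm = rng.normal(size=n)
        vpd = rng.normal(size=n)
        p0, n0 = rolling_coupling(sm, vpd, lag=7)
        sm2 = sm.copy()
        sm2[150] = np.nan
        p1, n1 = rolling_coupling(sm2, vpd, lag=7)
        # sm[150] enters only the triple at t = 157 (as SM(t - lag)), so
        # exactly the windows containing t = 157 lose one triple each
        t = 157
        affected = np.zeros(n, dtype=bool)
        affected[t - 14 : t + 16] = True
        assert np.array_equal(n0 - n1, affected.astype(int))
        same = ~affected
        assert np.allclose(p0[same], p1[same], equal_nan=True)

    def test_shift_equivariance(self, rng):
        sm = rng.normal(size=365)
        vpd = rng.normal(size=365)
        p0, _ = rolling_coupling(sm, vpd, lag=7)
        p1, _ = rolling_coupling(sm + 5.0, vpd - 3.0, lag=7)
        assert np.allclose(p0, p1, equal_nan=True)

    def test_range_bounded(self, rng):
        pcor, _ = rolling_coupling(rng.normal(size=500), rng.normal(size=500), lag=1)
        v = pcor[np.isfinite(pcor)]
        assert np.all((v >= -1.0) & (v <= 1.0))

    def test_matches_per_window_formula(self, rng):
        """Cumulative-sum implementation equals the direct per-window formula."""
        n = 200
        sm = rng.normal(size=n)
        sm[rng.random(n) < 0.05] = np.nan
        vpd = rng.normal(size=n)
        lag, window = 7, 30
        pcor, npairs = rolling_coupling(sm, vpd, lag=lag, window=window)
        x = np.full(n, np.nan)
        z = np.full(n, np.nan)
        x[lag:] = sm[:-lag]
        z[lag:] = vpd[:-lag]
        for d in range(0, n, 17):
            lo, hi = max(d - 15, 0), min(d + 15, n)
            pc = partial_correlation(x[lo:hi], vpd[lo:hi], z[lo:hi])
            m = np.isfinite(x[lo:hi]) & np.isfinite(vpd[lo:hi]) & np.isfinite(z[lo:hi])
            if m.sum() < 24:
                assert np.isnan(pcor[d])
            else:
                assert pcor[d] == pytest.approx(pc, abs=1e-10)


class TestMonthlyAggregate:
    @pytest.mark.parametrize("n_missing,eligible", [(6, True), (7, False)])
    def test_twenty_percent_rule_on_31_day_month(self, n_missing, eligible):
        dates = pd.date_range("2003-01-01", "2003-01-31", freq="D")
        pcor = np.full(31, -0.4)
        pcor[:n_missing] = np.nan
        out = monthly_aggregate(dates, pcor)
        assert bool(out["eligible"].iloc[0]) is eligible

    def test_constant_daily_value_mean(self):
        dates = pd.date_range("2003-03-01", "2003-03-31", freq="D")
        out = monthly_aggregate(dates, np.full(31, -0.4))
        assert out["pcor_monthly"].iloc[0] == pytest.approx(-0.4)


class TestApplyFilters:
    def _monthly(self, n=3):
        dates = pd.date_range("2003-06-01", periods=n * 30, freq="D")
        return monthly_aggregate(dates, np.full(n * 30, -0.3))

    def test_temperature_threshold_boundaries(self):
        m = self._monthly(3)
        t = pd.Series([4.9, 5.0, 5.1], index=m.index)
        s = pd.Series([-0.01, -0.01, -0.01], index=m.index)
        out = apply_filters(m, t, s)
        assert list(out["retained"]) == [False, True, True]

    def test_positive_sm_anomaly_excluded(self):
        m = self._monthly(2)
        t = pd.Series([15.0, 15.0], index=m.index)
        s = pd.Series([0.02, -0.02], index=m.index)
        out = apply_filters(m, t, s)
        assert list(out["retained"]) == [False, True]

    def test_misaligned_axes_rejected(self):
        m = self._monthly(2)
        t = pd.Series([15.0], index=m.index[:1])
        with pytest.raises(ValueError):
            apply_filters(m, t, t)


def test_lag_consistency_with_planted_lag(small_run):
    """Mean |coupling| across cells peaks at the generator's true lag (7 d)
    among the candidate lags 1, 7, 14."""
    cfg, data, anom, _ = small_run
    strengths = {}
    for lag in (1, 7, 14):
        vals = []
        for r in range(0, 6, 2):
            for c in range(0, 6, 2):
                p, _ = rolling_coupling(
                    anom["sm_anom"].values[:, r, c],
                    anom["vpd_anom"].values[:, r, c],
                    lag=lag,
                )
                vals.append(np.nanmean(np.abs(p)))
        strengths[lag] = np.mean(vals)
    assert strengths[7] > strengths[1] and strengths[7] > strengths[14]
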
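"""Ground-truth recovery experiments on the synthetic generator.

Each function sets up a known generative scenario, runs the relevant part of
the pipeline from scratch, and measures how well the known structure is
recovered (or, for the formula-level checks, how closely an implementation
matches an independent oracle).  They are used by the validation test-suite
and the reproduction script; problem sizes are chosen so a full run stays in
the minutes range on one core.
"""

from __future__ import annotations

import filecmp
import itertools
from pathlib import Path

import numpy as np
import pandas as pd

from .attribution import attribution_sweep, theil_sen_sensitivity
from .config import RunConfig, SyntheticConfig
from .coupling import (
    apply_filters,
    monthly_aggregate,
    partial_correlation,
    rolling_coupling,
)
from .pipeline import anomaly_grid, coupling_grid, run_pipeline
from .spatial import benjamini_hochberg
from .synthetic import generate_dataset, generate_driver_benchmark

__all__ = [
    "residual_partial_correlation",
    "pairwise_median_slope",
    "bh_stepup_reference",
    "partial_correlation_oracle_check",
    "null_coupling_calibration",
    "sign_recovery",
    "dominant_driver_recovery",
    "theil_sen_exactness",
    "bh_fdr_check",
    "filter_rule_conformance",
    "determinism_check",
]


# --------------------------------------------------------------------------
# independent oracles


def residual_partial_correlation(x, y, z):
    """Partial correlation via the regression-residual route: correlate the
    least-squares residuals of x~z and y~z (independent of the closed-form
    three-correlation formula)."""
    Z = np.column_stack([np.ones_like(z), z])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def pairwise_median_slope(x, y):
    """Theil-Sen slope by explicit O(n^2) enumeration of pairwise slopes."""
    slopes = [
        (y[j] - y[i]) / (x[j] - x[i])
        for i, j in itertools.combinations(range(len(x)), 2)
        if x[j] != x[i]
    ]
    return float(np.median(slopes))


def bh_stepup_reference(p, q=0.05):
    """Benjamini-Hochberg by the textbook step-up definition: sort, find the
    largest k with p_(k) <= k q / m, reject everything up to it."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    thresh = (np.arange(1, m + 1) / m) * q
    below = np.nonzero(ps <= thresh)[0]
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[: below[-1] + 1]] = True
    return reject


# --------------------------------------------------------------------------
# recovery experiments


def partial_correlation_oracle_check(n_instances=1000, n=30, seed=0):
    """Max |formula - residual oracle| over random trivariate samples."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        cov = rng.normal(size=(3, 3))
        cov = cov @ cov.T + 0.5 * np.eye(3)
        xyz = rng.multivariate_normal(np.zeros(3), cov, size=n)
        a = partial_correlation(xyz[:, 0], xyz[:, 1], xyz[:, 2])
        b = residual_partial_correlation(xyz[:, 0], xyz[:, 1], xyz[:, 2])
        worst = max(worst, abs(a - b))
    return {"max_abs_diff": worst, "n": n_instances}


def null_coupling_calibration(n_cells=200, n_years=10, seed=0, lag=7, window=30):
    """Coupling statistics on cells with no planted coupling.

    Returns the grand mean of eligible monthly coupling values and the SD of
    full-window daily values expressed as a ratio to 1/sqrt(window - 3).
    """
    n_lat = max(int(np.sqrt(n_cells / 2)), 3)
    n_lon = int(np.ceil(n_cells / n_lat))
    syn = SyntheticConfig(
        n_lat=n_lat, n_lon=n_lon, n_years=n_years, seed=seed,
        b0=0.0, b_lai=0.0, b_phys=0.0,
    )
    cfg = RunConfig(seed=seed, lag=lag, window=window)
    data = generate_dataset(syn)
    anom = anomaly_grid(data.daily, cfg)
    dates = pd.DatetimeIndex(data.daily["time"].values)
    window_vals = []
    monthly_vals = []
    count = 0
    for r in range(n_lat):
        for c in range(n_lon):
            if count >= n_cells:
                break
            count += 1
            p, npairs = rolling_coupling(
                anom["sm_anom"].values[:, r, c],
                anom["vpd_anom"].values[:, r, c],
                lag=lag,
                window=window,
            )
            window_vals.append(p[npairs == window])
            m = monthly_aggregate(dates, p)
            monthly_vals.append(m.loc[m["eligible"], "pcor_monthly"].values)
    w = np.concatenate(window_vals)
    w = w[np.isfinite(w)]
    mm = np.concatenate(monthly_vals)
    mm = mm[np.isfinite(mm)]
    return {
        "grand_mean_monthly": float(mm.mean()),
        "window_sd": float(w.std()),
        "window_sd_ratio": float(w.std() * np.sqrt(window - 3.0)),
        "n_cells": count,
        "n_windows": int(w.size),
    }


def sign_recovery(seed=0, n_lat=15, n_lon=15, n_years=12):
    """Headline property: planted negative LAI / physiology modulation should
    be recovered as negative Theil-Sen sensitivities in screened cells.

    Runs the full chain (generation, anomalies, coupling, attribution) with
    the default negative ``b_lai``/``b_phys`` and reports, among cells that
    pass both screens and have slope p < 0.01, the fraction with negative
    slopes for LAI and for normalized transpiration.
    """
    cfg = RunConfig(seed=seed)
    cfg.synthetic = SyntheticConfig(n_lat=n_lat, n_lon=n_lon, n_years=n_years, seed=seed)
    data = generate_dataset(cfg.synthetic)
    anom = anomaly_grid(data.daily, cfg)
    coupling = coupling_grid(anom, data.daily, cfg)
    attribution, report = attribution_sweep(coupling, data.predictors, data.meta)
    out = {"n_cells": report["n_cells"], "n_passed": report["n_passed"]}
    for pred, key in (("lai", "lai"), ("transpiration_over_lai", "trlai")):
        sub = attribution.xs(pred, level="predictor")
        sub = sub[sub["passed_screen"].astype(bool) & sub["significant"].astype(bool)]
        out[f"n_significant_{key}"] = int(len(sub))
        out[f"frac_negative_{key}"] = (
            float((sub["theil_sen_slope"] < 0).mean()) if len(sub) else float("nan")
        )
    return out


def dominant_driver_recovery(n_cells=100, n_months=60, ratio=3.0, seed=0,
                             dominant="temperature"):
    """Fraction of replicate cells whose mean-|SHAP| rank 1 is the planted
    dominant driver (its modulation is ``ratio`` times all others')."""
    n_lat = max(int(np.sqrt(n_cells)), 3)
    n_lon = int(np.ceil(n_cells / n_lat))
    coupling, predictors, meta = generate_driver_benchmark(
        n_lat=n_lat, n_lon=n_lon, n_months=n_months, dominant=dominant,
        ratio=ratio, seed=seed,
    )
    attribution, report = attribution_sweep(coupling, predictors, meta)
    ranks = attribution.xs(dominant, level="predictor")
    ranked = ranks[np.isfinite(ranks["importance_rank"])]
    top1 = float((ranked["importance_rank"] == 1).mean()) if len(ranked) else float("nan")
    return {
        "top1_rate": top1,
        "n_cells": int(report["n_cells"]),
        "n_ranked": int(len(ranked)),
    }


def theil_sen_exactness(seed=0, sizes=(5, 25, 80, 200)):
    """Slope vs explicit pairwise-median enumeration, plus exact-line recovery."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for n in sizes:
        x = rng.normal(size=n)
        y = 1.5 * x + rng.normal(size=n)
        if n >= 25:
            y[rng.integers(n)] += 50.0  # gross outlier
        s, _, _ = theil_sen_sensitivity(x, y, alpha=0.01)
        worst = max(worst, abs(s - pairwise_median_slope(x, y)))
    x = np.linspace(-3, 7, 40)
    s_line, _, _ = theil_sen_sensitivity(x, 2.0 * x + 1.0)
    return {
        "max_abs_diff": worst,
        "line_slope_error": abs(s_line - 2.0),
        "n_max": max(sizes),
    }


def bh_fdr_check(n_p=1000, n_reps=200, q=0.05, seed=0, n_exact=50):
    """Exactness of the step-up flags vs the brute-force definition, and the
    mean false-discovery proportion under a complete null."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_exact):
        p = rng.random(size=rng.integers(3, 40))
        rej, _ = benjamini_hochberg(p, q=q)
        if not np.array_equal(rej, bh_stepup_reference(p, q=q)):
            mismatches += 1
    fdps = []
    for _ in range(n_reps):
        p = rng.random(size=n_p)
        rej, _ = benjamini_hochberg(p, q=q)
        fdps.append(1.0 if rej.any() else 0.0)  # all nulls: FDP is 0 or 1
    return {
        "n_flag_mismatches": mismatches,
        "mean_fdp": float(np.mean(fdps)),
        "n_reps": n_reps,
    }


def filter_rule_conformance():
    """Constructed 24-month scenario for the three retention rules.

    Daily coupling values are defined everywhere except in months where a
    prescribed fraction is masked; monthly temperature and SM anomaly take
    prescribed values.  Returns the number of months whose retention flag
    disagrees with the rule arithmetic (T >= 5 degC, SM anomaly < 0, missing
    fraction < 0.2), which must be zero, plus the retained month list.
    """
    dates = pd.date_range("2003-01-01", "2004-12-31", freq="D")
    rng = np.random.default_rng(12345)
    pcor = np.full(len(dates), -0.4)
    months = pd.period_range("2003-01", periods=24, freq="M")
    # per-month scenario: (missing_fraction, temperature, sm_anomaly)
    miss = np.tile([0.0, 0.1, 0.19, 0.21, 0.5, 0.0, 0.0, 0.15, 0.3, 0.05, 0.0, 0.25], 2)
    temp = np.tile([-3.0, 4.9, 5.0, 5.1, 12.0, 20.0, 25.0, 18.0, 10.0, 5.0, 2.0, -1.0], 2)
    sm_an = np.tile([-0.01, -0.02, -0.005, -0.01, 0.02, -0.03, 0.0, -0.01, -0.02, 0.01, -0.01, -0.02], 2)
    per = dates.to_period("M")
    for k, m in enumerate(months):
        idx = np.nonzero(per == m)[0]
        n_mask = int(np.floor(miss[k] * len(idx)))
        if n_mask:
            pcor[rng.choice(idx, size=n_mask, replace=False)] = np.nan
    monthly = monthly_aggregate(dates, pcor, max_missing=0.2)
    t_m = pd.Series(temp, index=months)
    s_m = pd.Series(sm_an, index=months)
    flagged = apply_filters(monthly, t_m, s_m, temp_threshold=5.0)
    # independent rule arithmetic on the construction itself
    days_in = monthly["n_days"].to_numpy()
    n_masked = np.array(
        [int(np.floor(miss[k] * days_in[k])) for k in range(24)]
    )
    expected = (
        (n_masked / days_in < 0.2) & (temp >= 5.0) & (sm_an < 0.0)
    )
    got = flagged["retained"].to_numpy(dtype=bool)
    return {
        "n_mismatch": int((expected != got).sum()),
        "n_months": 24,
        "n_retained": int(got.sum()),
        "retained_months": [str(m) for m, g in zip(months, got) if g],
    }


def determinism_check(workdir, seed=0, n_lat=6, n_lon=6, n_years=4):
    """Run the pipeline twice under one config; compare artifacts byte-wise."""
    workdir = Path(workdir)
    identical = True
    paths = []
    for run in ("run_a", "run_b"):
        cfg = RunConfig(seed=seed, output_dir=str(workdir / run))
        cfg.synthetic = SyntheticConfig(
            n_lat=n_lat, n_lon=n_lon, n_years=n_years, seed=seed
        )
        res = run_pipeline(cfg, write=True)
        paths.append(res.output_dir)
    names = sorted(p.name for p in paths[0].iterdir())
    names_b = sorted(p.name for p in paths[1].iterdir())
    if names != names_b:
        identical = False
    else:
        for name in names:
            if not filecmp.cmp(paths[0] / name, paths[1] / name, shallow=False):
                identical = False
                break
    return {"identical": bool(identical), "n_files": len(names)}
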
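"""Synthetic gridded dataset with a prescribed, recoverable SM->VPD coupling.

The generator emulates the statistical structure the pipeline assumes in real
data, with known ground truth:

* daily soil moisture = seasonal cycle + AR(1) anomalies,
* daily temperature = seasonal cycle + AR(1) anomalies,
* monthly LAI = temperature-driven seasonal cycle + multiplicative noise,
* monthly transpiration = conductance-like function of LAI, soil moisture and
  atmospheric demand (positive wherever LAI is positive),
* daily VPD = seasonal cycle + temperature-linked term
  + beta_cell(t) * SM_anomaly(t - lag_true) + white noise,

with ``beta_cell(t) = b0 + b_lai * LAI(t) + b_phys * (Tr/LAI)(t)`` carrying
the correlation sign: negative beta produces the physically typical negative
coupling (dry soil -> high VPD), and negative ``b_lai`` / ``b_phys`` make the
coupling more negative as vegetation activity increases.  Daily VPD anomalies
are dominated by white noise (fast atmospheric decorrelation), which keeps the
sampling variance of windowed correlations near the independent-sample value.

Everything is deterministic under ``(config, seed)``; monthly predictors are
exact aggregates of the daily fields where a daily field exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.signal import lfilter

from .config import SyntheticConfig

__all__ = [
    "SyntheticData",
    "generate_dataset",
    "generate_ancillary",
    "generate_driver_benchmark",
    "PREDICTOR_NAMES",
]

PREDICTOR_NAMES = (
    "lai",
    "transpiration_over_lai",
    "precipitation",
    "temperature",
    "vpd",
    "surface_sm",
    "wind",
)


@dataclass
class SyntheticData:
    """Bundle of generated inputs plus ground truth."""

    daily: xr.Dataset  # sm, vpd, temperature, precipitation, wind (time, lat, lon)
    predictors: pd.DataFrame  # tidy, MultiIndex (cell_id, month)
    meta: pd.DataFrame  # per-cell ancillary/static fields
    truth: pd.DataFrame  # per-cell generative coefficients
    config: SyntheticConfig


def _ar1(innov, a):
    """AR(1) filter along axis 0 from standard-normal innovations."""
    return lfilter([1.0], [1.0, -a], innov, axis=0)


def _monthly_mean(arr, starts):
    """Mean over month blocks of a (time, cells) array."""
    sums = np.add.reduceat(arr, starts, axis=0)
    counts = np.diff(np.append(starts, arr.shape[0]))
    return sums / counts[:, None]


def _monthly_mean_nan(arr, month_code):
    """NaN-skipping monthly mean of a (time, cells) array."""
    return pd.DataFrame(arr).groupby(np.asarray(month_code)).mean().to_numpy()


def generate_dataset(config: SyntheticConfig) -> SyntheticData:
    """Generate the full synthetic dataset for a config (see module docstring)."""
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    n_lat, n_lon = cfg.n_lat, cfg.n_lon
    C = n_lat * n_lon

    start = pd.Timestamp(cfg.start_date)
    dates = pd.date_range(
        start, start + pd.DateOffset(years=cfg.n_years), freq="D", inclusive="left"
    )
    N = len(dates)
    month_period = dates.to_period("M")
    month_code = (month_period.year - month_period.year[0]) * 12 + (
        month_period.month - month_period.month[0]
    )
    month_code = np.asarray(month_code)
    starts = np.flatnonzero(np.diff(np.append(-1, month_code)))
    M = month_code.max() + 1
    months = pd.period_range(dates[0], periods=M, freq="M")

    # ---- static climate gradients -------------------------------------
    lat = np.linspace(58.0, 28.0, n_lat)
    lon = np.linspace(0.0, 3.0 * (n_lon - 1), n_lon)
    t_lo, t_hi = cfg.temp_range
    a_lo, a_hi = cfg.aridity_range
    mean_t = np.repeat(np.linspace(t_lo, t_hi, n_lat), n_lon)
    mean_t = mean_t + rng.uniform(-0.5, 0.5, C)
    aridity = np.tile(np.linspace(a_lo, a_hi, n_lon), n_lat)
    aridity = np.maximum(aridity + rng.uniform(-0.08, 0.08, C), 0.05)

    # smooth spatial heterogeneity of the coupling modulation coefficients
    rr = np.repeat(np.arange(n_lat), n_lon) / max(n_lat - 1, 1)
    cc = np.tile(np.arange(n_lon), n_lat) / max(n_lon - 1, 1)
    u1 = np.cos(np.pi * rr) * np.cos(2.0 * np.pi * cc) + 0.3 * rng.normal(size=C)
    u2 = np.sin(np.pi * cc) * np.cos(2.0 * np.pi * rr) + 0.3 * rng.normal(size=C)
    u1 = (u1 - u1.mean()) / max(u1.std(), 1e-12)
    u2 = (u2 - u2.mean()) / max(u2.std(), 1e-12)
    b_lai_cell = cfg.b_lai * (1.0 + cfg.b_spatial_cv * u1)
    b_phys_cell = cfg.b_phys * (1.0 + cfg.b_spatial_cv * u2)
    b0_cell = np.full(C, cfg.b0)

    # ---- daily drivers -------------------------------------------------
    doy = dates.dayofyear.values
    seas = np.cos(2.0 * np.pi * (doy - 210) / 365.25)[:, None]  # peak late July

    t_det = mean_t[None, :] + cfg.temp_seasonal_amplitude * seas
    t_anom = cfg.temp_anom_sd * _ar1(rng.normal(size=(N, C)), cfg.temp_ar1)
    temperature = t_det + t_anom

    sm_mean = 0.16 + 0.12 * np.exp(-aridity / 1.2)
    sm_det = sm_mean[None, :] - 0.02 * seas  # slightly wetter winters
    sm_anom = cfg.sm_innovation_sd * _ar1(rng.normal(size=(N, C)), cfg.sm_ar1)
    sm = sm_det + sm_anom

    vpd_base = 0.10 + 0.035 * np.maximum(t_det, 0.0) * (0.8 + 0.2 * aridity[None, :])

    vpd_noise = cfg.noise_sd_vpd * rng.normal(size=(N, C))

    # ---- monthly vegetation fields ------------------------------------
    t_clim_month = _monthly_mean(t_det, starts)
    lai_max = 0.8 + 3.5 * np.exp(-aridity / 1.5)
    growth = np.clip((t_clim_month - 2.0) / 12.0, 0.05, 1.0)
    lai_noise = _ar1(rng.normal(size=(M, C)), 0.5) * np.sqrt(1.0 - 0.5**2)
    lai = lai_max[None, :] * growth * (1.0 + cfg.lai_noise_cv * lai_noise)
    lai = np.maximum(lai, 0.05)

    sm_month = _monthly_mean(sm, starts)
    vpd_clim_month = np.maximum(_monthly_mean(vpd_base, starts), 0.05)
    stress = np.clip((sm_month - 0.08) / (0.25 - 0.08), 0.05, 1.0)
    tr_noise = rng.normal(size=(M, C))
    transpiration = (
        1.2
        * lai**0.9
        * stress
        * vpd_clim_month**0.5
        * (1.0 + cfg.tr_noise_cv * tr_noise)
    )
    transpiration = np.maximum(transpiration, 1e-3)
    tr_over_lai = transpiration / lai

    # ---- coupled daily VPD --------------------------------------------
    beta_month = (
        b0_cell[None, :]
        + b_lai_cell[None, :] * lai
        + b_phys_cell[None, :] * tr_over_lai
    )
    beta_daily = beta_month[month_code, :]
    x_lag = np.zeros((N, C))
    if cfg.lag_true > 0:
        x_lag[cfg.lag_true :] = sm_anom[: -cfg.lag_true]
    else:
        x_lag = sm_anom
    vpd = vpd_base + cfg.vpd_temp_slope * t_anom + beta_daily * x_lag + vpd_noise

    # ---- precipitation and wind ---------------------------------------
    wet = rng.random(size=(N, C)) < 0.35
    p_scale = 8.0 / (aridity + 0.5)
    precipitation = np.where(wet, rng.exponential(1.0, size=(N, C)) * p_scale, 0.0)
    wind = np.maximum(3.0 + 0.8 * _ar1(rng.normal(size=(N, C)), 0.5), 0.2)

    # ---- missing-data injection ---------------------------------------
    if cfg.missing_rate > 0:
        sm = sm.copy()
        vpd = vpd.copy()
        sm[rng.random(size=(N, C)) < cfg.missing_rate] = np.nan
        vpd[rng.random(size=(N, C)) < cfg.missing_rate] = np.nan

    # ---- study-area mask ----------------------------------------------
    veg_frac = np.clip(
        80.0 - 12.0 * (aridity - a_lo) / max(a_hi - a_lo, 1e-9) + rng.uniform(-5, 5, C),
        6.0,
        98.0,
    )
    irr_frac = rng.uniform(0.0, 8.0, C)
    n_sparse = int(round(cfg.veg_sparse_frac * C))
    n_irr = int(round(cfg.irrigated_frac * C))
    special = rng.choice(C, size=min(n_sparse + n_irr, C), replace=False)
    veg_frac[special[:n_sparse]] = rng.uniform(0.0, 5.0, n_sparse)
    irr_frac[special[n_sparse : n_sparse + n_irr]] = rng.uniform(10.0, 40.0, n_irr)
    masked = (veg_frac <= 5.0) | (irr_frac >= 10.0)

    zone = np.where(
        mean_t < 6.0,
        "cold",
        np.where(aridity >= 1.6, "arid", np.where(mean_t >= 15.0, "warm", "temperate")),
    )

    annual_precip = precipitation.mean(axis=0) * 365.25
    cell_id = np.arange(C)
    meta = pd.DataFrame(
        {
            "cell_id": cell_id,
            "row": np.repeat(np.arange(n_lat), n_lon),
            "col": np.tile(np.arange(n_lon), n_lat),
            "lat": np.repeat(lat, n_lon),
            "lon": np.tile(lon, n_lat),
            "climate_zone": zone,
            "aridity": aridity,
            "mean_temperature": mean_t,
            "vegetation_fraction": veg_frac,
            "irrigation_fraction": irr_frac,
            "annual_precipitation_mm": annual_precip,
            "net_radiation_mm": aridity * annual_precip,
            "masked": masked,
        }
    ).set_index("cell_id")

    truth = pd.DataFrame(
        {
            "cell_id": cell_id,
            "b0": b0_cell,
            "b_lai": b_lai_cell,
            "b_phys": b_phys_cell,
            "noise_sd_vpd": cfg.noise_sd_vpd,
            "sm_innovation_sd": cfg.sm_innovation_sd,
            "lag_true": cfg.lag_true,
            "seed": cfg.seed,
        }
    ).set_index("cell_id")

    meta = generate_ancillary(cfg, truth, meta, rng=rng)

    def cube(a):
        return (("time", "lat", "lon"), a.reshape(N, n_lat, n_lon))

    daily = xr.Dataset(
        {
            "sm": cube(sm),
            "vpd": cube(vpd),
            "temperature": cube(temperature),
            "precipitation": cube(precipitation),
            "wind": cube(wind),
        },
        coords={"time": dates, "lat": lat, "lon": lon},
    )
    daily["sm"].attrs["units"] = "m3 m-3"
    daily["vpd"].attrs["units"] = "kPa"
    daily["temperature"].attrs["units"] = "degC"
    daily["precipitation"].attrs["units"] = "mm day-1"
    daily["wind"].attrs["units"] = "m s-1"

    idx = pd.MultiIndex.from_product([cell_id, months], names=["cell_id", "month"])
    pred = pd.DataFrame(
        {
            "lai": lai.T.ravel(),
            "transpiration": transpiration.T.ravel(),
            "transpiration_over_lai": tr_over_lai.T.ravel(),
            "precipitation": _monthly_mean(precipitation, starts).T.ravel(),
            "temperature": _monthly_mean(temperature, starts).T.ravel(),
            "vpd": _monthly_mean_nan(vpd, month_code).T.ravel(),
            "surface_sm": _monthly_mean_nan(sm, month_code).T.ravel(),
            "wind": _monthly_mean(wind, starts).T.ravel(),
        },
        index=idx,
    )

    return SyntheticData(daily=daily, predictors=pred, meta=meta, truth=truth, config=cfg)


def generate_ancillary(config, truth, meta, rng=None):
    """Biodiversity and root-zone storage with a prescribed monotone link to
    the cells' true coupling-modulation coefficients, confounded by climate.

    ``bio_effect`` links biodiversity to the physiology coefficient
    ``b_phys`` (signed: larger coefficient -> richer flora), and
    ``rootzone_effect`` links root-zone water storage to the structure
    coefficient ``b_lai``; both receive aridity/temperature confounding and
    independent noise (all in SD units).  A zero effect gives covariates with
    no sensitivity signal beyond climate.
    """
    if rng is None:
        rng = np.random.default_rng(np.uint32(config.seed) + 1_000_003)
    meta = meta.copy()

    def z(v):
        v = np.asarray(v, dtype=float)
        s = v.std()
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    z_phys = z(truth["b_phys"])
    z_lai = z(truth["b_lai"])
    z_t = z(meta["mean_temperature"])
    z_a = z(meta["aridity"])
    c = config.ancillary_confound
    noise = config.ancillary_noise
    bio = (
        config.bio_effect * z_phys
        + c * (z_t - z_a)
        + noise * rng.normal(size=len(meta))
    )
    rz = (
        config.rootzone_effect * z_lai
        + c * (-z_a)
        + noise * rng.normal(size=len(meta))
    )
    meta["biodiversity"] = np.maximum(300.0 + 120.0 * bio, 5.0)
    meta["rootzone_storage"] = np.maximum(180.0 + 70.0 * rz, 10.0)
    return meta


def generate_driver_benchmark(
    n_lat=10,
    n_lon=10,
    n_months=36,
    dominant="temperature",
    ratio=3.0,
    base_weight=1.0,
    noise_sd=1.5,
    seed=0,
    isolated=True,
):
    """Monthly-level attribution benchmark with one dominant planted driver.

    Each cell gets seven independent AR(0.3) standard-normal monthly predictor
    series; the target coupling is a linear combination where the dominant
    predictor's weight is ``ratio`` times the others', mapped affinely into a
    plausible coupling range.  Returns ``(coupling, predictors, meta)`` shaped
    like the outputs of the main pipeline (all months retained).  With
    ``isolated`` (default) the replicates are spread on a doubled grid with
    masked spacer cells so each model trains on its own cell only, making the
    replicates genuinely independent.
    """
    if dominant not in PREDICTOR_NAMES:
        raise ValueError(f"dominant must be one of {PREDICTOR_NAMES}")
    rng = np.random.default_rng(seed)
    C = n_lat * n_lon
    months = pd.period_range("2003-01", periods=n_months, freq="M")
    weights = np.full(len(PREDICTOR_NAMES), base_weight)
    weights[PREDICTOR_NAMES.index(dominant)] = ratio * base_weight

    zs = _ar1(rng.normal(size=(len(PREDICTOR_NAMES), n_months, C)), 0.3)
    zs *= np.sqrt(1.0 - 0.3**2)
    y = np.tensordot(weights, zs, axes=(0, 0)) + noise_sd * rng.normal(
        size=(n_months, C)
    )
    scale = np.sqrt((weights**2).sum() + noise_sd**2)
    pcor = np.clip(-0.45 + 0.12 * y / scale, -1.0, 1.0)

    if isolated:
        # replicates at even (row, col) of a doubled grid; spacers masked
        g_lat, g_lon = 2 * n_lat, 2 * n_lon
        rows = np.repeat(np.arange(g_lat), g_lon)
        cols = np.tile(np.arange(g_lon), g_lat)
        masked = ~((rows % 2 == 0) & (cols % 2 == 0))
        meta = pd.DataFrame(
            {
                "cell_id": np.arange(g_lat * g_lon),
                "row": rows,
                "col": cols,
                "masked": masked,
            }
        ).set_index("cell_id")
        cell_id = meta.index[~masked].to_numpy()[:C]
    else:
        cell_id = np.arange(C)
        meta = pd.DataFrame(
            {
                "cell_id": cell_id,
                "row": np.repeat(np.arange(n_lat), n_lon),
                "col": np.tile(np.arange(n_lon), n_lat),
                "masked": False,
            }
        ).set_index("cell_id")
    idx = pd.MultiIndex.from_product([cell_id, months], names=["cell_id", "month"])
    pred = pd.DataFrame(
        {name: zs[k].T.ravel() for k, name in enumerate(PREDICTOR_NAMES)}, index=idx
    )
    coupling = pd.DataFrame(
        {
            "pcor_monthly": pcor.T.ravel(),
            "retained": True,
        },
        index=idx,
    )
    return coupling, pred, meta
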
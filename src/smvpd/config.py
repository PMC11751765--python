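"""Configuration objects for the synthetic generator and the pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["SyntheticConfig", "RunConfig", "load_config", "config_hash"]

ALLOWED_LAGS = (1, 7, 14)


@dataclass
class SyntheticConfig:
    """Generative settings for the synthetic gridded dataset.

    The daily fields follow seasonal cycles plus AR(1) anomalies; the daily
    VPD contains a coupling term ``beta_cell(t) * SM_anomaly(t - lag_true)``
    whose coefficient is modulated linearly by vegetation structure (LAI) and
    physiology (transpiration / LAI):

        beta_cell(t) = b0 + b_lai * LAI(t) + b_phys * (Tr/LAI)(t)

    ``beta`` carries the sign of the resulting correlation: negative values
    produce the physically typical negative SM-VPD coupling (soil dryness
    propagating to atmospheric dryness), and negative ``b_lai`` / ``b_phys``
    make the coupling *more* negative as vegetation activity increases.
    """

    n_lat: int = 15
    n_lon: int = 15
    start_date: str = "2003-01-01"
    n_years: int = 12
    seed: int = 0
    lag_true: int = 7
    # coupling coefficients, kPa per unit SM anomaly (m3/m3)
    b0: float = 2.5
    b_lai: float = -3.0
    b_phys: float = -4.5
    b_spatial_cv: float = 0.25  # smooth relative spread of b_lai/b_phys across cells
    noise_sd_vpd: float = 0.15  # kPa, white daily VPD noise
    sm_ar1: float = 0.85  # lag-1 autocorrelation of daily SM anomalies
    sm_innovation_sd: float = 0.008  # m3/m3
    temp_range: tuple = (2.0, 18.0)  # deg C, long-term mean across rows
    temp_seasonal_amplitude: float = 10.0  # deg C
    temp_ar1: float = 0.6
    temp_anom_sd: float = 1.5  # deg C, innovation scale
    vpd_temp_slope: float = 0.03  # kPa per deg C of temperature anomaly
    aridity_range: tuple = (0.4, 2.5)  # net radiation (mm) / precipitation
    lai_noise_cv: float = 0.12
    tr_noise_cv: float = 0.12
    missing_rate: float = 0.0  # fraction of daily SM/VPD values masked at random
    veg_sparse_frac: float = 0.02  # cells with vegetation cover <= 5%
    irrigated_frac: float = 0.02  # cells with irrigation >= 10%
    # ancillary covariate links (SD units of the cell coupling coefficients)
    bio_effect: float = 0.8  # biodiversity ~ physiology coefficient
    rootzone_effect: float = 0.8  # root-zone storage ~ structure coefficient
    ancillary_confound: float = 0.5  # climate confounding, SD units
    ancillary_noise: float = 1.0  # SD units

    def validate(self):
        if self.n_lat * self.n_lon < 9:
            raise ValueError("grid must have at least 9 cells (3x3 pooling)")
        if not 0.0 < self.sm_ar1 < 1.0:
            raise ValueError("sm_ar1 must be in (0, 1)")
        if self.n_years < 3:
            raise ValueError("n_years must be >= 3 (climatology estimable)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not np.isfinite(v):
                raise ValueError(f"non-finite parameter {f.name}={v}")
        return self


@dataclass
class RunConfig:
    """End-to-end pipeline settings (thresholds per the coupling/attribution
    filtering rules; one data seed, a fixed independent model seed)."""

    output_dir: str = "smvpd_output"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    input_daily: str | None = None  # NetCDF paths; None -> synthetic
    input_predictors: str | None = None
    variable_map: dict = field(
        default_factory=lambda: {
            "sm": "sm",
            "vpd": "vpd",
            "temperature": "temperature",
        }
    )
    lag: int = 7
    window: int = 30
    min_pairs: int = 24
    max_missing: float = 0.2
    temp_threshold: float = 5.0
    require_negative_sm: bool = True
    require_negative_pcor: bool = False
    lowess_frac: float = 0.4
    lowess_iterations: int = 0
    lowess_delta_frac: float = 0.01
    anomaly_order: str = "climatology_first"
    min_samples: int = 20
    oob_threshold: float = 0.2
    slope_alpha: float = 0.01
    model_random_state: int = 42
    n_estimators: int = 100
    max_features: float = 0.3
    drop_predictors: tuple = ()
    include_month_predictor: bool = False
    bin_alpha: float = 0.05
    fdr_q: float = 0.05
    bin_min_cells_mean: int = 10
    bin_min_cells_corr: int = 20
    aridity_edges: tuple = (0.0, 0.5, 0.8, 1.2, 2.0, 5.0, np.inf)
    temperature_edges: tuple = (-np.inf, 0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, np.inf)
    allow_any_lag: bool = False

    def validate(self):
        if self.lag not in ALLOWED_LAGS and not self.allow_any_lag:
            raise ValueError(
                f"lag {self.lag} not in {ALLOWED_LAGS}; set allow_any_lag to override"
            )
        if not 0.0 < self.max_missing <= 1.0:
            raise ValueError("max_missing must be in (0, 1]")
        if not 0.0 < self.max_features <= 1.0:
            raise ValueError("max_features must be in (0, 1]")
        for name in ("slope_alpha", "bin_alpha", "fdr_q"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.min_samples < 3:
            raise ValueError("min_samples must be >= 3")
        self.synthetic.validate()
        return self


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, float) and np.isinf(obj):
        return "inf" if obj > 0 else "-inf"
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_hash(cfg) -> str:
    """Stable short hash of a config dataclass, for provenance blocks.

    Covers the scientific parameters only: artifact locations (output
    directory, input paths) do not change what is computed.
    """
    payload = _to_jsonable(cfg)
    if isinstance(payload, dict):
        for key in ("output_dir", "input_daily", "input_predictors"):
            payload.pop(key, None)
    payload = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _from_mapping(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = dict(data)
    for key in ("temp_range", "aridity_range", "aridity_edges", "temperature_edges",
                "drop_predictors"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(
                np.inf if v == "inf" else (-np.inf if v == "-inf" else v)
                for v in kwargs[key]
            )
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Read a RunConfig from a YAML key-value file."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    syn = data.pop("synthetic", {})
    cfg = _from_mapping(RunConfig, data)
    if syn:
        cfg.synthetic = _from_mapping(SyntheticConfig, syn)
    return cfg.validate()
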
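"""Per-cell driver attribution of monthly SM-VPD coupling.

For every unmasked grid cell a random-forest regression (100 trees, max
features 0.3, bootstrap sampling, random state 42) is trained on the retained
months of the cell and its up-to-8 existing neighbours (3x3 pooling raises the
sample size while preserving climatic homogeneity).  Skill is the out-of-bag
R²; cells with fewer than 20 pooled samples or out-of-bag R² below 0.2 are
screened out.  For the remaining cells, exact SHAP values decompose the
predictions into per-predictor contributions; predictors are ranked by mean
absolute contribution, and the sensitivity of the coupling to each predictor
is the Theil-Sen slope of its SHAP contributions against its values, with a
two-sided Kendall-tau significance test (significant below p = 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils.validation import check_is_fitted

from ._tree_shap import forest_shap_values
from .synthetic import PREDICTOR_NAMES

__all__ = [
    "assemble_training_table",
    "theil_sen_sensitivity",
    "DriverAttribution",
    "attribution_sweep",
]


def assemble_training_table(
    cell_id, coupling, predictors, meta, min_samples=20, feature_names=None
):
    """Pooled training table for one focal cell.

    Rows are all retained (cell, month) pairs from the focal cell and its
    existing, unmasked 3x3 neighbours; the target is the monthly coupling and
    the features are the predictor columns.  Returns ``(X, y)`` DataFrames/
    Series (possibly empty).  Cells with fewer than ``min_samples`` pooled
    rows are excluded by the caller ("fewer than 20 data samples"); exactly
    ``min_samples`` rows are kept.
    """
    if meta.loc[cell_id, "masked"]:
        raise ValueError(f"cell {cell_id} is masked (outside the study area)")
    row, col = int(meta.loc[cell_id, "row"]), int(meta.loc[cell_id, "col"])
    pool = meta[
        (meta["row"].between(row - 1, row + 1))
        & (meta["col"].between(col - 1, col + 1))
        & (~meta["masked"])
    ].index
    feats = list(feature_names) if feature_names is not None else list(PREDICTOR_NAMES)
    sub = coupling[
        coupling["retained"].to_numpy(dtype=bool)
        & coupling.index.get_level_values("cell_id").isin(pool)
    ]
    table = sub[["pcor_monthly"]].join(predictors[feats], how="inner").dropna()
    return table[feats], table["pcor_monthly"]


def theil_sen_sensitivity(values, contributions, alpha=0.01):
    """Theil-Sen slope of SHAP contributions against predictor values.

    The slope is the median of all pairwise slopes (pairs with equal
    predictor values are skipped); the two-sided p-value comes from the
    Kendall-tau test of monotone association.  Returns
    ``(slope, p, significant)``; all-NaN/(fewer than 3 distinct values)
    inputs yield ``(nan, nan, False)``.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(contributions, dtype=float)
    m = np.isfinite(x) & np.isfinite(y)
    x, y = x[m], y[m]
    if np.unique(x).size < 3:
        return float("nan"), float("nan"), False
    slope = stats.theilslopes(y, x).slope
    if np.ptp(y) == 0:
        return float(slope), 1.0, False
    p = stats.kendalltau(x, y).pvalue
    return float(slope), float(p), bool(p < alpha)


@dataclass
class CellAttribution:
    """Attribution result for one grid cell."""

    cell_id: int
    n_samples: int
    oob_r2: float
    passed_screen: bool
    mean_abs_shap: dict = field(default_factory=dict)
    importance_rank: dict = field(default_factory=dict)
    theil_sen_slope: dict = field(default_factory=dict)
    slope_p: dict = field(default_factory=dict)
    significant: dict = field(default_factory=dict)


class DriverAttribution(BaseEstimator):
    """Random-forest + SHAP + Theil-Sen attribution for one training table.

    Parameters mirror the pipeline defaults: ``n_estimators=100``,
    ``max_features=0.3``, bootstrap sampling, ``random_state=42``; cells need
    ``min_samples`` rows and out-of-bag R² of at least ``oob_threshold`` to
    pass the screen; slopes are significant below ``alpha``.

    Attributes (after :meth:`fit`)
    ------------------------------
    model_ : fitted ``RandomForestRegressor``
    oob_r2_ : float, out-of-bag R² (NaN if undefined)
    passed_screen_ : bool
    shap_values_ : ndarray (n_samples, n_features)
    base_value_ : float
    mean_abs_shap_ : Series per feature
    importance_rank_ : Series per feature (1 = most important; ties broken
        by feature name)
    theil_sen_slope_, slope_p_, significant_ : Series per feature
    """

    def __init__(
        self,
        n_estimators=100,
        max_features=0.3,
        random_state=42,
        min_samples=20,
        oob_threshold=0.2,
        alpha=0.01,
        always_compute_shap=False,
    ):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.random_state = random_state
        self.min_samples = min_samples
        self.oob_threshold = oob_threshold
        self.alpha = alpha
        self.always_compute_shap = always_compute_shap

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            self.feature_names_in_ = np.asarray(
                [f"x{i}" for i in range(Xv.shape[1])], dtype=object
            )
        yv = np.asarray(y, dtype=float)
        if Xv.ndim != 2 or yv.shape[0] != Xv.shape[0]:
            raise ValueError("X must be 2-D and aligned with y")
        if not (np.isfinite(Xv).all() and np.isfinite(yv).all()):
            raise ValueError("training table contains non-finite values")
        self.n_samples_ = Xv.shape[0]
        names = list(self.feature_names_in_)

        if self.n_samples_ < self.min_samples:
            self.oob_r2_ = float("nan")
            self.passed_screen_ = False
            return self

        self.model_ = RandomForestRegressor(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            bootstrap=True,
            oob_score=True,
            random_state=self.random_state,
            n_jobs=1,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # oob warning on tiny tables
            self.model_.fit(Xv, yv)
        if np.ptp(yv) == 0:
            self.oob_r2_ = float("nan")  # skill undefined for a constant target
            self.passed_screen_ = False
            return self
        self.oob_r2_ = float(self.model_.oob_score_)
        self.passed_screen_ = bool(self.oob_r2_ >= self.oob_threshold)
        if not self.passed_screen_ and not self.always_compute_shap:
            return self  # screened out: no decomposition needed

        phi, base = forest_shap_values(self.model_, Xv)
        self.shap_values_ = phi
        self.base_value_ = base
        mas = pd.Series(np.abs(phi).mean(axis=0), index=names)
        self.mean_abs_shap_ = mas
        order = sorted(names, key=lambda f: (-mas[f], f))
        self.importance_rank_ = pd.Series(
            {f: r + 1 for r, f in enumerate(order)}, index=names
        )

        slopes, ps, sig = {}, {}, {}
        for j, f in enumerate(names):
            s, p, ok = theil_sen_sensitivity(Xv[:, j], phi[:, j], alpha=self.alpha)
            slopes[f], ps[f], sig[f] = s, p, ok
        self.theil_sen_slope_ = pd.Series(slopes, index=names)
        self.slope_p_ = pd.Series(ps, index=names)
        self.significant_ = pd.Series(sig, index=names)
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=float))

    def to_record(self, cell_id=-1) -> CellAttribution:
        has_shap = hasattr(self, "mean_abs_shap_")
        return CellAttribution(
            cell_id=cell_id,
            n_samples=self.n_samples_,
            oob_r2=self.oob_r2_,
            passed_screen=self.passed_screen_,
            mean_abs_shap=dict(self.mean_abs_shap_) if has_shap else {},
            importance_rank=dict(self.importance_rank_) if has_shap else {},
            theil_sen_slope=dict(self.theil_sen_slope_) if has_shap else {},
            slope_p=dict(self.slope_p_) if has_shap else {},
            significant=dict(self.significant_) if has_shap else {},
        )


def attribution_sweep(
    coupling,
    predictors,
    meta,
    feature_names=None,
    min_samples=20,
    oob_threshold=0.2,
    alpha=0.01,
    n_estimators=100,
    max_features=0.3,
    random_state=42,
):
    """Fit the attribution model for every unmasked cell.

    Returns ``(results, report)`` where ``results`` is a tidy DataFrame with
    one row per (cell, predictor) plus per-cell skill columns, and ``report``
    collects screen statistics and per-cell failures (the sweep never aborts
    on a single-cell error).
    """
    feats = list(feature_names) if feature_names is not None else list(PREDICTOR_NAMES)
    rows = []
    report = {
        "n_cells": 0,
        "n_masked": int(meta["masked"].sum()),
        "n_too_few_samples": 0,
        "n_low_skill": 0,
        "n_passed": 0,
        "errors": {},
    }
    for cell_id in meta.index[~meta["masked"]]:
        report["n_cells"] += 1
        try:
            X, y = assemble_training_table(
                cell_id, coupling, predictors, meta,
                min_samples=min_samples, feature_names=feats,
            )
            est = DriverAttribution(
                n_estimators=n_estimators,
                max_features=max_features,
                random_state=random_state,
                min_samples=min_samples,
                oob_threshold=oob_threshold,
                alpha=alpha,
            ).fit(X, y)
        except Exception as exc:  # pragma: no cover - aggregated, not raised
            report["errors"][int(cell_id)] = str(exc)
            continue
        if est.n_samples_ < min_samples:
            report["n_too_few_samples"] += 1
        elif not est.passed_screen_:
            report["n_low_skill"] += 1
        else:
            report["n_passed"] += 1
        rec = est.to_record(cell_id)
        for f in feats:
            rows.append(
                {
                    "cell_id": cell_id,
                    "predictor": f,
                    "n_samples": rec.n_samples,
                    "oob_r2": rec.oob_r2,
                    "passed_screen": rec.passed_screen,
                    "mean_abs_shap": rec.mean_abs_shap.get(f, np.nan),
                    "importance_rank": rec.importance_rank.get(f, np.nan),
                    "theil_sen_slope": rec.theil_sen_slope.get(f, np.nan),
                    "slope_p": rec.slope_p.get(f, np.nan),
                    "significant": rec.significant.get(f, False),
                }
            )
    results = pd.DataFrame(rows)
    if not results.empty:
        results = results.set_index(["cell_id", "predictor"]).sort_index()
    return results, report
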
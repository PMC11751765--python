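"""Per-cell random-forest attribution: pooling, screens, ranks, slopes."""

import numpy as np
import pandas as pd
import pytest

from smvpd import (
    DriverAttribution,
    PREDICTOR_NAMES,
    assemble_training_table,
    attribution_sweep,
    generate_driver_benchmark,
    theil_sen_sensitivity,
)
from smvpd.benchmarks import pairwise_median_slope


def _toy_tables(n_lat, n_lon, months_per_cell, retained=None, seed=0):
    """Uniform grid where every cell has the same number of retained months."""
    rng = np.random.default_rng(seed)
    cells = np.arange(n_lat * n_lon)
    months = pd.period_range("2003-01", periods=months_per_cell, freq="M")
    idx = pd.MultiIndex.from_product([cells, months], names=["cell_id", "month"])
    predictors = pd.DataFrame(
        rng.normal(size=(len(idx), len(PREDICTOR_NAMES))),
        columns=list(PREDICTOR_NAMES),
        index=idx,
    )
    coupling = pd.DataFrame(
        {
            "pcor_monthly": rng.uniform(-0.8, -0.1, len(idx)),
            "retained": True if retained is None else retained,
        },
        index=idx,
    )
    meta = pd.DataFrame(
        {
            "cell_id": cells,
            "row": np.repeat(np.arange(n_lat), n_lon),
            "col": np.tile(np.arange(n_lon), n_lat),
            "masked": False,
        }
    ).set_index("cell_id")
    return coupling, predictors, meta


class TestAssembleTrainingTable:
    def test_interior_cell_pools_nine_cells(self):
        coupling, predictors, meta = _toy_tables(3, 3, 12)
        X, y = assemble_training_table(4, coupling, predictors, meta)
        assert len(X) == 9 * 12 == 108

    def test_corner_cell_pools_four_cells(self):
        coupling, predictors, meta = _toy_tables(3, 3, 5)
        X, y = assemble_training_table(0, coupling, predictors, meta)
        assert len(X) == 4 * 5 == 20  # boundary of the rule: 20 rows included

    def test_masked_focal_cell_rejected(self):
        coupling, predictors, meta = _toy_tables(3, 3, 12)
        meta.loc[4, "masked"] = True
        with pytest.raises(ValueError):
            assemble_training_table(4, coupling, predictors, meta)

    def test_masked_neighbours_excluded(self):
        coupling, predictors, meta = _toy_tables(3, 3, 12)
        meta.loc[[0, 1, 2], "masked"] = True
        X, _ = assemble_training_table(4, coupling, predictors, meta)
        assert len(X) == 6 * 12


class TestDriverAttribution:
    def test_sample_screen_boundary(self):
        coupling, predictors, meta = _toy_tables(1, 3, 19)  # corner pools 2 cells
        X, y = assemble_training_table(0, coupling, predictors, meta)
        est = DriverAttribution(min_samples=len(X) + 1).fit(X, y)
        assert not est.passed_screen_ and np.isnan(est.oob_r2_)

    def test_skill_on_smooth_signal(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=["a", "b", "c"])
        y = np.tanh(X["a"]) + 0.05 * rng.normal(size=200)
        est = DriverAttribution().fit(X, y)
        assert est.oob_r2_ > 0.8 and est.passed_screen_

    def test_null_skill_near_zero_on_average(self, rng):
        scores = []
        for _ in range(50):
            X = rng.normal(size=(60, 5))
            y = rng.normal(size=60)
            scores.append(DriverAttribution().fit(X, y).oob_r2_)
        assert np.mean(scores) <= 0.05

    def test_refit_is_deterministic(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 4)))
        y = X[0] + 0.3 * rng.normal(size=80)
        a = DriverAttribution().fit(X, y)
        b = DriverAttribution().fit(X, y)
        assert a.oob_r2_ == b.oob_r2_
        assert np.array_equal(a.shap_values_, b.shap_values_)

    def test_constant_target_screened_out(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)))
        est = DriverAttribution().fit(X, np.zeros(40))
        assert not est.passed_screen_ and np.isnan(est.oob_r2_)

    def test_rank_ties_broken_lexicographically(self):
        est = DriverAttribution()
        est.feature_names_in_ = np.array(["b", "a"], dtype=object)
        # two identical columns produce identical mean |SHAP|
        mas = pd.Series({"b": 0.5, "a": 0.5})
        order = sorted(["b", "a"], key=lambda f: (-mas[f], f))
        assert order == ["a", "b"]

    def test_zero_contribution_feature_ranked_last(self, rng):
        X = pd.DataFrame(
            {"signal": rng.normal(size=150), "dead": np.zeros(150)}
        )
        y = X["signal"] * 2 + 0.1 * rng.normal(size=150)
        est = DriverAttribution().fit(X, y)
        assert est.importance_rank_["dead"] == 2

    def test_sklearn_param_interface(self):
        est = DriverAttribution(alpha=0.05)
        assert est.get_params()["alpha"] == 0.05
        est.set_params(alpha=0.01)
        assert est.alpha == 0.01


class TestTheilSen:
    def test_exact_line(self):
        x = np.linspace(0, 10, 25)
        s, p, sig = theil_sen_sensitivity(x, 2 * x + 1)
        assert s == pytest.approx(2.0, abs=1e-12)
        assert sig

    def test_constant_contributions(self, rng):
        s, p, sig = theil_sen_sensitivity(rng.normal(size=30), np.zeros(30))
        assert s == 0.0 and not sig

    def test_matches_enumeration_with_outlier(self, rng):
        x = rng.normal(size=25)
        y = 0.7 * x + 0.1 * rng.normal(size=25)
        y[3] += 40.0
        s, _, _ = theil_sen_sensitivity(x, y)
        assert s == pairwise_median_slope(x, y)

    def test_degenerate_predictor(self):
        s, p, sig = theil_sen_sensitivity(np.ones(30), np.arange(30.0))
        assert np.isnan(s) and not sig


class TestSweep:
    def test_dominant_driver_recovered(self):
        coupling, predictors, meta = generate_driver_benchmark(
            n_lat=4, n_lon=4, n_months=60, dominant="wind", seed=3
        )
        res, report = attribution_sweep(coupling, predictors, meta)
        ranks = res.xs("wind", level="predictor")["importance_rank"].dropna()
        assert (ranks == 1).mean() >= 0.7
        assert report["errors"] == {}

    def test_ranks_are_permutations(self):
        coupling, predictors, meta = generate_driver_benchmark(
            n_lat=3, n_lon=3, n_months=40, seed=1
        )
        res, _ = attribution_sweep(coupling, predictors, meta)
        for cid, grp in res.groupby(level="cell_id"):
            r = grp["importance_rank"].dropna()
            if len(r):
                assert sorted(r) == list(range(1, len(PREDICTOR_NAMES) + 1))

    def test_sweep_deterministic(self):
        coupling, predictors, meta = generate_driver_benchmark(
            n_lat=3, n_lon=3, n_months=40, seed=2
        )
        a, _ = attribution_sweep(coupling, predictors, meta)
        b, _ = attribution_sweep(coupling, predictors, meta)
        pd.testing.assert_frame_equal(a, b)


def test_collinearity_robustness(small_run):
    """Dropping one vegetation predictor rarely flips the other's slope sign."""
    cfg, data, anom, coupling = small_run
    full, _ = attribution_sweep(coupling, data.predictors, data.meta)
    feats = [f for f in PREDICTOR_NAMES if f != "lai"]
    reduced, _ = attribution_sweep(
        coupling, data.predictors, data.meta, feature_names=feats
    )
    s_full = full.xs("transpiration_over_lai", level="predictor")
    s_red = reduced.xs("transpiration_over_lai", level="predictor")
    keep = (
        s_full["passed_screen"].astype(bool)
        & s_red["passed_screen"].astype(bool)
        & np.isfinite(s_full["theil_sen_slope"])
        & np.isfinite(s_red["theil_sen_slope"])
    )
    flips = (
        np.sign(s_full.loc[keep, "theil_sen_slope"])
        != np.sign(s_red.loc[keep, "theil_sen_slope"])
    ).mean()
    assert flips < 0.10
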
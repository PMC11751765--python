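"""Zone medians, aridity-temperature bins, partial Spearman, BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smvpd import (
    aridity_index,
    benjamini_hochberg,
    bin_means,
    covariate_analysis,
    partial_spearman,
    zone_median,
)
from smvpd.benchmarks import bh_stepup_reference


class TestAridityIndex:
    def test_ratio(self):
        assert aridity_index(800.0, 400.0) == pytest.approx(2.0)
        assert aridity_index(500.0, 500.0) == pytest.approx(1.0)

    def test_zero_precipitation_flagged(self):
        assert np.isnan(aridity_index(800.0, 0.0))


class TestZoneMedian:
    def test_small_zone(self):
        out = zone_median([-3.0, -1.0, 5.0, 2.0], ["a", "a", "a", "b"])
        assert out["a"] == -1.0 and out["b"] == 2.0

    def test_matches_sort_oracle(self, rng):
        s = rng.normal(size=200)
        z = rng.choice(list("abcd"), size=200)
        out = zone_median(s, z)
        for lab in "abcd":
            vals = np.sort(s[z == lab])
            mid = (vals[(len(vals) - 1) // 2] + vals[len(vals) // 2]) / 2
            assert out[lab] == pytest.approx(mid)


class TestBinMeans:
    def test_suppression_boundary(self, rng):
        # one bin with 9 significant cells, one with 10
        sens = np.full(19, -0.5)
        sig = np.ones(19, dtype=bool)
        arid = np.r_[np.full(9, 0.25), np.full(10, 0.75)]
        temp = np.full(19, 10.0)
        out = bin_means(sens, sig, arid, temp, [0.0, 0.5, 1.0], [0.0, 20.0], min_cells=10)
        nine = out[out["aridity_lo"] == 0.0].iloc[0]
        ten = out[out["aridity_lo"] == 0.5].iloc[0]
        assert nine["suppressed"] and np.isnan(nine["mean_sensitivity"])
        assert not ten["suppressed"] and ten["mean_sensitivity"] == pytest.approx(-0.5)

    def test_partition_conserves_cells(self, rng):
        n = 500
        sens = rng.normal(size=n)
        arid = rng.uniform(0, 3, n)
        temp = rng.uniform(-5, 30, n)
        out = bin_means(
            sens, np.ones(n, bool), arid, temp, [0, 1, 2, 3], [-10, 10, 35]
        )
        assert out["n_cells"].sum() + out.attrs["n_overflow"] == n


class TestPartialSpearman:
    def test_constant_controls_reduce_to_spearman(self, rng):
        x = rng.normal(size=60)
        y = x + rng.normal(size=60)
        rho, p = partial_spearman(x, y, controls=np.ones((60, 2)))
        ref_rho, ref_p = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref_rho, abs=1e-12)

    def test_strong_monotone_link(self, rng):
        x = rng.normal(size=50)
        y = np.exp(x)  # strictly increasing
        ctrl = rng.normal(size=(50, 2))
        rho, p = partial_spearman(x, y, controls=ctrl)
        assert rho > 0.9 and p < 1e-6

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=80)
        y = 0.6 * x + rng.normal(size=80)
        ctrl = rng.normal(size=(80, 2))
        rho1, _ = partial_spearman(x, y, controls=ctrl)
        rho2, _ = partial_spearman(np.exp(x), y**3, controls=ctrl)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_matches_rank_residual_oracle(self, rng):
        x = rng.normal(size=40)
        y = 0.4 * x + rng.normal(size=40)
        c1 = 0.3 * x + rng.normal(size=40)
        c2 = rng.normal(size=40)
        rho, _ = partial_spearman(x, y, controls=np.column_stack([c1, c2]))
        # oracle: Pearson of rank residuals computed independently
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        Z = np.column_stack([np.ones(40), stats.rankdata(c1), stats.rankdata(c2)])
        ex = rx - Z @ np.linalg.solve(Z.T @ Z, Z.T @ rx)
        ey = ry - Z @ np.linalg.solve(Z.T @ Z, Z.T @ ry)
        assert rho == pytest.approx(np.corrcoef(ex, ey)[0, 1], abs=1e-10)

    def test_degenerate_inputs(self, rng):
        rho, p = partial_spearman(np.ones(30), rng.normal(size=30))
        assert np.isnan(rho)
        rho, p = partial_spearman([1, 2], [2, 1])
        assert np.isnan(rho)


class TestBenjaminiHochberg:
    def test_worked_example(self):
        reject, adj = benjamini_hochberg([0.01, 0.02, 0.04, 0.8], q=0.05)
        assert list(reject) == [True, True, False, False]

    def test_all_tiny_rejected(self):
        reject, _ = benjamini_hochberg(np.full(20, 0.001))
        assert reject.all()

    def test_adjusted_at_least_raw(self, rng):
        p = rng.random(100)
        _, adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15)

    def test_matches_brute_force_stepup(self, rng):
        for _ in range(200):
            p = rng.random(rng.integers(2, 30))
            rej, _ = benjamini_hochberg(p)
            assert np.array_equal(rej, bh_stepup_reference(p))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])


class TestCovariateAnalysis:
    def _frame(self, rng, n=300, effect=0.0):
        arid = rng.uniform(0, 2, n)
        temp = rng.uniform(0, 20, n)
        sens = -0.5 + 0.1 * rng.normal(size=n)
        cov = pd.DataFrame(
            {
                "biodiversity": effect * sens * 10 + rng.normal(size=n),
                "rootzone_storage": rng.normal(size=n),
            }
        )
        return sens, cov, arid, temp

    def test_small_bins_disregarded(self, rng):
        sens, cov, arid, temp = self._frame(rng, n=19)
        out = covariate_analysis(
            sens, np.ones(19, bool), cov, arid, temp, [0, 2], [0, 20], min_cells=20
        )
        assert out["suppressed"].all() and out["partial_rho"].isna().all()

    def test_null_effect_rarely_bh_significant(self, rng):
        hits = []
        for _ in range(20):
            sens, cov, arid, temp = self._frame(rng, n=400, effect=0.0)
            out = covariate_analysis(
                sens, np.ones(400, bool), cov, arid, temp,
                [0, 1, 2], [0, 10, 20],
            )
            hits.append(out["significant_bh"].fillna(False).mean())
        assert np.mean(hits) <= 0.05 + 0.03

    def test_planted_effect_recovered(self, rng):
        sens, cov, arid, temp = self._frame(rng, n=400, effect=1.0)
        out = covariate_analysis(
            sens, np.ones(400, bool), cov, arid, temp, [0, 1, 2], [0, 10, 20]
        )
        bio = out[out["covariate"] == "biodiversity"]
        assert (bio["partial_rho"] > 0).all()
        assert bio["significant_bh"].all()
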
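# smvpd

Vegetation modulation of soil-moisture → VPD coupling: a tested pipeline for
quantifying how vegetation structure (leaf area index) and physiology
(normalized transpiration, Tr/LAI) shape the propagation of soil dryness into
atmospheric dryness.

## The problem

When soils dry out, evaporation drops and the vapor pressure deficit (VPD) of
the near-surface air rises in the following days — a land–atmosphere feedback
that intensifies droughts.  Vegetation sits in the middle of this pathway:
canopy density controls how much latent heat a unit of soil water can supply,
and stomatal regulation controls how readily plants pass soil water to the
atmosphere.  This package implements, for gridded daily data, the full chain
needed to quantify that modulation:

1. **Anomalies** — remove the per-calendar-month climatology and a LOWESS
   trend (neighbourhood fraction 0.4) from daily SM and VPD.
2. **Coupling** — the partial correlation
   `rho(SM_{t-lag}, VPD_t | VPD_{t-lag})`
   in a 30-day moving window (lag 7 d; 1 and 14 d supported), aggregated to
   months and filtered to growing-season (monthly T ≥ 5 °C), dry
   (negative monthly SM anomaly) months with < 20% missing days.
3. **Attribution** — per grid cell, a random forest (100 trees,
   max_features 0.3, bootstrap, random_state 42) predicts monthly coupling
   from seven absolute-valued predictors (LAI, Tr/LAI, precipitation,
   temperature, VPD, surface SM, wind), pooling the 3×3 neighbourhood;
   cells with < 20 samples or out-of-bag R² < 0.2 are screened out.  Exact
   tree-SHAP values (implemented in-package, numba-compiled) decompose the
   predictions; predictors are ranked by mean |SHAP|, and the **sensitivity**
   of coupling to each predictor is the Theil–Sen slope of SHAP vs predictor
   (two-sided Kendall-tau test, p < 0.01).
4. **Spatial summaries** — median sensitivity per climate zone, mean per
   aridity × temperature bin (suppressed below 10 significant cells), and
   partial Spearman correlations of sensitivity against biodiversity and
   root-zone water storage within bins (≥ 20 cells), controlling for aridity
   and temperature, with Benjamini–Hochberg FDR across all bins and both
   covariates.

Because the pipeline is data-agnostic (NetCDF cubes + CSV tables in, the
variable names are mapped in the run configuration), the same code runs on
reanalysis, satellite or Earth-system-model output.  The package ships a
**synthetic generator** whose daily fields carry a prescribed coupling
coefficient `beta_cell(t) = b0 + b_lai·LAI + b_phys·(Tr/LAI)`, so every stage
can be validated against known ground truth; see `docs/methods.md` for the
generative model and all numerical choices.

## Worked example

```python
from smvpd import RunConfig, SyntheticConfig, run_pipeline

cfg = RunConfig(seed=7)
cfg.synthetic = SyntheticConfig(n_lat=6, n_lon=6, n_years=8, seed=7)
res = run_pipeline(cfg, write=False)

ret = res.coupling[res.coupling["retained"].astype(bool)]
print(f"mean coupling (retained): {ret['pcor_monthly'].mean():.3f}")
print(f"cells passing screens: {res.report['n_passed']}/{res.report['n_cells']}")
print(res.zone_medians.round(4))
```

prints

```
mean coupling (retained): -0.334
cells passing screens: 21/34
              lai  transpiration_over_lai
arid      -0.1321                 -0.3825
cold      -0.0873                 -0.2263
temperate -0.0718                 -0.1212
warm      -0.0305                 -0.0761
```

Read: the retained (growing-season, dry-anomaly) months show a mean coupling
of −0.33, i.e. drier-than-usual soils are followed a week later by higher
VPD.  21 of the 34 study-area cells carry enough signal to pass both screens,
and in every one of them the Theil–Sen sensitivity to LAI is significantly
negative — denser canopies strengthen the negative coupling, exactly the
structure the generator planted (`b_lai = −3.0`, `b_phys = −4.5`).  The
sensitivities are in coupling units per predictor unit (per m²/m² for LAI).

A CLI wraps the same pipeline:

```bash
smvpd simulate --seed 7 --output-dir out/sim
smvpd run-all  --seed 7 --lag 7 --output-dir out/run
```

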
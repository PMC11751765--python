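# Methods

## The statistic

Land–atmosphere coupling is measured here as the partial correlation between
soil-moisture (SM) anomalies and later vapor-pressure-deficit (VPD) anomalies,

```
rho(SM_{t-lag}, VPD_t | VPD_{t-lag})
  = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)),
```

with x = SM(t − lag), y = VPD(t), z = VPD(t − lag), computed from Pearson
correlations over all days t in a 30-day window centred on each focal day.
Controlling for VPD at t − lag absorbs VPD's own persistence, so the statistic
isolates the soil-dryness → atmospheric-dryness pathway; strongly negative
values mean soil drought propagating to the atmosphere.  The lag is 7 days by
default (1 and 14 supported); the window is centred with offsets −15…+14 days,
truncated at series edges, and a window needs at least 24 complete triples
(80% of 30, mirroring the monthly missing-data rule) to be defined.  This
per-window minimum and the exact centring are implementation choices; both are
configurable.

Daily values are averaged to calendar months and a month is retained only if

* fewer than 20% of its daily values are missing,
* its mean temperature is not below 5 °C (growing season; a month at exactly
  5 °C is kept, since the exclusion rule is strictly "below"), and
* its mean SM anomaly is negative (dry conditions, when the feedback matters).

An optional, off-by-default filter additionally drops months with
non-negative coupling.  The monthly SM anomaly used by the dry filter is the
monthly mean of the daily SM anomaly series — the most direct aggregation,
chosen because nothing forces any other.

## Anomaly construction

Anomalies remove (i) the per-calendar-month climatology and (ii) a LOWESS
trend (tricube local linear regression, neighbourhood fraction 0.4 of the
series length, robustness iterations 0, evaluated on the day axis).  The
climatology is removed first so the annual cycle cannot leak into the local
trend fit; the alternative order is exposed as a switch (`anomaly_order`).  A
final re-centering pass subtracts the residual per-month means, making the
monthly-mean-zero property exact while leaving the trend property intact.
Missing days are excluded from all fits; the trend at missing days is linearly
interpolated from neighbouring fitted values.  For multi-thousand-day series
the pipeline uses LOWESS's standard interpolation shortcut
(`lowess_delta_frac = 0.01` of the time range, error ≪ 0.1% of the noise SD);
the library default is the exact fit.

Two numerical consequences worth knowing: sub-monthly structure of a
deterministic seasonal cycle survives monthly-climatology removal (only the
monthly means are removed), and re-applying the anomaly transform removes a
further ~n^(-1/2) sliver of noise via the second LOWESS pass, so exact
idempotence is approached only for long records.

## Per-cell driver attribution

Retained monthly coupling values are explained by seven monthly predictors in
absolute values (not anomalies): LAI, normalized transpiration
(transpiration/LAI, a large-scale canopy-conductance proxy), precipitation,
temperature, VPD, surface SM, and wind speed.  For each unmasked cell a
random-forest regression is trained on the cell and its up-to-8 existing,
unmasked neighbours (3×3 pooling; grid edges simply have fewer neighbours).
Hyperparameters are fixed: 100 trees, max_features 0.3, bootstrap sampling,
random state 42; everything else is the scikit-learn default.  Skill is the
out-of-bag R² (1 − SSE/SST on out-of-bag predictions).  Cells with fewer than
20 pooled samples or out-of-bag R² below 0.2 are screened out; a constant
target leaves the skill undefined and screens the cell out.

SHAP contributions are computed with an exact path-dependent tree-Shapley
algorithm implemented in this package (numba-compiled), evaluated on the full
pooled training table.  Additivity (base value + contributions = prediction)
holds to ~1e-12 per row and the implementation is tested against a brute-force
subset-enumeration Shapley oracle.  Predictors are ranked per cell by mean
absolute contribution (ties — measure-zero on continuous data — break by
predictor name); ranks are not comparable across cells because each cell has
its own model.

The sensitivity of the coupling to a predictor is the Theil–Sen slope (median
of pairwise slopes; pairs with equal predictor values skipped) of that
predictor's SHAP contributions against its values, in coupling units per
predictor unit.  Significance is the two-sided Kendall-tau monotone
association test at p < 0.01; the slope estimator itself supplies no standard
p-value, and Kendall's tau is the conventional companion test.

## Spatial summaries

Sensitivities are summarised as medians per climate-zone label, as means over
aridity × temperature bins (aridity = net radiation in water-equivalent mm
divided by precipitation), and through partial Spearman correlations between
ecosystem covariates (biodiversity, root-zone water storage capacity) and
sensitivity within each bin, controlling for aridity and temperature.  Bin
means are taken over cells with significant slopes and suppressed below 10
such cells; correlation bins are disregarded entirely below 20 cells.  The
two cut-offs intentionally count different things (significant cells vs all
cells), following the different summary rules they implement.  Default bin
edges (aridity {0, 0.5, 0.8, 1.2, 2, 5, ∞}; temperature every ~5 °C) are
config-exposed.  Partial Spearman rank-transforms all series and correlates
the rank residuals after regressing out the ranked controls, with a
t-distributed p-value on n − 2 − k degrees of freedom; constant controls are
dropped, reducing to ordinary Spearman.  Benjamini–Hochberg adjustment runs
jointly across all populated bins and both covariates for a given sensitivity
type (separate families per sensitivity type); raw (p < 0.05) and BH-robust
flags are both reported.

## Synthetic data: what it emulates, and what it does not

The generator produces gridded daily SM, VPD and temperature plus monthly
predictors with a known, recoverable coupling structure:

* Daily SM = seasonal cycle + AR(1) anomalies (lag-1 autocorrelation
  `sm_ar1 = 0.85`, innovation SD 0.008 m³/m³ → stationary anomaly SD ≈ 0.015).
* Daily temperature = latitude-dependent mean (2–18 °C) + 10 °C seasonal
  amplitude + AR(1) anomalies.
* Monthly LAI follows a temperature-driven growth curve scaled by an
  aridity-dependent maximum, with multiplicative AR noise (CV 0.12).
* Monthly transpiration is conductance-like:
  `1.2 · LAI^0.9 · f(SM) · VPD_clim^0.5 · noise`, positive wherever LAI is
  positive; the SM stress factor ramps between 0.08 and 0.25 m³/m³.  The
  exponents were chosen so LAI and transpiration/LAI are only moderately
  collinear (median within-cell |r| ≈ 0.2), as in real data where structure
  and physiology decouple through stress and demand.
* Daily VPD = seasonal demand curve + 0.03 kPa/°C × temperature anomaly
  + `beta_cell(t)` × SM anomaly(t − 7 d) + white noise (SD 0.15 kPa), with

  `beta_cell(t) = b0 + b_lai · LAI(t) + b_phys · (Tr/LAI)(t)`.

  `beta` carries the correlation sign: negative values give the physically
  typical negative coupling, and negative `b_lai` / `b_phys` strengthen it as
  vegetation activity rises.  Defaults `b0 = +2.5`, `b_lai = −3.0`,
  `b_phys = −4.5` (kPa per unit SM anomaly) put the retained-month coupling
  near −0.35 with a seasonal swing large enough that the out-of-bag-R² screen
  is attainable: the sampling noise of a 30-day windowed correlation bounds
  any model's achievable R², so the vegetation modulation must move the true
  coupling by a comparable amount, as it does in the strongly
  vegetation-modulated regions the method targets.
* Daily VPD anomalies are noise-dominated (fast atmospheric decorrelation).
  This matters for null calibration: sampling variance of a windowed
  correlation inflates with the product of the two series' autocorrelations,
  and the partial-correlation control removes the VPD persistence term, so
  the null window-level spread stays near the independent-sample value
  1/sqrt(n − 3).
* Ancillary per-cell fields: climate-zone labels from the temperature and
  aridity gradients, vegetation and irrigation fractions (cells with cover
  ≤ 5% or irrigation ≥ 10% are masked out of the study area), net radiation
  consistent with the prescribed aridity, and biodiversity / root-zone
  storage covariates with configurable monotone links to the cells' true
  physiology and structure coefficients plus climate confounding.

The generator makes no attempt to emulate real remote-sensing spectra of
variability, cloud-gap patterns, actual climate-zone geography, advection, or
spatially correlated weather; cells are statistically independent given the
smooth parameter gradients.  Passing recovery tests therefore demonstrates
that the pipeline's inference chain is correct and well-calibrated under its
own assumptions — not that those assumptions hold for any particular
observational product.

## Validation experiments and problem sizes

`smvpd.benchmarks` holds the recovery experiments run by both
`tests/test_acceptance.py` and `scripts/acceptance.py`: formula-level oracle
checks (partial correlation vs regression residuals; Theil–Sen vs pairwise
enumeration; BH vs the textbook step-up), a 200-cell/10-year null
calibration, the 15×15-cell/12-year sign-recovery run, a 100-replicate
dominant-driver ranking benchmark (isolated cells, 60-month records, one
predictor's weight 3× the others), a constructed 24-month filter-rule
scenario, and a byte-level determinism check of two identical 6×6 pipeline
runs.  These sizes keep a complete validation run in the tens of minutes on
one core while leaving each recovered quantity comfortably away from its
decision threshold.  One statistical subtlety: under a complete null BH's
expected false-discovery proportion equals q exactly, so the measured mean
over 200 replicates is compared within two Monte-Carlo standard errors.

## Reproducibility

One data seed governs all synthetic generation; the forests always use the
fixed model random state 42, so data and model randomness never interact.
Outputs embed a hash of the scientific configuration (artifact paths
excluded) and the seed, and contain no wall-clock metadata; identical
configurations reproduce every artifact byte for byte.

## Known limitations

* Monthly-climatology deseasonalisation leaves sub-monthly seasonal
  structure; harmonic or spline alternatives are out of scope.
* No spatial autocorrelation correction in the bin tests, and no remote
  (upwind) coupling — both outside the method's scope.
* The attribution is associational; nothing here identifies causal effects.
* NetCDF output uses the NetCDF-3 (scipy) backend.
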
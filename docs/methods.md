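# Methods

This note documents the models implemented in `isomigrate`, the
parameters and their defaults, the synthetic generator used for
validation, and the numerical choices that matter for reproducing the
results.

## 1. Isoscape regression (`isomigrate.isoscape`)

The precipitation deuterium surface δ²Hp is modelled per grid cell as

    δ²Hp = β₀ + β₁·T + β₂·E + β₃·φ + β₄·λ + ε,   ε ~ N(0, σ²)

with T mean temperature (°C), E elevation (m), φ latitude (°N) and λ
longitude (°E), fit by ordinary least squares over all valid
(optionally range-masked) cells.  Prediction uncertainty is the
design-based standard error of the regression mean,

    se(x) = σ̂ · sqrt(xᵀ (XᵀX)⁻¹ x),

computed per cell from the stored unscaled covariance factor (XᵀX)⁻¹.
A rank-deficient design raises an error naming the collinear
covariates.  A saturated fit (cells = parameters) is defined to have
R² = 1 and zero residual SD (the residual dof is floored at 1).
Residual-SD units are ‰ throughout.

## 2. Feather calibration (`isomigrate.calibration`)

Feather and precipitation δ²H differ by tissue fractionation, so the
precipitation surface is rescaled into feather units using calibration
populations of known origin — by default 10 sites totalling 186 birds.
Uncertainty in both variables is propagated by a parametric bootstrap
with `n_boot = 1000` replicates.  Each replicate draws, per site,

    feather* ~ N(feather_mean, feather_sd)
    env*     ~ N(env_d2h, env_sd)          (env_sd = isoscape prediction SE)

and fits the simple regression `feather* = a + b·env*` in closed form.
The model stores the empirical means and SDs of `a` and `b` over
replicates plus the mean residual SD.  The rescaled surface is

    μ_f(cell)  = a̅ + b̅ · δ²Hp(cell)
    σ_f(cell)² = sd(a)² + (sd(b)·|δ²Hp|)² + resid_sd² + (b̅·se_p(cell))²

i.e. intercept, slope, residual and isoscape-prediction uncertainty
added in quadrature.  Fewer than 3 sites, or sites with identical
environmental values, are rejected; single-bird sites (SD 0) are
allowed with a warning.

## 3. Likelihood assignment (`isomigrate.assignment`)

For a bird with feather value y, each cell inside the species range
mask gets the normal density `f(y | μ_f, σ_f)`.  The computation is
done in log space with max-subtraction before exponentiating, so
surfaces remain well defined when every density underflows.  The
surface is normalised to unit mass over the masked support (checked to
1e-9); cells outside the range carry the nodata sentinel.

The natal **centroid** retains the top `top_fraction = 0.10` of valid
cells by probability (count = ceil(0.10·n)), resamples
`n_resample = 100` cells from that set (without replacement when
enough cells are retained, with replacement otherwise), and takes the
probability-weighted mean of the resampled cell centres.  Per-bird
random streams derive from a master seed and a CRC-32 of the bird id,
so cohort results do not depend on processing order.

## 4. Morphometrics (`isomigrate.morphometrics`)

Fat-free body mass is a sex-specific linear function of wing chord,
`ffm = a_sex + b_sex·chord` (defaults: females a = 0.3 g,
b = 0.062 g/mm; males a = 0.5 g, b = 0.055 g/mm).  Fuel load is
`mass − ffm` (g); negative values are logged, not clamped.  Chords
outside 30–60 mm warn but still compute.

## 5. Temporal model (`isomigrate.temporal`)

Candidate predictors (arrival ordinal day, fat-free mass, fuel load)
are first screened by pairwise Spearman correlation; |ρ| > 0.7 warns.
Estimated natal latitude is then modelled as

    lat_i = f₁(day_i) + f₂(ffm_i) + f₃(fuel_i) + u_year(i) + e_i

an additive mixed model with a Gaussian year random intercept.  The
smooths are B-spline bases (`patsy` `bs`, df = 5) fit as fixed effects
in `statsmodels` MixedLM by REML.  This is a fixed-basis additive
model rather than a penalised GAM: with n = 150 and df = 5 per term
the unpenalised basis is well conditioned, and a one-test cross-check
against R's `mgcv::gam` (run when R is present) confirms both reach
the same arrival-day conclusion.  Each term is tested with a Wald test
on its coefficient block, converted to F = χ²/k with k and residual
dof; the term's direction is the sign of a least-squares line through
its fitted partial effect.  A near-singular REML profile (year
variance ≈ 0) is handled by an optimizer cascade (lbfgs → powell →
Nelder–Mead) and, failing that, a basis-df-3 retry.  With fewer than
20 complete cases or fewer than 2 years the model falls back to fixed
effects only.

Classification at α = 0.05: arrival-day effect significant and
positive → `type_1` (southern populations pass first); significant and
negative → `type_2`; otherwise `indeterminate`.

## 6. Synthetic world generator (`isomigrate.synthetic`)

The generator emulates the study conditions end to end with known
truth.  Defaults (all overridable via frozen config dataclasses):

- **Domain**: 25–55 °N, 95–75 °W at 0.5° resolution (60 × 40 cells).
- **Covariates**: temperature = 38 − 0.6·lat + smooth noise; elevation
  = smoothed positive Gaussian field; latitude/longitude grids.
- **Precipitation**: δ²Hp = −14 + 0.4·T − 0.015·E − 1.5·φ − 0.2·λ +
  N(0, 3²) ‰.  Because temperature itself declines with latitude, the
  *effective* latitudinal gradient is ≈ −1.8 ‰/°, matching the strong
  north–south signal the method relies on.
- **Tissue model**: δ²Hf = −25 + 1.0·δ²Hp with 2 ‰ within-site SD.
- **Calibration design**: 10 sites stratified by latitude band, 186
  birds allocated as evenly as possible.
- **Cohort**: 3 years (2010, 2011, 2014) × 2 sexes × 25 birds = 150
  migrants with uniform natal cells.  Arrival day = 192 + 2·natal_lat
  + N(0, 5) d, redrawn up to 100 times into the stopover season window
  (ordinal days 237–305), then clamped — a type 1 world by default.
- **Morphometry**: sex-specific chord means (F 47 mm, M 40 mm),
  fat-free mass from the coefficients above, fuel ~ Gamma(2, 0.35) g.

What it does **not** emulate: spatial autocorrelation of individual
feather errors, band-recovery or observation error in arrival dates,
within-season moult variation, and non-Gaussian isoscape residuals.

All randomness flows from a single seed through `numpy`
`SeedSequence` streams (world / sites / migrants), so identical
configs reproduce byte-identical outputs.

## 7. Rasters and I/O (`isomigrate.raster`)

Grids use outer-corner origin with cell-centre semantics and negative
latitude cell size (rows run north → south); nodata is −9999.  Two
text-friendly formats are supported: ESRI ASCII grid (values written
with `repr`, so round-trips are bit exact) and single-band GeoTIFF via
`tifffile` with the ModelPixelScale / ModelTiepoint / GDAL-nodata
tags.

## 8. Pipeline (`isomigrate.pipeline`, CLI `isomigrate`)

`run_pipeline(RunConfig)` chains simulate (or load) → isoscape →
calibrate → morphometrics → assign → temporal, with per-stage seeds
derived as `SeedSequence((master, stage_index))` (all < 2³¹), SHA-256
input checksums and per-stage timings recorded in `manifest.json`.  A
`.partial` marker flags interrupted runs.  Configs load from TOML with
unknown-field rejection.

## 9. Problem sizes and runtime

A full default run (2400-cell grid, 1000 bootstraps, 150 birds) takes
≈ 0.2 s.  The validation suite (144 tests) runs in ≈ 30 s; the
`scripts/acceptance.py` report, including 50 end-to-end replicates,
in ≈ 10 s.

## 10. Limitations

- The assignment likelihood treats cells independently; no spatial
  prior or movement model is applied.
- Centroids summarise multimodal surfaces poorly; the full surface can
  be written with `write_surfaces = true`.
- The additive model tests the arrival-day *effect direction* via a
  linear summary of the smooth; strongly non-monotone effects of equal
  rise and fall would be called flat.
- The bootstrap calibration assumes site feather means are normal;
  very small sites make that approximation rough.
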
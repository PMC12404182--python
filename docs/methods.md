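# Methods

`lakescape` implements a landscape-scale climate-vulnerability analysis for
mountain lake watersheds: heat accumulation from monthly air temperatures,
per-watershed velocity of thermal change from mixed models, and a
three-tier vulnerability classification projected onto future climatology
periods. Because the real inputs (hydrography point layers joined to
downscaled monthly climate rasters) are not bundled, a synthetic landscape
generator with known ground truth drives all tests and the demo pipeline;
real extracts can be supplied through the same CSV schemas.

## Degree days from monthly means

Degree days accumulate the excess of mean temperature over a threshold,

    DD = sum_t (T_t - T0)  for  T_t > T0.

With monthly-resolution input, each day of a month is assigned that month's
mean, so month *m* of year *y* contributes `n_days(y, m) * max(0, T_m - T0)`
and the annual value is the sum over the 12 months. Negative contributions
are truncated to zero per month (no heat accrued), not after annual
summation. GDD uses a fixed base `T0 = 0 °C`, a parsimonious growth
threshold for coldwater taxa. KDD uses a region-specific supraoptimal
threshold: the 90th percentile of the region's pooled (watershed, year,
month) monthly means over the historical window. Watershed-years with
GDD = 0 or KDD = 0 are retained; incomplete years are dropped with a
warning rather than imputed.

Numerical conventions, fixed because thresholds are sensitive to them:

- **Quantile**: linear interpolation of order statistics (position
  `h = (n-1)q + 1`), the numpy default; values 1..10 at q = 0.9 give 9.1.
- **Quantile pool**: all monthly means of a region, unweighted. Pooling
  day-expanded values would give identical thresholds, since expansion
  replicates each monthly mean.
- **Calendar**: Gregorian with leap years for historical years; fixed
  365-day month lengths for climatology periods, which have no specific
  year.

## Velocity of change

Per region, annual GDD is `ln(x+1)`-transformed (annual mean temperature
uses `log(x+10)` to shift values positive) and modelled as

    y_it = (beta0 + b0_i) + (beta1 + b1_i) * year_t + e_it,

with watershed-level random intercepts and slopes, an unstructured 2×2
random-effect covariance, and REML estimation (statsmodels `MixedLM`;
optimizers tried in the order bfgs, lbfgs, powell, keeping the converged
fit with the highest REML objective — bfgs reproduces an independent
direct maximization of the REML objective to ~1e-6 on balanced panels,
while lbfgs alone can under-converge). The year covariate is centered at
its sample mean for conditioning; slopes are per calendar year either way.
Boundary fits (a variance component at numerical zero) are flagged, not
rejected: degenerate inputs such as exactly linear series legitimately
produce them.

A watershed's **velocity** is its total slope, fixed effect plus BLUP
deviation, on the transformed scale per year. BLUP deviations alone are
mean-zero by construction and are kept behind `mode="deviation"`; the
strictly signed per-range velocity distributions only make sense for total
slopes, which is therefore the default.

Fit quality is summarized by marginal/conditional pseudo-R² in place of
random-effect p-values: marginal = Var(fixed predictions) / total,
conditional adds the design-averaged random-effect variance
`Var(b0) + Var(b1) * mean(year_c²)` (the intercept–slope covariance term
vanishes under mean-centering), and total additionally includes residual
σ². Landscape summaries are the Pearson correlation of velocity against
elevation (two-sided t test) and a one-way fixed-effects ANOVA of velocity
across regions.

## Vulnerability tiers and projection

Per region, mean historical GDD per watershed is `ln(x+1)`-transformed and
clustered by 1-D k-means constrained a priori to k = 3 (Lloyd's algorithm,
best of 25 random seeded initializations by within-cluster sum of squares;
deterministic given data, seed and restart count). Clusters are labelled
cold / transitional / hot by ascending center; center ties (possible only
on degenerate data) break by data order and are flagged. On 1-D data the
optimal k-means partition is contiguous in sorted order, so the test suite
checks Lloyd's solutions against exhaustive search over all contiguous
3-partitions.

A linear discriminant on the single standardized feature (class means,
pooled within-class variance, empirical priors — scikit-learn
`LinearDiscriminantAnalysis`) is then fitted to the k-means labels.
Projected period GDD is `ln(x+1)`-transformed and standardized **with the
historical scaler** before scoring: re-standardizing within each future
period would erase exactly the warming signal being classified. Posterior
probabilities are normalized class likelihood × prior; the reported
accuracy is resubstitution (training) accuracy, with no cross-validation
in the main pipeline. With ordered class means on one feature the decision
regions are intervals, so predicted tier is monotone non-decreasing in
projected GDD — asserted on a grid in the tests.

Models are fitted per region; the pooled "all" row of the membership table
pools watershed counts, never region percentages, and percent changes are
computed on unrounded percentages (whole-percent rounding is display
only).

## The synthetic landscape generator

Monthly mean temperature of watershed *w* (elevation `E` km) in year *y*,
month *m*:

    T = baseline - lapse * E
        + amplitude * cos(2*pi*(m - peak_month)/12)
        + slope_w * (y - first_year) + eps,    eps ~ N(0, noise_sd²)
    slope_w = trend_base + coupling * E.

Period climatologies are the noise-free structural mean at the period's
midpoint year plus a stepwise warming offset — projected climatologies
lack interannual variance, so no noise is added. Period midpoints resolve
from an explicit map, else from "YYYY-YYYY" labels, else fall back to the
historical midpoint (only relevant when the trend is nonzero).

Defaults (the demo study conditions, chosen once):

| parameter | default | unit | rationale |
|---|---|---|---|
| regions × watersheds | 2 × 50 | — | smallest landscape exercising per-region models and pooled tables |
| elevation range | 200–1800 | m | temperate mountain range; see sign analysis below |
| years | 1980–2019 | — | 40-year historical window |
| baseline | 14 | °C at 0 m | warm-temperate reference |
| lapse rate | 6.5 | °C/km | standard environmental lapse |
| seasonal amplitude / peak | 10 / July | °C / month | mid-latitude cycle |
| trend base | 0.03 | °C/yr | recent-decades warming magnitude |
| elevation coupling | −0.015 | °C/yr/km | low elevations warm fastest |
| noise | 0.5 | °C | monthly interannual scatter |
| period offsets | +1, +2, +3 | °C | stepwise "business as usual" warming for 2011–2040 / 2041–2070 / 2071–2100 |

**Why a temperate (not alpine) default.** The generator's contract is that
low-elevation watersheds have the highest velocity *on the transformed
scale*. Writing M(E) for annual mean temperature, the transformed-scale
velocity is approximately `slope_w / M` when all months clear the GDD
base; it decreases with elevation iff `|coupling| * baseline >
lapse * trend_base`, and warming must stay positive at the top
(`trend_base > |coupling| * E_max`). Together these force M to remain
positive at the top elevation. A high-alpine parameterization (elevations
to 3500 m) instead *inverts* the correlation: GDD collapses toward zero at
cold sites and the `1/GDD` amplification dominates the smaller absolute
warming. The defaults above satisfy both constraints with ~1 °C to spare.

What the generator does **not** emulate: spatial autocorrelation among
watersheds, region-to-region structural differences (the two demo regions
are statistically exchangeable, so the cross-range ANOVA F is small by
construction — on real landscapes ranges differ strongly), realistic
emissions-scenario forcing curves, snow/ice processes, and any
air-to-water temperature conversion. Passing tests therefore demonstrate
that the estimators recover planted structure under the model's own
assumptions, not that real landscapes satisfy those assumptions.

## Problem sizes and runtime

The demo pipeline (2 × 50 watersheds × 40 years, 3 periods) runs in a few
seconds on one core. The REML cross-check uses a balanced 20-watershed ×
40-year panel; velocity recovery uses 50 × 40 at 0.5 °C noise; k-means
optimality is checked on 200 instances of n ≤ 12 (where exhaustive search
is exact); tier recovery uses three elevation bands of 20 watersheds each,
separated by ≥ 4 within-band standard deviations of mean GDD.

## Known limitations

- The mixed model assumes independent Gaussian residuals; no temporal
  autocorrelation or heteroscedasticity (ln-scale residual variance grows
  sharply as GDD → 0).
- Velocities from the GDD and temperature responses agree in rank, not in
  units; slopes depend on the logarithm base (a constant rescaling,
  configurable; natural log is the default).
- Cluster count is fixed at three by design; no model-selection
  diagnostics are offered.
- Resubstitution accuracy is optimistic by construction; a cross-validated
  option exists at the library level but is not part of the pipeline.
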
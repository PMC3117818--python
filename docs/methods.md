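# Methods

## Model

For an outcome `y` (a continuous metabolic-syndrome component in its own
units) measured on individuals at two examination waves, the linear model is

```
y = b0 + b1·Age + b2·Period + b3·Cohort + e
```

with `Age` the age at examination (years), `Cohort` the birth year and
`Period` the examination wave. Since exam year = age + birth year exactly,
the centred design `X` has rank 2 and `X'X` is singular: `b` is identified
only up to translations along the null direction. Any procedure that returns
a single estimate therefore imposes a constraint; this package's point is
that PLS1 imposes a *transparent* one — the estimate lies in the row space
of `X`, hence is orthogonal to the null direction.

### PLS1 core

NIPALS for a univariate outcome, on the column-centred (optionally
unit-variance-scaled) design:

1. `w_h = X'_{h-1} y / ‖X'_{h-1} y‖` (unit-norm weights),
2. `t_h = X_{h-1} w_h` (scores; mutually orthogonal),
3. `p_h = X'_{h-1} t_h / t'_h t_h`, `q_h = y' t_h / t'_h t_h`,
4. deflation `X_h = X_{h-1} − t_h p'_h`.

Only `X` is deflated: deflating `y` as well changes nothing for a univariate
outcome (verified against scikit-learn's `PLSRegression`, which deflates
both, to 1e−15). Coefficients at `h` retained components are
`B(h) = W (P'W)⁻¹ q`, computed by inverting the upper-triangular `P'W`
(at most 9×9 here), then divided by the column scale factors and completed
with an intercept from the centering metadata. `h = rank(X)` reproduces the
minimum-norm least-squares solution; on full-rank designs `h = p` reproduces
OLS (both are test oracles).

Numerical rank treats singular values below `max(n, p)·ε·σ₁` as zero;
requests beyond it are truncated with a warning, and extraction stops early
if the deflated `X'y` is numerically zero (below `1e−12` of its initial
norm).

### The identification constraint

With all covariates centred and in year units the null direction is
`(1, −1, 1)`, so every PLS coefficient vector satisfies
`b_age + b_cohort = b_period`. When columns are scaled to unit variance the
constraint picks up the variances:
`s²_age·b_age + s²_cohort·b_cohort = s²_period·b_period` for the
back-transformed coefficients. Scaling is recommended (and is the pipeline
default) because unscaled PLS penalises the period column, whose variance is
tiny relative to age and birth year.

**Period coding.** The reporting convention codes the two waves 0/1, so the
period coefficient is the full later-vs-earlier contrast (the layout used in
the coefficient tables). Under that coding the wave gap Δ (10 years here)
enters the constraint: `b_age + b_cohort = Δ·b_period`. The design builder's
`period_units="years"` option instead codes period as exam year minus the
first wave, restoring the exact year-unit identity and the clean
`b_age + b_cohort = b_period` form. Both are tested; they are the same model
expressed in different units.

## Design construction

- Age is centred on 20 years and birth year on 1937 (the youngest age and
  earliest birth year in the emulated two-wave setup), which stabilises the
  iteration without changing slopes.
- Restricted cubic splines for age and birth year use five knots at the
  0.05 / 0.275 / 0.5 / 0.725 / 0.95 within-variable percentiles. Quantiles
  use the linear-interpolation (type 7) convention; the paper-style knot
  lists are data-dependent configuration, not constants. The basis is the
  truncated-power form with the tail restriction and normalisation by the
  squared boundary-knot span, so a k-knot spline contributes k−1 columns
  (1 linear + k−2 nonlinear) and the fitted function is linear beyond the
  boundary knots (asserted at machine precision). Splines are computed on
  the centred variables ("centre first"); centring before vs after affects
  only the linear column's offset.
- In spline mode no column is dropped: collinearity is local to the linear
  terms and PLS resolves it; the 9-column design has rank 8.
- Unit-variance scaling can live either in the design builder (factors
  recorded in the column metadata, useful for design dumps) or in the
  estimator (`PLS1Regression(scale=True)`). The pipeline and all resampling
  use the estimator path so that every cross-validation or jackknife refit
  re-estimates centering and scaling on its own training rows — no
  information leaks from held-out observations (tested against brute-force
  refit loops).

## Confounder adjustment

Stage one regresses the outcome on education years plus ordinal smoking /
alcohol / betel-quid categories (indicators, lowest level as reference)
within each sex × exam-year stratum, by OLS. The adjusted value is the
stratum mean plus the residual: residuals are exactly orthogonal to the
confounders and stratum means are preserved, so period contrasts remain in
outcome units. A `grand` anchoring flag re-centres all strata on the overall
mean instead. Records with missing modelled fields are dropped and counted.
Adjustment is idempotent.

## Component selection and uncertainty

**PRESS.** For each candidate component count `h = 0..H`, each held-out fold
is predicted from a model refit on the remaining rows;
`PRESS(h) = Σ (y_i − ŷ_{−i})²`. Leave-one-out is used up to n = 2000 and 20
seeded random groups beyond (fidelity at test scale, tractability at cohort
scale). The selected `h` is the global minimiser, ties (within 1e−10
relative) going to the smaller count. The pipeline nevertheless always
reports one- *and* two-component fits side by side as a robustness check,
since the two-component model captures essentially the full least-squares
fit on the rank-2 linear design.

**Jackknife.** Coefficient standard errors come from delete-one resampling
(delete-group with 30 seeded groups beyond n = 2000), re-running the entire
pipeline — centering, scaling, extraction at a *fixed* component count,
back-transformation — per deletion, combined with the Tukey variance formula
`SE² = (G−1)/G · Σ (θ_(g) − θ̄)²` and normal critical values. The component
count is frozen across refits so the estimand does not drift. The jackknife
target under rank deficiency is the identifiable projection of the
generating coefficients; simulated 95% intervals cover that projection at
roughly nominal rates (the acceptance suite checks 90–98% over 500
replicates at n = 500).

## Synthetic cohorts

`generate_cohort` emulates a two-wave health-screening cohort: waves 1996
and 2006, integer ages 20–59 drawn with decade weights (0.30, 0.35, 0.20,
0.15 — more thirty-somethings than fifty-somethings), birth year = exam year
− age exactly, sex Bernoulli(½). Education rises by 0.15 years per birth
year (younger cohorts more educated) with sd 2.5, clipped to [0, 22];
smoking/alcohol/betel are 4-level ordinals with probabilities (0.55, 0.20,
0.15, 0.10). The default outcome is SBP-like: intercept 115 mmHg, age slope
0.4 mmHg/yr, cohort slope −0.05 mmHg/yr (optionally hinged at a changepoint
year such as 1970), period effect −2 mmHg for the later wave, +5 mmHg for
men, confounder effects (−0.2 per education year; 1.2/0.8/0.6 per ordinal
level), Gaussian noise sd 10 mmHg. All draws come from one seeded generator
in a documented order (ages per wave, sex, education, smoking, alcohol,
betel, noise), so a seed fully determines the table.

What the generator does *not* emulate: real marginal distributions of the
screening cohort, measurement error, within-person correlation across waves,
selection into screening, or interactions among age, period and cohort.
Passing recovery tests therefore demonstrate correctness of the estimation
machinery under the stated data-generating process, not epidemiological
validity on real data.

The worked-example fixture constructs a deliberately rank-one six-row
regression problem whose centred cross-products equal the printed reference
vector exactly (columns proportional to a centred `y` with
`y'y = 0.026·‖X'y‖`), so the one-component fit reproduces the reference
weights, score-regression coefficient and coefficients end to end; it is
synthetic and labelled as such.

## Reported quantities and problem sizes

Trend curves evaluate the fitted spline contribution of age (or birth year)
on the observed integer grid, anchored to zero at the centering reference;
they are point estimates only — no confidence bands are drawn, and the
1- vs 2-component pair is the robustness display. Curves are identified only
up to the constraint, like the coefficients.

Validation problem sizes were chosen to make the checked properties sharp
while remaining quick to run: the constraint identity on 100 cohorts of
n = 2000; interval coverage on 500 replicates of n = 500 with delete-one
jackknifes; changepoint recovery on one cohort of n = 20,000 with the
five-knot spline design, locating the changepoint as the grid point of
maximum absolute second difference of the fitted cohort curve. With
percentile knots the fitted curve can bend only at knots, so localisation is
knot-limited (the nearest knot to a 1970 hinge sits around 1972–73 under the
default age distribution); ±3 years is the supported resolution.

## Known limitations

- Exactly two examination waves; the generic PLS core accepts arbitrary
  designs, but the APC layer mirrors the two-wave setup.
- PLS2 (multiple outcomes), kernel and penalised PLS variants, bootstrap
  intervals and information-criterion selection are out of scope.
- Jackknife intervals assume approximate normality of the coefficient
  estimates; no distributional result is claimed for the trend curves.
- Whether reported coefficients should be on the original or standardised
  covariate scale is a reporting choice; this package reports original-scale
  coefficients (per year, per wave contrast) throughout.
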
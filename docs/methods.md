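# Methods

This note records the models implemented in `esvgrey`, the parameter and
design choices that were genuinely open, and what the synthetic-data
machinery does and does not establish.

## Valuation

The valuation is a linear benefit transfer: every category-year cell is
`area (hm²) × per-category coefficient (CNY/hm²/yr)`, with the
per-category coefficient the column sum of a 9-service × 7-category
matrix.  Two modelling commitments worth stating explicitly:

* **Construction land is priced at zero.**  The coefficient matrix
  carries an explicit zero column rather than dropping the category, so
  closure checks always see all seven first-class categories and the
  construction share of the territory is visible in every report.
* **Full precision internally, rounding only at report time.**  Reports
  round values to 2 decimals of billions and rates to 3 decimals of
  percent.  The packaged Guizhou tables, valued this way, give yearly
  totals of 223.64 and 221.50 billion CNY; one printed source cell
  (garden land 2009) rounds to 1.04 where the arithmetic gives 1.035, so
  per-cell comparisons in the tests carry a ±0.01-billion band.

Category names are matched case- and whitespace-insensitively through a
small alias map ("water" = "water area", "cropland" = "cultivated land",
…), so area tables and coefficient tables from different sources can be
combined without manual renaming.

Change accounting between two survey years reports the plain difference
and the signed percent rate `(A₁ − A₀)/A₀ × 100`.  Decade-cumulative
change figures that would require the intervening annual surveys are
deliberately not estimated.

The closure check reports each year's deviation of the category sum from
the territory total; the packaged 2018 survey column sits 1 hm² under the
total (rounding in the printed figures), hence the default tolerance of
1 hm².

## Sensitivity

The coefficient of sensitivity is evaluated **within one calendar year**
as `CS = (|ESV_adj − ESV_base|/ESV_base)/|δ|`.  Because the valuation is
linear in the coefficients, this equals the perturbed category's share of
that year's total: CS is identical for +δ and −δ and for any |δ|, and the
CS values of all value-bearing categories sum to 1.  Both signs are still
evaluated and reported (the conventional table layout), and the δ
magnitude is configurable (default ±0.5).  The per-year reading is the
one under which the packaged study's printed 2009 sensitivity column is
reproduced exactly; a pooled two-year denominator reproduces nothing and
was rejected.

## GM(1,1) grey forecasting

Fitting follows the standard construction: accumulate the series
(x⁽¹⁾ = cumsum x⁽⁰⁾), form mean-generation background values
`z⁽¹⁾(k) = ½(x⁽¹⁾(k)+x⁽¹⁾(k−1))`, and solve the n−1 stacked equations
`x⁽⁰⁾(k) = −a·z⁽¹⁾(k) + u` by least squares via a stable factorization
(`numpy.linalg.lstsq`), never an explicit inverse.  Preconditions: n ≥ 4
and strictly positive data (violations raise, naming the offending
index).

**Response form.**  The package restores and forecasts, by default, with
the exact solution of the fitted *difference* system,

```
x̂⁽¹⁾(k) = (x⁽⁰⁾(1) − u/a)·βᵏ⁻¹ + u/a,   β = (1 − a/2)/(1 + a/2),
```

rather than the classical continuous (whitenization) response
`e^{−a(k−1)}`, which remains available as `response="continuous"`.  The
two differ by O(a²) per step — negligible for land-use series, whose
fitted |a| is well below 0.1 — but the discrete form makes the model
self-consistent: it restores any series generated by its own recursion
(including geometric series) with zero residual, so parameter-recovery
and accuracy tests have exact expectations instead of
tolerance-smudged ones.  This is the "unbiased" GM(1,1) variant of the
grey-systems literature.  The discrete form requires |a| < 2; a fit
outside that region falls back to the continuous response with a
warning.

**Degeneracies.**  When |a| < 1e−12 the limiting linear response
`x̂⁽¹⁾(k) = x⁽⁰⁾(1) + u(k−1)` is used, which handles constant series
exactly (a = 0, u = the constant, constant continuation).

**Accuracy grading.**  Residuals are defined over k = 1..n with
ε(1) = 0 by construction.  S₁ and S₂ are population (divide-by-n)
standard deviations of the data and residuals; C = S₂/S₁; P is the share
of residuals within 0.6745·S₁ of the mean residual.  Grades: 1
(C < 0.35, P ≥ 0.95), 2 (C < 0.50, P ≥ 0.80), 3 (C < 0.65, P ≥ 0.70),
else 4 — the interior thresholds are the standard grey-forecast grading
ladder.  A constant series (S₁ = 0) is graded 1 with C = 0, P = 1 by
convention.

**Closure forecasting.**  In a multi-category forecast every category
but one gets its own GM(1,1); the designated closure category (default
"unused land", configurable) is the territory total minus the rest, so
closure holds exactly by construction.  A negative closure residual is
clamped to zero and the other categories rescaled proportionally, with a
warning and a flag in the result.  Calendar years map to model steps via
the (uniformly spaced) input year axis.

## Grey relational analysis

Series are normalized per analysis window (mean normalization by
default — it treats series of wildly different magnitudes symmetrically
and makes grades invariant to units; initial-value normalization is a
switch).  Deviations from the normalized reference, their global
min/max *within the window*, and the distinguished coefficient ρ
(default 0.5) give the coefficients; grades are unweighted time means;
ranking is by descending grade with ties broken by input order (logged).
Windows are self-contained: sub-period grades re-evaluate normalization
and min/max on the window's data only.  With ρ = 0.5 and an attained
zero minimum deviation, coefficients live in [1/3, 1].

## Synthetic data

The generator emulates the study conditions the analysis assumes: a
decade (2009–2018) of annual observations between the two packaged
survey endpoints under a fixed 17,609,858-hm² territory, and seven
driver series inside their published 2009–2018 ranges.

* **Land use:** geometric (constant-annual-rate) interpolation between
  endpoints — chosen because the grey model's response is exponential,
  so generator and model share a family and recovery tests are
  meaningful; a linear mode exists for robustness checks (zero-endpoint
  categories fall back to linear automatically).  Multiplicative
  lognormal noise with a stated coefficient of variation (default
  cv = 1%) is applied before each year is rescaled proportionally to
  close on the territory exactly.  With cv = 0 the endpoint years equal
  the survey columns exactly.
* **Drivers:** monotone geometric or linear trends spanning the
  published ranges (population, urbanization, GDP, industry proportions,
  investment), except the afforestation programme, which fluctuates
  uniformly within its range as policy-driven series do.
* **Exact grey sequences:** `gm11_exact_series` inverts the model's own
  discrete recursion, so fitting its output recovers (a, u) to machine
  precision — the backbone of the exactness tests.

All randomness flows from the explicit integer seed in the scenario
spec; the same spec reproduces the same data byte-for-byte.

What passing synthetic tests establish: the estimators are correct on
data from the assumed family, robust at the 10%-relative level under 1%
multiplicative noise on decade-length series, and the pipeline is
deterministic.  What they do not establish: real interannual land-use
variability is not calibrated (policy shocks, reclassification
discontinuities), real driver series are not monotone-smooth, and
benefit-transfer coefficients themselves carry regional deviation that
no amount of synthetic data can resolve.  At 1% noise the per-category
trends (0.1–1% a year) are partly masked, so forecast accuracy grades on
noisy synthetic decades are worse than on the smooth series real surveys
produce — grade-1 expectations are therefore asserted on zero-noise
fixtures only.

## Problem sizes

The shipped tests and the acceptance script run on the natural sizes of
the problem: 7 categories × 9 services, decade-length (n = 10) annual
series, 200-replicate noise studies and 100-seed ranking studies; the
whole suite completes in a few seconds on one core.

## Known limitations

* GM(1,1) extrapolates a single exponential trend; structural breaks
  (policy interventions) invalidate long horizons.
* The sensitivity index, being the category's value share, ranks
  categories by contribution; it cannot validate the absolute level of a
  transferred coefficient.
* Grey relational grades measure curve similarity, not causation; a
  driver that merely trends smoothly alongside ESV scores high.
* Valuation coefficients are treated as time-invariant across the study
  decade and the forecast horizon.
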
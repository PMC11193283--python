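# Methods

## The transfer model

The package predicts the all-cause years-lived-with-disability (YLD)
rate of each of 21 abridged age groups (0, 1–4, then 5-year groups to
95+) from three indicators that Chinese routine surveillance publishes
annually: the incidence of class A/B notifiable infectious diseases
(IID), the prevalence/incidence of chronic disease among persons aged
15+ (PCDPF), and the under-five mortality rate (U5MR). Each age group
has its own linear model on a transformed scale,

    Γ(Y) = 0.5 · ln((1 − Y) / Y),      Γ_i = β_i + a_i X₁ + b_i X₂ + c_i X₃,

fit independently by ordinary least squares over the panel years — no
pooling or smoothing across ages. Two properties of the transform
matter and are implemented exactly as published: the 0.5 factor, and the
reversed orientation (Γ falls as Y rises). A coefficient table is only
meaningful together with this exact transform; substituting a standard
logit would silently halve and flip every coefficient.

Sex handling: only PCDPF is sex-specific. Male and female models take
the combined-population IID and U5MR together with the sex-specific
PCDPF; this mirrors how the indicators are actually published (combined
rates are routine; sex-splits are rare).

The bundled `gbd2019_china_3param` asset stores the published
coefficients at their published 4-decimal precision, with 95% bounds.
User fits are kept at full precision; rounding to 4 decimals is an
explicit export option (`--rounded`, or `decimals=4`), never applied
internally — predictions and the fitted-value identity are exact only
before rounding.

## Life table and the Sullivan conversion

HALE is the person-years formulation of the Sullivan method: healthy
person-years L_j(1 − Y_j) are accumulated over the remaining groups and
divided by survivors l_x. The life table is a plain substrate — users
supplying l and L directly (the usual case, since published abridged
tables include both) bypass construction entirely.

A convenience constructor builds the table from 21 death rates with the
standard abridged formulas: q = n·m / (1 + (n − a)·m) with a = a0·n in
the infant group and a = n/2 elsewhere, open-group q = 1 and
L = l/m. Defaults: radix 100 000 and a0 = 0.3 (infant deaths are
concentrated early in the first year). If a closed group's rate implies
q ≥ 1 the constructor raises rather than producing a zero-survivor
table; the invariants (l positive and non-increasing, L positive and
≤ width·l) are enforced on every table, however obtained.

Life-table uncertainty is deliberately **not** propagated: the table is
held fixed in all interval computations, so intervals reflect the YLD
model alone.

The disability-free limit (Y ≡ 0 gives HALE = e exactly) is a useful
identity check, so `sullivan_hale` accepts a bare 21-vector in [0, 1) in
addition to a `YLDSeries`; the series type itself (and therefore all
file input) enforces the model's open interval (0, 1), since a fitted
rate of exactly 0 or 1 is always an upstream error.

## Predictor screening and gap filling

`screen_predictors` reads "global optimum" literally: every subset of
candidates up to the requested size is fitted (21 per-age OLS models
each) and ranked by the selection criterion averaged over age groups.
The default criterion is adjusted R²; AIC is available. Exhaustive
enumeration is capped at 20 candidates (2²⁰ subsets) — beyond that the
user is asked to pre-filter. The report also carries the candidate
correlation matrix, per-age correlations with Γ(Y), and variance
inflation factors (∞ flags exact collinearity).

Missing predictor values are completed by a natural cubic spline through
the observed points, interior gaps only — the procedure interpolates,
never extrapolates — with at least 4 observed points required. Natural
boundary conditions are the conventional default and make the fill
independently checkable against the textbook tridiagonal moment system.

Inputs are assumed pre-harmonised to the canonical 21-group schedule;
loaders reject any other age-group spelling rather than coerce it, to
make silent row misalignment impossible.

## Uncertainty intervals

The reference panel's YLD rates carry 95% bounds. On the Γ scale each
(year, age) value is treated as normal with

    sd = |Γ(lower) − Γ(upper)| / (2 · 1.96),

the symmetric normal-theory recovery of a standard deviation from a 95%
interval (the absolute value absorbs the transform's reversed
orientation). Three modelling choices are assumptions, not published
facts, and are worth restating:

* **Diagonal covariance across age groups** within a year. No
  cross-age correlation structure is published; real YLD estimates are
  positively correlated across neighbouring ages, so our coefficient
  intervals may be somewhat narrower than a correlated resampling would
  give.
* **Years sampled independently** — one 21-dimensional normal per panel
  year.
* **Refit per draw**: each draw perturbs the whole Γ panel, refits all
  21 models, re-predicts YLD at the target predictors and re-computes
  HALE, so coefficient, YLD and HALE intervals are mutually consistent.

Percentiles (default 2.5/97.5) use linear interpolation on order
statistics (`numpy.percentile` default). The point estimate is the
unperturbed fit, run through the identical vectorised pipeline as a
zero-noise draw — this makes the degenerate case (zero-width input
bounds) collapse to exactly zero-width output intervals, bit-identical
to the point fit. Because a finite-draw percentile interval need not
bracket the point estimate, reported bounds are clamped to contain it.

Draw refits use the precomputed least-squares pseudoinverse of the
design matrix (one tensor contraction for all draws and ages); the point
fit's diagnostics come from per-age OLS fits. Both are the same
least-squares solution.

Every stochastic routine takes an explicit seed and is bit-reproducible;
the CLI echoes seed and draw count into each output's metadata header.

## The synthetic generator

The generator emulates the structure of the reference data the model is
calibrated against, so the whole pipeline is testable offline:

* **Predictors**: linear trend plus Gaussian noise, clipped to the
  observed 1990–2019 ranges of the Chinese indicators — IID within
  [0.0017, 0.0030] (drifting down), PCDPF within [0.16, 0.55] (drifting
  up), U5MR within [0.0078, 0.0610] (drifting down). Sex-specific PCDPF
  is the combined path rescaled by the observed male/female-to-combined
  mean ratios. The noise is what makes the three series jointly
  identifiable (three exact linear trends would be collinear).
* **YLD panel**: Γ = true linear predictor + N(0, σ), inverted to the
  rate scale; 95% bounds are Γ ∓ 1.96·h back-transformed. Defaults
  σ = 0.05 and h = 0.05 on the Γ scale — with h = σ the Monte-Carlo
  intervals should attain close to nominal coverage, which is exactly
  what the coverage test measures. The generating coefficients default
  to the bundled combined-population table, so synthetic rates live on a
  realistic scale, and travel with the panel as ground truth.
* **Mortality**: Gompertz–Makeham hazard m(x) = c + α·e^{βx} evaluated
  at group midpoints (97.5 years stands in for the open group), defaults
  α = 3·10⁻⁵, β = 0.1, c = 5·10⁻⁴, giving e₀ ≈ 73.9 years — a plausible
  contemporary schedule with three interpretable parameters. Any
  21-vector of rates can be injected instead.

What the generator does **not** emulate: cross-age correlation of YLD
estimates, autocorrelated indicator dynamics, measurement error in the
predictors, and the actual Chinese indicator trajectories beyond their
ranges. Passing tests therefore demonstrate correctness of the machinery
under the model's own assumptions, not predictive accuracy on real GBD
or yearbook data — reproducing the published error tables would require
those databases.

## Error assessment

MAE (units of the quantity) and MAPE (percent) per age group and in
total, for YLD rates and, given a life table, for HALE — with both the
fitted and reference YLD series converted through the *same* life table,
so HALE errors isolate the YLD model. "Total" pools all (year × age)
records; a per-age-mean alternative (`total_mode="per_age_mean"`) is
provided for sensitivity, since the two conventions differ whenever
per-age record counts or error scales differ. Residual records are
emitted as tidy CSV rather than plots.

## Problem sizes

Tests and the acceptance script run on 30-year panels (matching a
1990–2019 reference span), 100–200 replicate fits, and 300–1000
Monte-Carlo draws; these sizes give Monte-Carlo error well inside the
asserted tolerances (e.g. pooled coverage over 8 400
replicate-coefficients has a standard error of about 0.3 points).

## Known limitations

* All-cause YLD only; no cause decomposition.
* The coefficient asset is only as good as the reference estimates it
  was fit to; intervals quantify reference uncertainty under the
  independence assumptions above, not structural error.
* Single-year (unabridged) life tables and HALE decomposition between
  populations are out of scope.
* A four-predictor variant (adding the two-week incidence of impairment
  and poisoning) is supported structurally by the screening and fitting
  machinery, but no published coefficient values for it are bundled.
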
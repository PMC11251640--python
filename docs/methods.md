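# Methods

## Sampling frame and geometry

The sampling frame is the polygonal footprint of a resting herd (the
"haulout outline"), assumed planar in meters.  All geometry is done with
shapely on projected coordinates; the package performs no geodesy and
carries the CRS only as a label, so callers must reproject (e.g. to the
appropriate UTM zone) before analysis.

A square grid of side `cell_size` (default **19.68 m**, giving 387.3 m²
cells; configurable because the value is survey-specific) is anchored at
the outline's bounding-box minimum corner — the anchoring convention is a
package choice, and `random_grid_origin` provides a seeded jitter for
sensitivity checks.  Cells are clipped to the outline; a clipped cell that
splits into several parts yields one model polygon per part.  Clipped
fragments under **0.01 m²** are discarded as slivers to avoid degenerate
densities (with the threshold at 0 the clipped areas sum to the outline
area to ~1e-9 relative, which the tests assert at 1e-6).  Model polygons
are selected by uniform sampling without replacement of
`round(fraction · n)` cells (round-half-up, minimum 1), default fraction
**0.30**.

## Count summaries

Per-plot observer counts reduce to the mean, sample SD (n−1 denominator)
and CV% = 100·SD/mean.  With one observer neither SD nor CV is defined;
with mean 0 the CV is reported unavailable rather than infinite.  Plot
density is mean count / plot area.  The survey-level density is the
area-weighted mean `d̄ = Σaᵢdᵢ/Σaᵢ` — identically the ratio estimator
`Σcᵢ/Σaᵢ` — with an area-weighted SD using frequency-style weights
`aᵢ/Σaᵢ`.  Whether the SD fed to the extrapolation CI should be weighted
is genuinely open; weighted is the default and `weighted=False` gives the
unweighted sample SD.

## Estimators and intervals

**Direct extrapolation.** `N̂ = A·d̄`; the CI multiplies empirical
2.5/97.5% quantiles of `n_sims` (default 10,000) draws from `N(d̄, s_d)`
by `A`.  Deliberately, `s_d` is the SD of plot densities, *not* the SE of
their mean: the interval describes plot-to-plot density variability, which
is the dominant uncertainty at real haulouts, and matches the procedure
the pipeline reproduces.  The statistical caveat — such an interval does
not shrink with the number of plots — is acknowledged; pass the SE variant
by dividing `s_d` by √n upstream if a sampling-error interval is wanted.
Negative lower bounds (possible because the normal draws are unbounded)
are floored at 0 and flagged.

**Linear model.** OLS of count on area with intercept; prediction at the
haulout area `A` uses the SE of the *mean response* (not a prediction
interval) and a fixed z = 1.96.  `A` lies far outside the plot-area range,
so the prediction is a genuine extrapolation; an `ExtrapolationWarning` is
emitted but the estimate is produced, since the linear trend through the
origin-adjacent plot data is exactly what the method exploits.

**Negative-binomial GLM.** `count ~ terrain + offset(log area)`, log link,
mean/size parameterization `Var = μ + μ²/θ` (stated because θ conventions
differ).  Fitting alternates an IRLS step for the coefficients at fixed θ
(statsmodels GLM with `NegativeBinomial(alpha=1/θ)`) with a univariate
Brent maximization of the exact log-likelihood in θ at fixed means,
starting from θ₀ = 0.1, until the joint log-likelihood changes by < 1e-8
(this mirrors R's `glm.nb`; the test suite checks agreement with
`MASS::glm.nb` to ~1e-5 on coefficients and deviances).  The log-likelihood
uses the gamma-function form so fractional responses (multi-observer mean
counts) are handled as in R.  θ's SE comes from the observed information
(central second difference of the profile log-likelihood).  The null
deviance refits an intercept-only model at the final θ.  With a single
terrain level an intercept-only model is fitted with a warning.  No
additional covariates and no multiple-testing adjustments are applied.

Prediction for a haulout of area `A` and terrain `t` exponentiates the
linear predictor.  The delta-method CI converts the coefficient variance
`var(η̂)` to the log-count scale, `sd_log = sqrt(log(1 + var(N̂)/N̂²))`
(with `var(N̂) = N̂²·var(η̂)`), and reports `N̂·exp(∓2·sd_log)`.  Two
interpretation choices are fixed here: "SD" in the interval is
`sqrt(var(log count))` — the only dimensionally coherent reading — and the
variance is that of the *fitted mean*, excluding NB observation noise,
because the target is the mean herd size rather than a new plot draw.
The terrain effect is reported both as the raw coefficient and, where
users need it, the exponentiated ratio `exp(β_sandy)`; the two differ
(a coefficient of 0.305 is a ×1.357 density ratio) and the package takes
no position on which is "the" effect size.

## Comparisons

Estimates are set against complete counts as ratio = predicted/complete
and percent deviation = 100·(ratio − 1); ratios are kept positive with the
sign carried by the deviation.  The Wilcoxon signed-rank test drops zero
differences (reporting how many), midranks ties, uses the exact null
distribution (dynamic programming over sign assignments, valid with
midranks) for n ≤ 25 and a normal approximation with tie correction and a
0.5 continuity correction above; the rank-sum test reports the rank sum of
the first sample, exact by subset enumeration when min(n) ≤ 10 without
ties.  All p-values are two-sided.  Both implementations are checked
against brute-force enumeration oracles in the tests.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the estimators assume:
homogeneous terrain-level density (defaults 0.648 walrus/m² rocky, 0.879
sandy), NB cell counts with θ = 8.979 (so per-cell variance/mean ≈
1 + μ/θ), uniform point placement within cells by bbox rejection sampling
(exactly uniform on arbitrary clipped shapes), multiplicative rounded
observer noise with CV 5.8%, and visual land counts scaled by a bias
factor (default 0.61, the scale of the systematic visual undercount the
method was designed to replace) with 15% relative noise on top — visual
counts in the field disagree with photo counts by up to ~30%, and the
noise level was fixed at half that range before any calibration against
tests.  A single scenario seed feeds split sub-streams per stage
(outline, counts, points, selection, observers, land count), so stages are
independently reproducible.

Not emulated: within-season density trends (several-fold in real data —
constant density is the default and a user can vary density across
scenarios instead), spatial autocorrelation of density beyond the cell
level, walrus movement/behavior, age classes, mixed-terrain haulouts, and
imagery artifacts.  Passing recovery tests therefore demonstrate
correctness of the estimators under their own assumptions, not robustness
to heterogeneous real haulouts: in particular a haulout mixing both
terrains inside one outline violates the GLM's single-terrain covariate
and is out of scope.

## Validation experiments and problem sizes

`validation.py` holds the recovery experiments the tests and the
acceptance script run: 100 synthetic haulouts (5,000–50,000 m²,
density 0.76) for the counting-reduction proxy, where counting only the
selected 30% of cells leaves ~70% of animals uncounted; 200 surveys
(10,000–30,000 m², defaults otherwise) for estimator unbiasedness, where
both the extrapolation and the linear estimator recover the complete count
to well under 1% on average; and 100 replicates of 2,000 equal-area plots
for NB coefficient recovery, where 95% Wald intervals cover the generating
values at close to nominal rates.  These sizes were chosen as realistic
survey scales at which the Monte-Carlo error of each check is comfortably
below its acceptance band.

## Numerical and degenerate-input choices

Areas come from shapely's shoelace computation; area conservation of
clipping is exact to ~1e-9 relative.  Observer counts are rounded to
integers and floored at 0, so `round(0·(1+ε)) = 0` exactly.  A
constant-count, single-terrain dataset makes both the null and residual
deviance 0; deviance explained is defined as 0% there.  θ estimates are
capped at 1e7 (Poisson-like data drives θ̂ → ∞; the cap keeps the GLM
family finite).  Empty intersections, zero areas, open rings, negative
counts, unknown terrain labels and broken polygon-id linkage all raise
typed errors with the offending object named.
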
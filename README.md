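# hauloutsurvey

Plot-sampling abundance estimation for animals aggregated on shore —
written for pinniped haulout surveys (the motivating system is Pacific
walrus herds of up to ~10⁵ animals resting on Chukotkan beaches), where
counting every individual on aerial imagery is accurate but very slow.

The pipeline implements the semi-automated alternative: digitized haulout
outlines (planar polygons in meters) are covered with a square grid
(default cell 19.68 m), the cells are clipped to the outline, a random 30%
of the clipped cells become *model polygons*, and only those plots are
counted (by one or more observers).  Abundance over the whole haulout area
`A` is then estimated three ways:

1. **Direct extrapolation** — `N̂ = A · d̄`, with `d̄ = Σaᵢdᵢ/Σaᵢ` the
   area-weighted mean plot density (algebraically the ratio estimator
   `Σcᵢ/Σaᵢ`).  The 95% CI multiplies empirical 2.5/97.5% quantiles of
   draws from `N(d̄, s_d)` by `A`, where `s_d` is the area-weighted SD of
   plot densities.
2. **Linear regression** — OLS of plot count on plot area; `N̂` is the mean
   prediction at `A` with a `±1.96·SE` interval.
3. **Negative-binomial GLM** — pooled across surveys,
   `count ~ terrain + offset(log aᵢ)` with log link and
   `Var = μ + μ²/θ`; θ and the coefficients are estimated by alternating
   IRLS and univariate ML from `θ₀ = 0.1`.  Predictions exponentiate the
   linear predictor; the delta-method CI uses
   `var(log N̂) = log(1 + var(N̂)/N̂²)` and reports
   `N̂·exp(∓2·sd(log N̂))`.

Observer agreement (CV of repeated plot counts), Wilcoxon signed-rank and
rank-sum comparisons of densities, and ratio/percent-deviation comparisons
against complete head counts round out the analysis.  A synthetic-data
module generates whole surveys — outlines, NB-distributed cell counts,
walrus point patterns, noisy observer counts, biased visual land counts —
with known truth, so every estimator is validated by parameter recovery.

## Worked example

```python
import hauloutsurvey as hs

scenario = hs.SimulationScenario(
    terrain="sandy_type", seed=42,
    outline_spec=hs.OutlineSpec(shape="blob", area=12_000),
)
survey = hs.simulate_survey(scenario)
areas = {c.polygon_id: c.area for c in survey.cells}
summaries = hs.summarize_count_table(survey.observer_counts, areas)
d_mean, d_sd = hs.weighted_mean_density(summaries)
est = hs.direct_extrapolation(survey.outline.area, d_mean, d_sd, seed=0)
```

prints, when the pieces are reported:

```
haulout area           12000 m^2
grid cells                42  (selected 13)
weighted density       0.791 walrus/m^2  (SD 0.327)
complete count         10756 walruses (truth)
extrapolation           9498 walruses  95% CI [1802, 17182]
deviation from truth   -11.7 %
```

A single survey can miss by ±10–20% — the plot-to-plot density SD here is
0.33 walrus/m², and the wide CI says exactly that — but the estimator is
unbiased: over 200 replicated surveys the mean deviation is below 1%
(see `hauloutsurvey.validation.estimator_recovery_experiment`).

The same workflow is available from the shell:

```sh
hauloutsurvey simulate --seed 42 --outdir survey/
hauloutsurvey estimate survey/cells.geojson survey/counts.csv --outdir est/
hauloutsurvey run config.yaml          # full pipeline from a YAML config
```

GeoJSON files carry planar meter coordinates with the projected CRS
recorded as a file-level `crs_label` property (outlines should be
projected, e.g. to a UTM zone, before entering the pipeline).

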
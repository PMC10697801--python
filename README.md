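# reefbayes

Drivers of coral-reef herbivore biomass and benthic condition, and the
fishing-depletion threshold at which the benthos measurably suffers.

`reefbayes` is a tested re-implementation of a reef monitoring analysis
pipeline for people who work with multi-institution underwater survey
data: fisheries and reef ecologists, marine resource managers, and
biostatisticians. It covers the full chain from raw fish counts to
management-facing numbers:

1. **Survey processing** — inter-method count calibration, allometric
   biomass (W = a·TL^b, grams vs total length in cm), truncation of
   extreme schooling counts (flag above the 99.9% count quantile,
   truncate flagged herbivore species above the 99% quantile), the
   hard-bottom/0–30 m/2004–2014 survey domain, aggregation of transects
   into replicates (unique source × lat × lon × depth × year), and the
   benthic condition statistic log((coral + CCA)/macroalgae).
2. **Hierarchical Bayesian driver models** — biomass
   y ~ Gamma(κ, mean e^μ) with log link and κ ~ Uniform(0, 100); benthic
   log-ratio y ~ Normal(μ, 1/τ) with τ ~ Gamma(0.1, 0.1). In both,
   μ = ε_year + ε_dataset + ε_moku + β·X on standardized drivers, with
   β ~ Normal(0, 100) and each hierarchical effect under a sum-to-zero
   constraint (ε_K = −Σ ε_k). Three chains, Gelman–Rubin diagnostics,
   posterior predictive checks and Bayesian R².
3. **Counterfactual depletion** — per 100 m pixel, *expected* biomass
   under measured drivers vs *potential* biomass with fishing drivers at
   native zero; their draw-wise ratio is the "% potential biomass"
   index. A pixel is *affected* when the 25th percentile of benthic
   condition under potential biomass exceeds the 75th percentile under
   expected biomass, and a logistic regression of unaffected/affected on
   median % potential biomass is inverted at probability 0.99 to give
   the depletion threshold.
4. **Post-stratification** — pooling full pixel posteriors within moku
   (or reserves) with equal pixel weight, quartile ranks and comparisons
   against a reference posterior.
5. **Management hurdle analysis** — binomial(logit) × gamma(log) hurdle
   model of parrotfish biomass across management levels; combined
   prediction = presence probability × conditional mean, with 5000
   stratified bootstrap resamples and bias-corrected 95% intervals.

A first-class synthetic-data generator (27 correlated drivers in four
groups, contiguous moku blocks, gamma biomass with known coefficients,
benthic interactions, schooling spikes, zero-inflated management strata)
provides ground truth for every stage, so the whole pipeline is testable
without access to monitoring data.

## Worked example

```python
import pandas as pd
import reefbayes as rb

grid = rb.make_driver_grid(n_pixels=1000, n_moku=4, seed=7)
truth = rb.make_truth({"beta": {"spear_shore": -0.5, "net_boat": -0.3,
                                "urban_runoff": -0.25, "sst_mean": 0.2,
                                "rugosity": 0.4},
                       "kappa": 3.0, "seed": 11})
reps, fish = rb.simulate_surveys(grid, truth, n_replicates=1000,
                                 n_years=3, n_datasets=2, seed=3)

drivers = ["spear_shore", "net_boat", "urban_runoff", "sst_mean", "rugosity"]
data = reps.drop(columns=["depth"]).merge(
    grid[["pixel_id"] + drivers], on="pixel_id")
st = rb.DriverStandardizer(columns=drivers).fit(grid)
design = rb.build_design(data, drivers, st, model="herbivore")
hier = pd.DataFrame({"year": data.year, "dataset": data.source_dataset,
                     "moku": data.moku_id})

model = rb.HierarchicalGammaRegression(schedule="ci", seed=5)
model.fit(design, data["biomass_total"].to_numpy(), hier)
print(model.summary().head(6).round(3).to_string(index=False))
```

```
   parameter  median    q25    q75   q2.5  q97.5  rhat
   intercept   2.977  2.948  3.002  2.874  3.051 1.002
 spear_shore  -0.519 -0.532 -0.507 -0.556 -0.483 1.005
    net_boat  -0.280 -0.290 -0.270 -0.307 -0.248 1.017
urban_runoff  -0.276 -0.290 -0.264 -0.318 -0.236 1.000
    sst_mean   0.234  0.221  0.247  0.196  0.269 1.029
    rugosity   0.414  0.399  0.428  0.378  0.452 1.004
```

The posterior medians recover the generating coefficients (−0.5, −0.3,
−0.25, 0.2, 0.4 on standardized drivers; intercept log 20 ≈ 3.0) with
every Gelman–Rubin statistic near 1. Coefficients are on the log-biomass
scale per SD of driver: one SD more shore spearfishing means
e^−0.52 ≈ 0.60× the herbivore biomass. The counterfactual then asks what
each pixel would hold without fishing:

```python
pc = rb.predict_counterfactual(model, grid, drivers, st,
                               unknown_moku="population")
print(round(float(pc.median_percent.mean()), 1))   # 52.9
```

so under these (deliberately heavy-fishing) generating conditions the
average pixel retains about 53% of its potential biomass; pixels whose
fishing drivers are natively zero return exactly 100.

The same analysis runs end to end from the command line:

```bash
reefbayes run --seed 1 --outdir out --mcmc-schedule ci
```

which writes replicate/grid CSVs, draws files, diagnostics, the
per-pixel threshold classification, moku summaries, the hurdle report
and a human-readable `report.md`.

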
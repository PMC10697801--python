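# Methods

## The modelling problem

Reef herbivores (grazers such as surgeonfishes, scraper/excavators such
as parrotfishes, browsers such as chubs) suppress algae and help keep
reefs in a calcified state. Monitoring data for such systems are pooled
from many institutions with different survey methods, are spatially
unbalanced, and sit on strong environmental gradients. The package
implements a chain of analyses for this setting: driver models of
herbivore biomass and of benthic condition, a counterfactual that
isolates the fishing contribution per pixel, a threshold linking fishing
depletion to benthic impact, post-stratified area summaries, and a
two-part model of management effects.

## Survey processing

The analysis unit is the *replicate*: all transects sharing data source,
latitude, longitude (rounded to 5 decimals, configurable), depth and
year, averaged with equal transect weight. Upstream steps:

* **Calibration** multiplies counts by species × method factors to
  reconcile survey methods. Missing pairs default to 1 with a warning;
  the factor table is supplied by the user (or simulated) — the package
  does not re-derive calibration factors.
* **Biomass** is count · a · TL^b / area (g m⁻²), with species-specific
  allometric a, b. An unknown species is an error, not a silent drop:
  dropping records would bias biomass low.
* **Schooling truncation** is two-stage: observations above the 99.9%
  quantile of all individual counts are flagged; for flagged *herbivore*
  species, counts above the 99% quantile are set to that quantile. All
  quantiles in the package use the sort-based linear-interpolation rule
  (numpy's default, R type 7). Re-applying the operation is a no-op
  whenever the whole extreme tail belongs to flagged herbivore species
  (the practical regime); if extreme counts belong to non-herbivores
  they are deliberately left untouched.
* **Domain filter**: hard bottom, 0–30 m, survey years 2004–2014 (reef
  condition before the 2014–2015 bleaching event). Moku (traditional
  Hawaiian land divisions, the spatial stratum) with fewer than 5
  replicates are dropped.
* **Benthic condition** is log((coral + CCA + δ)/(macroalgae + δ)) with
  a floor δ = 0.1 % cover added to both sides. The floor keeps the
  statistic defined at zero cover and preserves its antisymmetry; it is
  configurable because the choice is ours, not dictated by the science.

## Driver preparation

Continuous drivers are standardized to zero mean and unit sample
variance; the training moments are frozen and re-used on prediction
grids, never re-estimated. Predictors correlated above |Spearman ρ| =
0.7 are screened: the pair with the highest correlation is resolved
first, keeping the driver named earlier in a user-supplied preference
list, else the one with lower total absolute correlation to the rest.
The absolute value is used because collinearity does not care about
sign.

The herbivore design is the retained standardized drivers plus
habitat-class indicators (reef, pavement, boulder) against an "other
hard bottom" reference. The benthic design replaces fishing and habitat
terms with the herbivore block: log(1+x)-transformed functional-group
biomasses, centered, then all two-way products and the three-way product
(7 columns). Centering before forming interactions reduces collinearity;
the centers are stored in the design metadata and re-used for grid
prediction. Fishing drivers are rejected in the benthic design — fishing
is hypothesized to act on the benthos only through herbivores — and
habitat classes are excluded as circular with the response.

## The hierarchical Bayesian models

Both models share the linear predictor
μ = intercept + β·X + ε_year + ε_dataset + ε_moku.

* **Gamma biomass model**: y ~ Gamma(shape κ, mean e^μ),
  κ ~ Uniform(0, κ_max = 100), sampled through a logit transform. A
  literal shape/rate reading of the "Gamma(κ, κ·e^μ)" parameterization
  would give mean e^(−μ) and flip every coefficient's sign; the package
  uses mean = e^μ (rate κ·e^(−μ)), which matches the ecological sign
  convention (negative fishing coefficients = less biomass).
* **Normal benthic model**: y ~ Normal(μ, precision τ),
  τ ~ Gamma(0.1, 0.1), σ = τ^(−1/2). The alternative literal reading
  σ = 1/τ is available via `tau_is_sd_inverse=True`.
* **Coefficients**: β ~ Normal(0, variance 100) — weakly informative on
  standardized predictors. (A precision-100 reading would be strongly
  informative and is rejected.)
* **Hierarchical effects** use the sum-to-zero construction: for K
  levels, ε_1..ε_{K−1} ~ Normal(0, σ_g²) are free and ε_K = −Σ ε_k, so
  every effect vector sums to zero *identically* in every draw and the
  effects are identified against the intercept. Group SDs σ_g get
  Half-Normal(0, 2) priors (on the log-predictor scale): proper, weakly
  informative, stable with few levels.

### Sampling

The sampler is a blocked adaptive random-walk Metropolis implemented in
the package. Parameter blocks: coefficient sub-blocks of at most 8
entries, each hierarchy's free effects, the log group SDs, and the
transformed dispersion. Blocks are warm-started at the non-hierarchical
GLM estimate with the GLM covariance as initial proposal Cholesky (step
size 2.38/√d, the matched-proposal optimum); during initialization and
burn-in each block's step size follows a Robbins–Monro recursion toward
26% acceptance and the proposal covariance is re-estimated from the
chain; adaptation freezes before retained sampling. Chains start from
the warm start plus jitter of two coefficient standard errors (0.3 for
the remaining parameters), so the Gelman–Rubin statistic compares
genuinely dispersed chains.

Three chains with the schedule initialization 500 / burn-in 2000 / 5000
retained draws per chain ("paper"). The "ci" schedule (800/700/1500) is
the package's desk-scale default and matches the full schedule's point
estimates within Monte-Carlo error on the problem sizes used here
(asserted in the test suite). Convergence is flagged (not fatal) when
any classic between/within Gelman–Rubin statistic exceeds 1.1.
Diagnostics also include posterior predictive p-values for the mean and
SD discrepancies and the Bayesian R² of Gelman et al. (var(fitted) /
(var(fitted) + modelled residual variance), per draw; residual variance
is e^(2μ)/κ for the gamma model, σ² for the normal model).

### Leverage re-runs

`leverage_rerun` neutralizes a driver at high-leverage rows (by default
the top decile of that driver; any boolean mask can be supplied), sets
the native values to a replacement (default 0 — meaningful for pollution
and fishing intensities whose native floor is 0), re-standardizes,
refits, and reports whether the coefficient's 95% interval contains zero
before and after. This reproduces the "is this effect driven by one
anomalous site?" sensitivity analysis.

## Counterfactual depletion and the threshold

For each pixel the herbivore model yields matched posterior draws of
*expected* biomass (measured drivers) and *potential* biomass (fishing
drivers set to zero in native units before standardization, everything
else unchanged). Matched draw indices are used for the ratio, as a
ratio-of-posteriors requires; mismatched pairing would inflate ratio
variance. Year and dataset effects are set to their sum-to-zero mean of
0 — the map is a "typical year, typical source" prediction — while the
moku effect is taken from the fitted level (a population-level fallback
exists for unfitted moku). Pixels with all fishing drivers natively zero
return % potential ≡ 100 exactly, by construction.

Benthic condition under each scenario uses the measured non-fishing
drivers plus the posterior-mean functional-group biomasses for that
scenario, pushed through the benthic model's linear predictor only (no
observation noise: the comparison is between conditions, not single
surveys). A pixel is *affected* when Q25(condition | potential) >
Q75(condition | expected) — the central 50% intervals separate, with
potential higher. The binary unaffected(1)/affected(0) outcome is fit by
maximum-likelihood logistic regression on the median % potential
biomass, and the threshold is exact logit inversion at P(unaffected) =
0.99: x* = (logit(0.99) − b₀)/b₁. Complete separation returns the
mid-gap threshold with a flag; a slope whose 95% Wald interval contains
zero flags the threshold unreliable. Coverage summaries report the
fraction of hard-bottom pixels below x*, overall and per moku.

## Post-stratification

Because survey allocation does not represent habitat, area estimates
come from the prediction grid: soft-bottom pixels are masked, each
remaining pixel contributes its full posterior with equal weight, and an
area's posterior is the concatenation of its member pixels' draws.
Summaries are the pooled mean and central 50% interval (25th–75th
percentile, same sort-based quantile rule as the classifier), quartile
ranks across areas, and a "below reference" comparison that requires an
area's 50% interval to lie entirely below the reference posterior's.

## Management hurdle analysis

Parrotfish biomass across management levels is modelled in two parts on
the management factor: presence/absence by a binomial GLM (logit) and
biomass-when-present by a gamma GLM (log), with Wald statistics reported
per contrast together with each part's residual df. The combined
prediction per level is presence probability × conditional mean. If a
stratum has no zeros the analysis degrades to a plain gamma model
("gamma-only" mode), matching how a hurdle collapses when presence is
certain.

Uncertainty comes from non-parametric bootstrapping (default B = 5000;
B = 500 in desk-scale tests) with resampling stratified by management
level — unstratified resampling could empty a small level and break the
refit, and stratification preserves the sampling design. For the
one-factor model the GLM maximum-likelihood estimates are exactly the
per-level presence fraction and mean positive biomass, so bootstrap
refits use those closed forms; this is algebraically identical to
refitting both GLMs and orders of magnitude faster. Intervals are
bias-corrected percentile (BC) by default — the plain reading of
"bias-corrected 95% confidence intervals" — with BCa (jackknife
acceleration) available via `method="bca"`. Fold-changes between levels
are ratios of combined predictions with their own BC intervals.
Bootstrap draws in which a level loses all its positive observations are
discarded and counted.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the generative assumptions of the models, with
defaults chosen once to resemble the study system:

* 27 drivers in four groups (8 fishing, 7 pollution, 8 oceanography, 4
  habitat) from a latent Gaussian with within-group correlation 0.3
  (half that across groups), mapped through monotone transforms so
  fishing/pollution intensities are non-negative lognormals, depth spans
  0–30 m, and Spearman structure survives. 5% of pixels are fully
  unfished (remote-coast analogue). Moku are contiguous pixel blocks, so
  each moku has its own driver profile and post-stratification is
  non-trivial.
* Biomass: Gamma(κ = 2, mean e^μ) with intercept 3 (≈ 20 g m⁻², a
  plausible reef-wide herbivore biomass), hierarchical SDs 0.2/0.25/0.15
  (year/moku/dataset) on the log scale; functional-group shares from a
  Dirichlet around 45/30/15% (grazer/scraper/browser) with 10% other.
* Benthic log-ratio: Normal around the herbivore-block predictor with
  positive main effects, negative two-way and positive three-way
  interactions (the qualitative pattern expected of complementary
  herbivore functions), residual SD 0.8; reported covers are constructed
  to be exactly consistent with the drawn log-ratio.
* Fish records decompose replicate biomass over a 9-species allometric
  table; a configurable fraction of schooling-prone species' records is
  multiplied by a spike factor to exercise truncation.
* Hurdle strata: presence ~ Bernoulli(p_level), biomass | present ~
  Gamma(κ, mean μ_level).

Each output table draws from its own RNG stream under one master seed,
so generating an extra table never perturbs the others, and identical
seeds give bit-identical outputs.

Deliberately *not* emulated: spatial autocorrelation beyond moku blocks,
real Hawai‘i geography, species-level abundance patterns, temporal
trends within the survey window, and observation error in benthic cover.
Passing tests therefore demonstrate that the estimators recover the
stated generative structure at realistic sizes — not that real reef data
satisfy that structure.

## Numerical choices and degenerate inputs

* All quantiles use numpy's default linear-interpolation (type-7) rule.
* Linear predictors are rejected beyond |μ| > 50 during sampling
  (overflow guard far outside the data-supported region).
* κ is sampled on logit(κ/κ_max); τ and group SDs on the log scale, with
  Jacobians included.
* Constant driver columns are a standardization error; unknown species,
  unknown moku (without the explicit population fallback), unknown
  management levels, empty draw vectors and single-class threshold data
  all raise instead of guessing.
* A management level with no positive observations yields combined
  prediction 0 with a warning and an undefined gamma contrast.
* Ties in the correlation screen resolve by total-correlation, then by
  name, making the retained set independent of column order.

## Problem sizes

The default test/acceptance sizes — grids of 400–2000 pixels, 400–2000
replicates, the "ci" MCMC schedule, B = 500–2000 bootstrap draws — were
chosen as the smallest sizes at which the Monte-Carlo checks (coverage,
moment recovery, threshold recovery) are sharp; the full 7500-iteration
schedule and B = 5000 remain the defaults for real analyses
(`--mcmc-schedule paper`).

## Known limitations

* The Metropolis sampler mixes more slowly than gradient-based samplers
  on large coefficient blocks; with ~30 predictors the "ci" schedule can
  leave Gelman–Rubin statistics slightly above 1.1 (flagged, not fatal —
  use the "paper" schedule for final inference).
* The benthic counterfactual propagates posterior-*mean* functional-group
  biomass, not full biomass uncertainty, mirroring the stated procedure;
  benthic uncertainty therefore reflects benthic-model coefficients
  only.
* The hurdle analysis supports a single management factor (the case-study
  design); covariate-adjusted hurdles are out of scope.
* GeoTIFF/GeoJSON export is not provided; all spatial outputs are CSV
  keyed by pixel id.
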
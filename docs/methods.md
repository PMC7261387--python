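# Methods

This note records the models, conventions and design choices behind
`forestdyn`, in the order the pipeline applies them.

## Census data model

The substrate is a long-format stem table (one row per tree per census) with
status `alive`, `dead` or `not_recorded`, plus a plot table (area, FF/NF
fire stratum, topographic sector). Time is decimal years; census intervals
are consecutive census-year pairs, so the monitored design
1996/1999/2003/2006/2010/2016 yields intervals of t = 3, 4, 3, 4, 6 years.

Conventions where field protocols are silent:

* **Inclusion.** A tree's first alive record must have DBH ≥ 5 cm (the cm
  threshold of the census protocol); established trees may later shrink
  below it without being dropped.
* **Recruits** are not a stored status: a recruit is a tree whose first
  alive record falls at the end census of an interval. This avoids a
  redundant field that could disagree with the observations.
* **Gaps.** A tree missing from one census but recorded alive on both sides
  is treated as alive at the missed census for counting, with DBH and
  height linearly interpolated for biomass; every filled gap is counted and
  logged. A tree that vanishes permanently without a dead record is counted
  as dying in the interval after its last alive record (the standard
  plot-network convention), also logged.
* **Multi-stemmed trees** must be pre-merged to one record per tree id.

Validation is total: a table either satisfies every invariant (unique
(tree, census) records, known plots and censuses, no dead→alive
transitions, positive measurements) or the error lists each offending row.

## Allometry and wood density

Per-tree aboveground biomass uses the moist-tropical form
AGB = 0.0673·(WD·H·DBH²)^0.976 (kg), and carbon is the fixed fraction
0.47·AGB. Size classes partition the DBH axis as S = [5, 10],
M = (10, 35], L = (35, ∞) cm; the field convention "10.1–35" for M is read
as the half-open boundary at 10 cm given 0.1 cm measurement resolution, so
the classes tile the axis with no gap or overlap.

Wood density is a species trait. Species lacking a measured value receive
the mean of measured species weighted by stem abundance in the most recent
census — the census against which measurement coverage (~80 % of stems) is
defined — with an unweighted-mean option (`weighted=False`). Fallback
assignments are flagged `measured = 0` in the output.

## Demographic rates

For a plot-interval with counts N₀ (initial live), N_m (deaths), N_r
(recruits), N_t (final live):

* M = 100·[1 − ((N₀ − N_m)/N₀)^(1/t)] %/yr — mortality on the initial count;
* R = 100·[1 − (1 − N_r/N_t)^(1/t)] %/yr — recruitment on the final count;
* λ_corr = λ·t^0.08 applied to both, compensating the downward bias of
  longer census intervals (stems that both appear and die between censuses
  go unseen). At t = 1 the correction is the identity.

Stem conservation N_t = N₀ − N_m + N_r is an exact integer identity under
the counting conventions above and is asserted at construction. An empty
cohort (N₀ = 0 or N_t = 0) yields a flagged missing rate (NaN), never 0.

Site aggregation defaults to per-plot rates summarized as mean ± sample SD
within each site-interval (matching how plot networks report error bars);
a pooled mode (summing counts across a site's plots before applying the
formulas) is available because the two conventions can differ when plots
vary in stem count.

## Flux accounting

Stocks are summed alive AGB per plot-census, reported in Mg ha⁻¹. Over an
interval of length t on a plot of area A ha:

* PB = [Σ recruit AGB at end + Σ survivor (AGB_end − AGB_start)]/(A·t);
* mortality flux = Σ AGB of dying stems valued at the start census,
  classed by start-census DBH, /(A·t);
* NBC = (stock_end − stock_start)/t.

Valuing deaths at their last live census and recruits at first record is
the only convention under which NBC = PB − mortality flux holds exactly;
the identity (to floating-point summation error, ~1e−14 relative) is the
module's master test, and size-class fluxes partition the total exactly.
Negative survivor growth (shrinkage, measurement noise) is kept and logged
by default; truncation to zero is available for sensitivity analysis but
deliberately breaks the identity.

## Longitudinal models

Plot-level responses are modelled population-averaged with GEE, plots as
clusters: Gamma family with log link for AGB, Poisson with log link for
stem counts, Gaussian for rates. Predictors are the census (or interval)
factor, the site factor, and their interaction; the time predictor is a
factor rather than a trend because per-census contrasts (letter displays)
are the reporting unit.

The working correlation defaults to exchangeable — the natural first choice
for plot-level repeated measures — with independence and AR(1) options.
Term-level hypotheses use the Wald chi-square on the cluster-robust
covariance. With only 18 clusters the plain sandwich is anti-conservative,
so the default covariance is the Mancl–DeRouen bias-reduced estimator
(`cov_type="bias_reduced"`); the plain (`robust`) and model-based (`naive`)
estimators remain selectable. Pairwise post hoc contrasts compare
site-averaged marginal linear predictors between time levels, are
Bonferroni-adjusted (p_adj = min(1, k·p), monotone and capped), and are
rendered as a compact letter display via the insert-and-absorb algorithm,
which is a deterministic, order-invariant function of the significant-pair
set. Non-convergence is flagged on the result, never silent.

## Stand simulator

The generator emulates the study design so every stage runs without field
data: 8 FF + 10 NF plots of 600 m² (1.08 ha), censuses
1996/1999/2003/2006/2010/2016, stems included at DBH ≥ 5 cm.

Dynamics step annually — deliberately finer than the census spacing, so the
interval-length bias that the λ·t^0.08 correction addresses genuinely
arises in the synthetic data. Each year a live stem dies with probability
1 − exp(−h), where

h = base_hazard × size_multiplier × exp(drought_effect · deficit ·
drought_size_multiplier) × fire_multiplier

* base_hazard defaults to 0.0357 yr⁻¹, placing stem mortality in the
  3–5 %/yr background band of hyperdynamic transition forests;
* the background size multipliers (1.2, 0.9, 0.25 for S/M/L) encode that
  small stems die most and large stems rarely at background — while
  droughts specifically elevate large-stem hazards
  (drought_l_factor = 2.5 on the drought exponent), the mechanism behind
  drought-driven large-tree mortality;
* deficit = max(0, −index − 1): drought index values above −1 are benign,
  so ordinary dry years do not elevate mortality;
* the fire multiplier (default 4.0) applies once, in the 2010→2011 step,
  on FF plots only.

Survivors add a Normal(0.25, 0.12) cm yr⁻¹ DBH increment (floored so DBH
stays positive); recruits arrive as a Poisson stream of 60 stems ha⁻¹ yr⁻¹
entering at 5 + Exp(0.6) cm and become visible to the census once
DBH ≥ 5 cm; heights follow the saturating curve
H = 26·DBH/(18 + DBH)·exp(ε) with per-tree lognormal noise (σ = 0.12).
Initial stands draw ~1600 stems ha⁻¹ with DBH = 5 + Weibull(1, 9) cm.
These values were chosen once as a realistic moist-forest stand (stocks
around 200–250 Mg ha⁻¹, turnover 3–5 %/yr); they are preset conventions,
not field estimates. The drought series is AR(1) (φ = 0.6, σ = 0.6) with
negative excursions at episode years (2002, 2005, 2010, 2016 in the
study-like presets) and an optional drying trend.

A stem's first census after death carries an explicit dead record. All
randomness flows from one seeded generator, so outputs are byte-identical
per (config, seed), and the returned truth object (event log, applied
hazards) reconciles exactly with the emitted table.

What the generator does *not* emulate: spatial competition, species-level
demographic differences beyond wood density, measurement error on DBH
re-measurement, tag loss, or climate-derived drought indices. Passing tests
therefore demonstrate the correctness of the accounting and inference
machinery under a known generative model, not the field accuracy of any
particular rate.

## Problem sizes and numerics

The test suite and acceptance script run the full 18-plot design once,
50-plot parameter-recovery runs once, and 200-replicate Monte-Carlo
contrasts on the 8–10-plot presets; these sizes give Monte-Carlo standard
errors far smaller than the effects being detected while keeping a full
run in the minutes range on one CPU. Formula implementations agree with
independent log-domain evaluations to < 1e−10 relative error; conservation
identities hold to ~1e−14 (floating-point summation order); rate formulas
return NaN, never 0, for empty cohorts; Bonferroni adjustment is capped at
1; the letter display depends only on the set of significant pairs.

## Known limitations

* No height–diameter imputation: heights are required on alive records
  (they are measured in this protocol).
* No uncertainty propagation through the allometric equation, no
  belowground biomass or necromass.
* GEE assumes enough clusters for asymptotics even with the bias-reduced
  covariance; designs much smaller than ~15 plots warrant permutation
  inference instead.
* The pooled-site rate mode and the per-plot default can disagree when plot
  stem counts are very uneven; both are reported deliberately.
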
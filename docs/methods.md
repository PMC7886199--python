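# Methods

This note records the models and procedures implemented in `streamtherm`,
the choices made where several defensible options existed, and what the
synthetic-data experiments do and do not demonstrate.

## Thermal-regime descriptors

Hourly water temperatures are condensed to daily maximum, minimum, mean,
range and within-day sample variance (n−1) of the hourly values. A day
qualifies when at least 90% of its 24 hours are present and pass the
plausibility screen (−1 to 40 °C; out-of-bounds hours are flagged, reported,
and treated as missing rather than dropped silently). Seasonal statistics use
only qualifying days; a season is flagged `low_coverage` below 80% qualifying
days and `missing` with none.

- **MWMT / MWAT** are the maxima over all 7-consecutive-calendar-day windows
  lying fully inside the season of the mean daily maximum / mean daily mean.
  Windows never cross season boundaries (descriptors are seasonal
  summaries), and a window containing a non-qualifying day is skipped rather
  than renormalized.
- **Degree days** are the cumulative sum of qualifying daily means with base
  0 °C; no base is conventionally fixed for these streams, and base 0 keeps
  the quantity a plain cumulative exposure.
- **Exceedance counts** apply the regulatory cold-water thresholds (16 and
  20 °C, configurable) to the daily *maximum* (configurable to the daily
  mean), since those criteria are conventionally stated for maxima. The
  consecutive-day statistic is the longest run of consecutive calendar days
  above the threshold; a missing day breaks a run.
- **Within-day variance** is the variance of a day's hourly values; the
  seasonal `avg_variance`/`max_variance` are the mean/max of those daily
  variances. Variance could alternatively be windowed weekly; the daily
  window matches the daily-summary basis of every other descriptor.

The reach-level series is the sensor at the reach's downstream extent
(`reach_bottom`), which integrates exposure over the reach; `reach_top` can
be selected instead.

Seasons partition the water year labeled by its ending calendar year:
Fall = Oct 1–Dec 31, Winter = Jan 1–Mar 31, Spring = Apr 1–Jun 30,
Summer = Jul 1–Sep 30.

## BACI mixed model

One value per (site, reach, year) cell enters
`value ~ Reach + Year + Reach:Year` with a random site intercept and
stratum-specific residual variances. The default variance strata are the six
Reach×Year cells — the most general relaxation of homoscedasticity "among
reaches and years" — configurable to Reach-only or Year-only. The marginal
Gaussian likelihood (ML or REML) is maximized directly: fixed effects are
profiled out by GLS, the 1 + G log-variances are optimized with L-BFGS-B
(relative tolerance 1e−8), with up to three jittered restarts on failure and
the best point returned flagged unconverged. Bounds on log-variances are set
relative to the response variance so that degenerate (constant) responses
remain representable without making the weighted normal equations singular.

Under reference coding (upstream, pre) the thinned and downstream BACI
double differences equal the two interaction coefficients, and for any
converged fit the Wald estimate equals the plug-in double difference of
model cell means.

**Intervals.** The Wald CI uses a t reference with containment degrees of
freedom n − p − n_sites + 1, a conservative choice for ~10-site designs.
The cluster bootstrap resamples whole sites with replacement — the site is
the independent replicate — and recomputes the plug-in double difference per
replicate. The default interval is the *studentized* (bootstrap-t) form: in
calibration experiments at the study's own scale (10 sites, Gaussian
responses) the plain percentile interval rejects a true null ~9% of the time
at nominal 5%, while the bootstrap-t and the Wald interval sit at ~5%. The
percentile interval remains available.

The pipeline's `auto` mode follows the residual diagnostics: Shapiro–Wilk on
BLUP-adjusted, stratum-standardized residuals; when normality is rejected at
α = 0.05 (or the residuals are degenerate) the bootstrap interval is used.
The heteroscedastic strata absorb part of any heavy-tail signal before
standardization, so the diagnostic's power against extreme tails is
moderate (~40% against t₂ at this design size) — adequate as a switch, not
as a formal test.

Seasons lacking pre-treatment data (e.g. a logger network deployed in
spring of the pre-treatment year) cannot form a double difference; the
pipeline then reports the post-treatment reach-minus-upstream difference,
flagged `post_only`.

No multiplicity correction is applied across descriptors; each contrast is
reported with its own interval.

## Longitudinal profiles

The per-sensor (post − pre) change in a descriptor (MWMT by default) is
anchored to 0 at the upstream-most sensor, making profiles comparable across
sites and invariant to uniform between-year shifts. Trajectories are
labeled: `undetectable` when no anchored change exceeds 0.2 °C in absolute
value, `persists` when the value at the downstream extent retains ≥ 50% of
the peak change, `dissipates` otherwise. The 50% rule and the tolerance are
explicit quantifications of patterns usually described verbally; both are
options.

## Multivariate regime structure

The regime matrix holds one row per (site, reach, year, season) and one
column per selected descriptor (default: the 14 named descriptors). Columns
are z-standardized before Euclidean distances are taken, because the
descriptors mix °C, °C² and day counts and raw distances would be
unit-dominated; raw mode is available. Rows with any unavailable descriptor
are dropped (logged); constant columns cannot be standardized and are
dropped with a warning.

NMS minimizes Kruskal stress-1 in two dimensions via iterative majorization
with monotone regression, run as best-of-up-to-999 restarts. The first start
is the classical (metric) MDS configuration — which also guarantees the
non-metric solution never ends worse than metric MDS on the same distances —
and the search stops early once the two best stresses agree within 1e−4.
Reach ellipses are normal-theory 95% ellipses (group mean, covariance,
χ²₂ radius); groups under 3 points are skipped, collinear groups flagged.

PerMANOVA partitions the Gower-centered squared-distance matrix by the
sequential projections of Reach, Year and Reach×Year (McArdle–Anderson);
sums of squares add to the total exactly. p-values use free permutation of
rows, p = (#{F* ≥ F} + 1)/(n_perm + 1) with 999 permutations by default; a
restricted within-site scheme is available and is more conservative. Sites
appear in several rows (reaches pseudo-replicate sites), as is conventional
for this design; the free-permutation p-values should be read accordingly.

## Covariate screening and AICc selection

Candidate fixed-effect sets are screened against the Pearson correlation
matrix (any set containing a pair with |r| > 0.6 is rejected, the offending
pair named) and against VIFs (1/(1−R²) from regressing each covariate on the
others; perfect collinearity reports ∞). Candidates are a priori — default:
the null model, covariate singletons, shade+upstream-temperature, and
shade+upstream+proximity — never a stepwise search. Models are fit by ML,
ranked by AICc with k = fixed effects + residual variance (+ site-intercept
variance when a random intercept is used; the shared constant cancels in
rankings), ties under 1e−6 resolved toward fewer parameters, and the best
model refit by REML for reported coefficients. n is the number of response
rows, acknowledged pseudo-replication included. Ordinary linear and
random-intercept candidates use `statsmodels` (OLS / MixedLM).

## Synthetic-study generator

The generator emulates the experiment, not the physics: there is no energy
balance or discharge model. Hourly temperature is

annual sinusoid (mean 10.5 °C, amplitude 4 °C, peak day-of-year 222)
+ diel sinusoid (summer peak-to-trough 2 °C, damped to 30% in winter,
peak 14:00)
+ site intercept (SD 0.8 °C) + 0.05 °C per-sensor downstream increment
+ per-sensor-per-year offset (SD 0.3 °C; between-year microclimate, the main
source of BACI-scale spread)
+ AR(1) hourly noise shared along the site's four sensors (coefficient 0.7,
innovation SD 0.15 °C) + sensor white noise (SD 0.05 °C).

The thinning effect is added only in the post-treatment year at the
thinned-reach sensor (and ×0.5 by default at the downstream extent) as a
daytime window — cosine ramps 09:00–12:00 and 16:00–19:00 around a full-
amplitude plateau 12:00–16:00 — scaled by a squared seasonal factor that is
normalized to mean 1 over July–September afternoon hours and effectively
vanishes in winter. Because the plateau covers the hours where the daily
maximum occurs, the injected increase in the summer mean daily maximum
equals `effect_dmax_C` (default 2.8 °C) in expectation; daily means rise by
roughly a third of that, and minima are untouched. A pure half-sine window
was rejected because argmax jitter under noise biases the realized
daily-maximum effect a few percent low.

Shade records draw VisSky/GSF from beta distributions around reach means
(baseline closure 95%, effective shade 94%); light records pair a clear-sky
above-canopy curve with a noisy transmission fraction (baseline 6%).
Post-treatment thinned reaches shift by the configured losses/gain
(defaults: closure −16.9, effective shade −23.0, transmission +27.1
percentage points). `pre_start` truncates the pre-treatment year (e.g. a
spring deployment) to exercise the post-only fallback.

Site covariates are drawn from plausible coastal-stream ranges and are
*independent of the injected temperature effects*; consequently the null
(intercept) model should, and does, win the AICc ranking on synthetic
responses — the machinery is exercised, but covariate-effect coupling is not
simulated.

Fixed seed ⇒ bit-identical output (all draws from one seeded generator per
product).

**What passing tests show.** Calibration, recovery and pattern-fidelity
results hold under this generator's assumptions: Gaussian noise, a shared
AR(1) term, effects constant across sites, no weather, no flow, no sensor
drift, no canopy regrowth between post-treatment years. Real data violate
several of these (notably between-site effect heterogeneity and
non-stationary weather), so the simulations validate the estimators'
implementation and their behavior at the design's scale — not field
performance guarantees.

## Problem sizes used in simulations

Replicate counts were chosen to keep Monte-Carlo error well below the
quantities being checked: 200 replicate studies for effect recovery (SE of
the mean ≈ 0.013 °C against a ±0.1 °C band), 1,000 replicates for interval
calibration (SE ≈ 0.007 on a rate of 0.05), 500 repeats × 199 permutations
for PerMANOVA null uniformity, 20 random matrices for the NMS/metric-MDS
bound. The acceptance script uses 50 recovery replicates and 300 calibration
replicates to keep a full from-scratch run near half a minute.
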
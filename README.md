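# streamtherm

Tools for analyzing how riparian forest thinning changes stream shade, light
and thermal regimes, built around a replicated Before–After–Control–Impact
(BACI) design: each of ~10 sites holds an upstream reference reach, a thinned
reach and a downstream reach, monitored with hourly water-temperature loggers
for one pre-treatment and one post-treatment water year, plus hemispherical
photographs (shade) and paired pyranometers (light).

It is written for stream ecologists and forest hydrologists who need more
than a single summer maximum: the package characterizes the whole *thermal
regime* and asks where, when and how strongly thinning changes it — locally,
downstream, and across seasons.

## What it computes

**Thermal-regime descriptors** per (site, reach, water year, season), from
hourly series summarized to daily values:

- *magnitude* — mean daily maximum, MWMT (maximum 7-day mean of daily
  maxima), mean daily mean, MWAT, cumulative degree days, mean daily minimum;
- *variability* — mean and maximum daily range, mean and maximum within-day
  variance;
- *frequency/duration* — days with daily maximum > 16 °C (and > 20 °C) and
  the longest consecutive-day run above each threshold.

Seasons partition the water year (Oct 1–Sep 30): Fall (Oct–Dec), Winter
(Jan–Mar), Spring (Apr–Jun), Summer (Jul–Sep).

**BACI inference.** For each response $y$ the mixed model
$y \sim \mathrm{Reach} + \mathrm{Year} + \mathrm{Reach{\times}Year}$ with a
random site intercept and a separate residual variance per Reach×Year stratum
is fit by direct ML/REML. The treatment effects are the double differences

$$\Delta_{thin} = (T_{post}-T_{pre}) - (U_{post}-U_{pre}), \qquad
  \Delta_{down} = (D_{post}-D_{pre}) - (U_{post}-U_{pre}),$$

with 95% CIs from the Wald $t$ interval or a cluster bootstrap that resamples
whole sites (the studentized bootstrap-t interval by default). An effect is
significant when its CI excludes 0.

**Shade and light.** Canopy closure $(1-\mathrm{VisSky})\cdot100$, effective
shade $(1-\mathrm{GSF})\cdot100$, and percent transmission (daily below- to
above-canopy irradiance totals), summarized to reach-year means and fed
through the same BACI machinery.

**Longitudinal profiles.** Per site and season, the (post − pre) change in a
descriptor (MWMT by default) at every sensor along the channel, anchored to 0
at the upstream-most sensor, with a persists / dissipates / undetectable
trajectory label.

**Multivariate regime structure.** A z-standardized descriptor matrix,
non-metric multidimensional scaling (2-D, Euclidean distances, best of up to
999 restarts, Kruskal stress-1), 95% reach ellipses, and a two-factor
PerMANOVA of Reach, Year and Reach×Year.

**Covariate model selection.** Pearson screening (|r| > 0.6 pruning), VIF
checks, ML fits of a priori candidate models ranked by
$\mathrm{AIC}_c = -2\log L + 2k + 2k(k+1)/(n-k-1)$, REML refit of the best.

**Synthetic studies.** Because field logger records for such experiments are
rarely published, `streamtherm.synth` simulates the whole design — seasonal +
diel temperature structure, AR(1) noise shared along each site, and a
daytime-weighted treatment perturbation that raises summer daily maxima by a
configured amount (half of it persisting downstream) while leaving minima
untouched — with every injected effect recorded for parameter-recovery and
calibration experiments.

## Worked example

```python
import streamtherm as st
from streamtherm import pipeline as pl

cfg = st.SyntheticConfig(seed=1)              # 10 sites, +2.8 degC injected
study = pl.generate_study(cfg)                # temps, shade, light, covariates
table = st.descriptor_table(study.temps)      # seasonal descriptor suite
suite = pl.run_baci_suite(pl.reach_rows(table), 2016, 2018,
                          descriptors=["mwmt", "avg_daily_min"],
                          seasons=("Summer",))
print(suite[["response", "season", "contrast", "estimate",
             "lower", "upper", "significant"]].round(2))
```

prints

```
     response season   contrast  estimate  lower  upper  significant
         mwmt Summer    thinned      2.94   2.60   3.27         True
         mwmt Summer downstream      1.67   1.31   2.04         True
avg_daily_min Summer    thinned     -0.15  -0.49   0.18        False
avg_daily_min Summer downstream      0.13  -0.20   0.45        False
```

The thinned reach warmed (summer MWMT up ~2.9 °C, CI excluding 0, close to
the injected 2.8 °C), roughly half the effect persisted downstream, and daily
minima did not move — the signature of a shade-mediated daytime response.

The same stages are available from the shell:

```bash
streamtherm generate --seed 1 --out study/
streamtherm descriptors --temps study/hourly_temps.csv --out descriptors.csv
streamtherm baci --temps study/hourly_temps.csv --pre 2016 --post 2018 --out baci.csv
streamtherm ordination --temps study/hourly_temps.csv --season Summer --out nms.csv
```

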
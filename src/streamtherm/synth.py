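"""Synthetic BACI study generator with known injected treatment effects.

The generator emulates a replicated three-reach (upstream reference, thinned,
downstream) before-after design: ten sites in three coastal watersheds, four
temperature loggers per site at the reach boundaries, one pre-treatment and
one post-treatment water year of hourly data, plus per-photo hemispherical
shade fractions and paired pyranometer records.

Hourly temperature is an annual sinusoid (coastal peak in early August) plus
a seasonally modulated diel sinusoid (afternoon peak, largest range in
summer), a site random intercept, a small downstream warming increment per
sensor, a per-sensor-per-year offset representing between-year microclimate
differences, AR(1) noise shared along a site's sensors, and sensor-specific
white noise.

The thinning effect is applied in the post-treatment year only, to the
thinned-reach sensor (and a configurable fraction of it to the downstream
sensor), as a daytime perturbation: a trapezoidal window with cosine ramps
(zero before 09:00 and after 19:00, full amplitude 12:00-16:00), scaled by a
seasonal factor that peaks in midsummer and vanishes in winter.  The window
covers the hours where the diel maximum occurs, so the injected increase in
the summer mean daily maximum equals ``effect_dmax_C`` in expectation while
daily minima are untouched and daily means rise by roughly a third of the
maximum effect.  Every injected quantity is recorded in ``SyntheticTruth``.

No energy-balance or discharge modeling is attempted; noise parameters are
free knobs chosen to give response-scale spread comparable to a 10-site
field study, not estimates of any real stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io import HourlyTempSeries

#: sensor index -> (reach, position) labels; boundary sensors are shared
#: between adjacent reaches and labeled by the reach whose extent they close
SENSOR_LAYOUT = (
    ("upstream", "reach_top"),
    ("upstream", "reach_bottom"),
    ("thinned", "reach_bottom"),
    ("downstream", "reach_bottom"),
)

_DEFAULT_WATERSHEDS = (
    "WestForkTectah",
    "WestForkTectah",
    "WestForkTectah",
    "WestForkTectah",
    "WestForkTectah",
    "EastForkTectah",
    "EastForkTectah",
    "EastForkTectah",
    "LostMan",
    "LostMan",
)

#: day-of-year of the annual temperature peak (early August, coastal lag)
_ANNUAL_PEAK_DOY = 222.0
#: hour of the diel temperature peak
_DIEL_PEAK_HOUR = 14.0


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Temperatures in degC, lengths in m, shade/light quantities in percent
    (percentage points for effect sizes).  ``years`` are the pre- and
    post-treatment water-year labels.  A fixed ``seed`` makes every output
    bit-identical.
    """

    seed: int = 0
    n_sites: int = 10
    watershed_labels: Sequence[str] = _DEFAULT_WATERSHEDS
    sensors_per_site: int = 4
    reach_lengths_m: tuple[float, float, float] = (150.0, 200.0, 150.0)
    years: tuple[int, int] = (2016, 2018)
    baseline_annual_mean_C: float = 10.5
    annual_amplitude_C: float = 4.0
    diel_amplitude_summer_C: float = 2.0
    ar1_coef: float = 0.7
    noise_sd_C: float = 0.15
    sensor_noise_sd_C: float = 0.05
    site_sd_C: float = 0.8
    sensor_year_sd_C: float = 0.3
    reach_increment_C: float = 0.05
    effect_dmax_C: float = 2.8
    effect_downstream_fraction: float = 0.5
    shade_loss_closure_pct: float = 16.9
    shade_loss_effective_pct: float = 23.0
    light_gain_pct: float = 27.1
    pre_closure_mean_pct: float = 95.0
    pre_effective_shade_pct: float = 94.0
    pre_transmission_pct: float = 6.0
    photos_per_reach: tuple[int, int] = (10, 22)
    pyranometers_per_reach: int = 4
    pre_start: str | None = None  # e.g. "2016-04-01" truncates the pre year

    def __post_init__(self) -> None:
        for name in (
            "baseline_annual_mean_C",
            "annual_amplitude_C",
            "diel_amplitude_summer_C",
            "noise_sd_C",
            "effect_dmax_C",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must lie in [0, 1)")
        if not 0 <= self.effect_downstream_fraction <= 1:
            raise ValueError("effect_downstream_fraction must lie in [0, 1]")
        if len(self.watershed_labels) != self.n_sites:
            raise ValueError("watershed_labels must name one watershed per site")
        if self.sensors_per_site != 4:
            raise ValueError("the three-reach layout requires 4 boundary sensors")
        if self.years[0] >= self.years[1]:
            raise ValueError("pre-treatment water year must precede post-treatment")
        for name in (
            "pre_closure_mean_pct",
            "pre_effective_shade_pct",
            "pre_transmission_pct",
            "shade_loss_closure_pct",
            "shade_loss_effective_pct",
            "light_gain_pct",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100]")

    @property
    def site_ids(self) -> list[str]:
        counts: dict[str, int] = {}
        out = []
        for w in self.watershed_labels:
            counts[w] = counts.get(w, 0) + 1
            out.append(f"{w}_{counts[w]}")
        return out

    @property
    def sensor_distances_m(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.reach_lengths_m)])


@dataclass
class SyntheticTruth:
    """Injected effect sizes and the generator parameters actually used."""

    effects: dict
    config: dict = field(default_factory=dict)


def _water_year_index(wy: int) -> pd.DatetimeIndex:
    return pd.date_range(f"{wy - 1}-10-01", f"{wy}-09-30 23:00", freq="h")


def _annual_norm(doy: np.ndarray) -> np.ndarray:
    """Seasonal factor in [0, 1], peaking at the annual temperature maximum."""
    return 0.5 + 0.5 * np.cos(2 * np.pi * (doy - _ANNUAL_PEAK_DOY) / 365.25)


def _daytime_weight(hour: np.ndarray) -> np.ndarray:
    """Trapezoidal daytime window: cosine ramps 09-12 and 16-19, plateau 12-16."""
    w = np.zeros_like(hour, dtype=float)
    up = (hour >= 9) & (hour < 12)
    w[up] = 0.5 * (1 - np.cos(np.pi * (hour[up] - 9) / 3))
    w[(hour >= 12) & (hour <= 16)] = 1.0
    down = (hour > 16) & (hour <= 19)
    w[down] = 0.5 * (1 - np.cos(np.pi * (19 - hour[down]) / 3))
    return w


def _base_signal(cfg: SyntheticConfig, time: pd.DatetimeIndex) -> np.ndarray:
    doy = time.dayofyear.to_numpy(float)
    hour = time.hour.to_numpy(float)
    annual = cfg.baseline_annual_mean_C + cfg.annual_amplitude_C * np.cos(
        2 * np.pi * (doy - _ANNUAL_PEAK_DOY) / 365.25
    )
    diel_range = cfg.diel_amplitude_summer_C * (0.3 + 0.7 * _annual_norm(doy))
    diel = 0.5 * diel_range * np.cos(2 * np.pi * (hour - _DIEL_PEAK_HOUR) / 24)
    return annual + diel


def _perturbation(cfg: SyntheticConfig, time: pd.DatetimeIndex) -> np.ndarray:
    """Unit treatment perturbation: summer mean daily-maximum effect is 1 degC."""
    doy = time.dayofyear.to_numpy(float)
    hour = time.hour.to_numpy(float)
    seasonal = _annual_norm(doy) ** 2
    # normalize so the July-September mean of the daily plateau value is 1
    summer = (time.month >= 7) & (time.month <= 9)
    at_peak = hour == _DIEL_PEAK_HOUR
    scale = seasonal[summer & at_peak].mean()
    return (seasonal / scale) * _daytime_weight(hour)


def _ar1(rng: np.random.Generator, n: int, coef: float, sd: float) -> np.ndarray:
    from scipy.signal import lfilter

    innov = rng.normal(0.0, sd, n)
    return lfilter([1.0], [1.0, -coef], innov)


def generate_hourly_temperature(
    cfg: SyntheticConfig,
) -> tuple[list[HourlyTempSeries], SyntheticTruth]:
    """Simulate hourly temperatures for every site, sensor and water year."""
    rng = np.random.default_rng([int(cfg.seed), 0])
    site_ids = cfg.site_ids
    distances = cfg.sensor_distances_m
    pre_wy, post_wy = cfg.years

    site_eff = rng.normal(0.0, cfg.site_sd_C, cfg.n_sites)
    sensor_year = rng.normal(0.0, cfg.sensor_year_sd_C, (cfg.n_sites, 4, 2))

    # treatment multiplier per sensor: thinned-reach bottom gets the full
    # effect, the downstream extent a configured fraction, reference sensors 0
    effect_mult = np.array([0.0, 0.0, 1.0, cfg.effect_downstream_fraction])

    times, bases, perts = {}, {}, {}
    for k, wy in enumerate(cfg.years):
        t = _water_year_index(wy)
        times[wy] = t
        bases[wy] = _base_signal(cfg, t)
        perts[wy] = _perturbation(cfg, t) if k == 1 else 0.0

    series: list[HourlyTempSeries] = []
    for i, site in enumerate(site_ids):
        for k, wy in enumerate(cfg.years):
            t = times[wy]
            shared = _ar1(rng, len(t), cfg.ar1_coef, cfg.noise_sd_C)
            for j in range(4):
                reach, position = SENSOR_LAYOUT[j]
                temp = (
                    bases[wy]
                    + site_eff[i]
                    + cfg.reach_increment_C * j
                    + sensor_year[i, j, k]
                    + shared
                    + rng.normal(0.0, cfg.sensor_noise_sd_C, len(t))
                )
                if k == 1 and effect_mult[j] > 0:
                    temp = temp + cfg.effect_dmax_C * effect_mult[j] * perts[wy]
                tt, temp = t, temp
                if k == 0 and cfg.pre_start is not None:
                    keep = tt >= pd.Timestamp(cfg.pre_start)
                    tt, temp = tt[keep], temp[keep]
                series.append(
                    HourlyTempSeries(
                        watershed=cfg.watershed_labels[i],
                        site=site,
                        reach=reach,
                        position=position,
                        distance_m=float(distances[j]),
                        time=tt,
                        temp_c=temp,
                    )
                )

    pert_mean = float(np.mean(_daytime_weight(np.arange(24.0))))
    truth = SyntheticTruth(
        effects={
            "thinned": {
                "summer_avg_daily_max": cfg.effect_dmax_C,
                "summer_avg_daily_mean": cfg.effect_dmax_C * pert_mean,
                "summer_avg_daily_min": 0.0,
                "winter_avg_daily_max": 0.0,
            },
            "downstream": {
                "summer_avg_daily_max": cfg.effect_dmax_C
                * cfg.effect_downstream_fraction,
                "summer_avg_daily_min": 0.0,
            },
            "shade_light": {
                "canopy_closure_pct": -cfg.shade_loss_closure_pct,
                "effective_shade_pct": -cfg.shade_loss_effective_pct,
                "transmission_pct": cfg.light_gain_pct,
            },
        },
        config=asdict(cfg),
    )
    return series, truth


def _beta_around(rng: np.random.Generator, mean: np.ndarray, n: int, conc: float = 150.0):
    mean = np.clip(mean, 1e-3, 1 - 1e-3)
    return rng.beta(mean * conc, (1 - mean) * conc, n)


def generate_shade_light(cfg: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-photo shade fractions and paired hourly pyranometer records.

    Thinned-reach post-treatment means are shifted by the configured shade
    losses and light gain; reference and downstream reaches keep their
    pre-treatment means.  VisSky/GSF use beta noise around the reach mean;
    below-canopy irradiance is the above-canopy curve times a noisy
    transmission fraction.
    """
    rng = np.random.default_rng([int(cfg.seed), 1])
    hours = np.arange(24.0)
    above = np.where(
        (hours >= 6) & (hours <= 18), 900.0 * np.sin(np.pi * (hours - 6) / 12), 0.0
    )

    shade_rows, light_rows = [], []
    for site in cfg.site_ids:
        for reach in ("upstream", "thinned", "downstream"):
            for k, year in enumerate(cfg.years):
                treated = k == 1 and reach == "thinned"
                closure = cfg.pre_closure_mean_pct - (
                    cfg.shade_loss_closure_pct if treated else 0.0
                )
                eff_shade = cfg.pre_effective_shade_pct - (
                    cfg.shade_loss_effective_pct if treated else 0.0
                )
                trans = cfg.pre_transmission_pct + (
                    cfg.light_gain_pct if treated else 0.0
                )
                n_photo = int(rng.integers(cfg.photos_per_reach[0], cfg.photos_per_reach[1] + 1))
                vis_sky = _beta_around(rng, 1 - closure / 100.0, n_photo)
                gsf = _beta_around(rng, 1 - eff_shade / 100.0, n_photo)
                for p in range(n_photo):
                    shade_rows.append(
                        {
                            "site": site,
                            "reach": reach,
                            "year": year,
                            "photo": p + 1,
                            "vis_sky": vis_sky[p],
                            "gsf": gsf[p],
                        }
                    )
                for p in range(cfg.pyranometers_per_reach):
                    frac = np.clip(
                        (trans / 100.0) * rng.lognormal(0.0, 0.15), 0.0, 1.0
                    )
                    below = above * frac
                    for h in range(24):
                        light_rows.append(
                            {
                                "site": site,
                                "reach": reach,
                                "year": year,
                                "pyranometer": p + 1,
                                "hour": h,
                                "below_wm2": below[h],
                                "above_wm2": above[h],
                            }
                        )
    return pd.DataFrame(shade_rows), pd.DataFrame(light_rows)


def generate_covariates(cfg: SyntheticConfig) -> pd.DataFrame:
    """Plausible physical covariates and ancillary summaries per site."""
    rng = np.random.default_rng([int(cfg.seed), 2])
    n = cfg.n_sites
    dist = np.sort(rng.uniform(100, 4000, n))
    df = pd.DataFrame(
        {
            "watershed": list(cfg.watershed_labels),
            "site": cfg.site_ids,
            "distance_upstream_m": dist,
            "reach_length_m": float(np.sum(cfg.reach_lengths_m)),
            "bankfull_width_m": rng.uniform(3.0, 7.0, n).round(1),
            "aspect_deg": rng.uniform(0.0, 360.0, n).round(0),
            "gradient_pct": rng.uniform(1.0, 7.0, n).round(1),
            "elevation_m": (350 + dist * 0.03 + rng.normal(0, 10, n)).round(1),
            "proximity_upstream_treatment_m": rng.uniform(0, 2000, n).round(0),
            "air_temp_mean_C": rng.normal(14.0, 1.0, n).round(2),
            "upstream_temp_mean_C": (
                cfg.baseline_annual_mean_C
                + cfg.annual_amplitude_C * 0.9
                + rng.normal(0, 0.5, n)
            ).round(2),
        }
    )
    return df


def simulate_baci_table(
    rng: np.random.Generator,
    n_sites: int = 10,
    cell_means: np.ndarray | None = None,
    sigma_site: float = 0.5,
    sigma_cells: np.ndarray | float = 0.3,
) -> pd.DataFrame:
    """Response-level BACI study: one value per (site, reach, year) cell.

    ``cell_means`` is a 3x2 array over (upstream, thinned, downstream) x
    (pre, post); ``sigma_cells`` gives per-cell residual SDs (scalar or 3x2).
    Used for calibration studies where simulating full hourly series would
    add nothing.
    """
    reaches = ("upstream", "thinned", "downstream")
    years = ("pre", "post")
    if cell_means is None:
        cell_means = np.zeros((3, 2))
    sigma_cells = np.broadcast_to(np.asarray(sigma_cells, float), (3, 2))
    site_eff = rng.normal(0.0, sigma_site, n_sites)
    rows = []
    for s in range(n_sites):
        for r, reach in enumerate(reaches):
            for y, year in enumerate(years):
                rows.append(
                    {
                        "site": f"S{s + 1}",
                        "reach": reach,
                        "year": year,
                        "value": cell_means[r, y]
                        + site_eff[s]
                        + rng.normal(0.0, sigma_cells[r, y]),
                    }
                )
    return pd.DataFrame(rows)
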
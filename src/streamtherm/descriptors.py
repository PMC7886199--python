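"""Thermal-regime descriptors from hourly water-temperature series.

Hourly records are first condensed to daily summaries (max, min, mean, range
and within-day variance of the hourly values), assigned to water-year seasons,
and then summarized per season into the descriptor suite used throughout the
pipeline:

magnitude
    average daily maximum, MWMT (maximum 7-consecutive-day mean of daily
    maxima), average daily mean, MWAT (same statistic on daily means),
    cumulative degree days (base 0 degC), average daily minimum;
variability
    average daily range, maximum daily range, average within-day variance,
    maximum within-day variance;
frequency / duration
    days with daily maximum above a threshold (16 and 20 degC by default) and
    the longest run of consecutive such days.

Seasons partition the water year (Oct 1 - Sep 30, labeled by the ending
calendar year): Fall Oct-Dec, Winter Jan-Mar, Spring Apr-Jun, Summer Jul-Sep.

A day qualifies when at least ``min_completeness`` of its 24 hours are present
and pass QA (default 0.9); weekly windows containing a non-qualifying day are
skipped.  The exceedance thresholds are regulatory cold-water criteria applied
to the daily maximum (configurable to the daily mean).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import HourlyTempSeries

SEASONS = ("Fall", "Winter", "Spring", "Summer")

#: calendar months belonging to each season of the water year
SEASON_MONTHS = {
    "Fall": (10, 11, 12),
    "Winter": (1, 2, 3),
    "Spring": (4, 5, 6),
    "Summer": (7, 8, 9),
}

_MONTH_TO_SEASON = {m: s for s, months in SEASON_MONTHS.items() for m in months}

MAGNITUDE = [
    "avg_daily_max",
    "mwmt",
    "avg_daily_mean",
    "mwat",
    "degree_days",
    "avg_daily_min",
]
VARIABILITY = ["avg_daily_range", "max_daily_range", "avg_variance", "max_variance"]
FREQUENCY_DURATION = ["days_gt_16", "consec_days_gt_16", "days_gt_20", "consec_days_gt_20"]

#: the named descriptor suite, in reporting order
DESCRIPTORS = MAGNITUDE + VARIABILITY + FREQUENCY_DURATION


def water_year(dates: pd.DatetimeIndex | pd.Series) -> np.ndarray:
    """Water year containing each date: Oct 1 of N-1 through Sep 30 of N -> N."""
    dates = pd.DatetimeIndex(dates)
    return np.where(dates.month >= 10, dates.year + 1, dates.year)


def assign_season(dates: pd.DatetimeIndex | pd.Series) -> pd.DataFrame:
    """Water-year and season labels for each date."""
    dates = pd.DatetimeIndex(dates)
    season = pd.Series(dates.month, dtype=int).map(_MONTH_TO_SEASON).to_numpy()
    return pd.DataFrame({"water_year": water_year(dates), "season": season})


def daily_summaries(
    series: HourlyTempSeries, min_completeness: float = 0.9
) -> pd.DataFrame:
    """Summarize one hourly series into per-day statistics.

    Returns one row per calendar day present in the record with columns
    ``date, tmax, tmin, tmean, trange, tvar, n_hours, qualifies``.  Days with
    fewer than ``min_completeness * 24`` valid hours are retained but marked
    ``qualifies=False``; they are excluded from all seasonal statistics.
    Within-day variance is the sample variance (n-1) of the day's hourly
    values.
    """
    if len(series.temp_c) == 0:
        raise ValueError(f"empty series for sensor {series.sensor_id}")
    mask = series.valid
    time = series.time[mask]
    temp = series.temp_c[mask]
    if len(temp) == 0:
        raise ValueError(f"no valid hours for sensor {series.sensor_id}")

    day = time.normalize()
    codes, uniques = pd.factorize(day, sort=True)
    order = np.argsort(codes, kind="stable")
    codes_s, temp_s = codes[order], temp[order]
    starts = np.searchsorted(codes_s, np.arange(len(uniques)))
    ends = np.append(starts[1:], len(temp_s))

    n = (ends - starts).astype(float)
    sums = np.add.reduceat(temp_s, starts)
    sq = np.add.reduceat(temp_s**2, starts)
    tmax = np.maximum.reduceat(temp_s, starts)
    tmin = np.minimum.reduceat(temp_s, starts)
    tmean = sums / n
    # sample variance, guarded for single-hour days
    with np.errstate(invalid="ignore", divide="ignore"):
        tvar = np.where(n > 1, (sq - n * tmean**2) / (n - 1), np.nan)
    tvar = np.clip(tvar, 0.0, None)

    return pd.DataFrame(
        {
            "date": pd.DatetimeIndex(uniques),
            "tmax": tmax,
            "tmin": tmin,
            "tmean": tmean,
            "trange": tmax - tmin,
            "tvar": tvar,
            "n_hours": n.astype(int),
            "qualifies": n >= min_completeness * 24,
        }
    )


def _season_bounds(wy: int, season: str) -> tuple[pd.Timestamp, pd.Timestamp]:
    months = SEASON_MONTHS[season]
    year = wy - 1 if season == "Fall" else wy
    start = pd.Timestamp(year=year, month=months[0], day=1)
    return start, start + pd.offsets.MonthEnd(3)


def _season_arrays(daily: pd.DataFrame, wy: int, season: str) -> dict[str, np.ndarray]:
    """Daily statistics on the season's full calendar grid; missing days NaN."""
    start, end = _season_bounds(wy, season)
    n = (end - start).days + 1
    dates = daily["date"].to_numpy("datetime64[D]")
    offsets = (dates - np.datetime64(start, "D")).astype(int)
    keep = (offsets >= 0) & (offsets < n) & daily["qualifies"].to_numpy()
    idx = offsets[keep]
    out = {}
    for col in ("tmax", "tmin", "tmean", "trange", "tvar"):
        v = np.full(n, np.nan)
        v[idx] = daily[col].to_numpy(float)[keep]
        out[col] = v
    return out


def _season_grid(daily: pd.DataFrame, wy: int, season: str) -> pd.DataFrame:
    """DataFrame view of :func:`_season_arrays`, indexed by date."""
    start, end = _season_bounds(wy, season)
    return pd.DataFrame(
        _season_arrays(daily, wy, season), index=pd.date_range(start, end, freq="D")
    )


def weekly_max_statistics(
    daily: pd.DataFrame, wy: int, season: str
) -> tuple[float, float]:
    """MWMT and MWAT for one season.

    MWMT is the maximum over all 7-consecutive-calendar-day windows lying
    fully inside the season of the mean of daily maxima; MWAT is the same
    statistic on daily means.  Windows containing a non-qualifying or missing
    day are skipped; with no qualifying window both are NaN.
    """
    arrs = _season_arrays(daily, wy, season)
    return _weekly_max(arrs["tmax"]), _weekly_max(arrs["tmean"])


def _weekly_max(v: np.ndarray) -> float:
    if len(v) < 7:
        return np.nan
    win = np.lib.stride_tricks.sliding_window_view(v, 7)
    means = win.mean(axis=1)  # NaN if any day in the window is missing
    return np.nan if np.all(np.isnan(means)) else float(np.nanmax(means))


def degree_days(daily: pd.DataFrame, wy: int, season: str) -> float:
    """Cumulative degree days: sum of qualifying daily means (base 0 degC)."""
    v = _season_arrays(daily, wy, season)["tmean"]
    if np.all(np.isnan(v)):
        raise ValueError(f"no qualifying days in {season} WY{wy}")
    return float(np.nansum(v))


def threshold_exceedance(
    daily: pd.DataFrame,
    wy: int,
    season: str,
    threshold: float,
    on: str = "tmax",
) -> tuple[int, int]:
    """Days above a threshold and the longest consecutive-day run.

    Counts days whose daily maximum (default; configurable to the daily mean)
    strictly exceeds ``threshold``.  Runs are over consecutive calendar days;
    a missing or non-qualifying day breaks a run.
    """
    v = _season_arrays(daily, wy, season)[on]
    return _exceedance(v, threshold)


def _exceedance(v: np.ndarray, threshold: float) -> tuple[int, int]:
    above = np.where(np.isnan(v), False, v > threshold)
    days = int(above.sum())
    longest = run = 0
    for a in above:
        run = run + 1 if a else 0
        longest = max(longest, run)
    return days, longest


def regime_descriptors(
    daily: pd.DataFrame,
    wy: int,
    season: str,
    thresholds: Sequence[float] = (16.0, 20.0),
    exceed_on: str = "tmax",
    min_season_coverage: float = 0.8,
) -> dict:
    """The full descriptor vector for one (water year, season).

    Returns a dict of descriptor values plus ``n_days`` (qualifying days) and
    a ``flag`` field: ``"ok"``, ``"low_coverage"`` when fewer than
    ``min_season_coverage`` of the season's days qualify, or ``"missing"``
    when no day qualifies (all values NaN).
    """
    arrs = _season_arrays(daily, wy, season)
    tmax = arrs["tmax"]
    n_days = int(np.sum(~np.isnan(tmax)))
    season_len = len(tmax)
    out: dict = {"water_year": wy, "season": season, "n_days": n_days}
    if n_days == 0:
        out.update({d: np.nan for d in DESCRIPTORS})
        out["flag"] = "missing"
        return out

    out["avg_daily_max"] = float(np.nanmean(tmax))
    out["mwmt"] = _weekly_max(tmax)
    out["avg_daily_mean"] = float(np.nanmean(arrs["tmean"]))
    out["mwat"] = _weekly_max(arrs["tmean"])
    out["degree_days"] = float(np.nansum(arrs["tmean"]))
    out["avg_daily_min"] = float(np.nanmean(arrs["tmin"]))
    out["avg_daily_range"] = float(np.nanmean(arrs["trange"]))
    out["max_daily_range"] = float(np.nanmax(arrs["trange"]))
    out["avg_variance"] = float(np.nanmean(arrs["tvar"]))
    out["max_variance"] = float(np.nanmax(arrs["tvar"]))
    for thr in thresholds:
        days, consec = _exceedance(arrs[exceed_on], thr)
        key = f"{int(thr)}" if float(thr).is_integer() else f"{thr}"
        out[f"days_gt_{key}"] = days
        out[f"consec_days_gt_{key}"] = consec
    out["flag"] = "ok" if n_days >= min_season_coverage * season_len else "low_coverage"
    return out


def descriptor_table(
    series: Iterable[HourlyTempSeries],
    min_completeness: float = 0.9,
    thresholds: Sequence[float] = (16.0, 20.0),
    exceed_on: str = "tmax",
) -> pd.DataFrame:
    """Descriptor vectors for every sensor and (water year, season) present.

    One row per (watershed, site, reach, position, water_year, season) with
    descriptor columns; the basis of the BACI, profile and ordination stages.
    """
    rows = []
    for s in series:
        daily = daily_summaries(s, min_completeness=min_completeness)
        labels = assign_season(daily["date"])
        for (wy, season), _ in daily.groupby(
            [labels["water_year"].to_numpy(), labels["season"].to_numpy()]
        ):
            rec = regime_descriptors(
                daily, int(wy), str(season), thresholds=thresholds, exceed_on=exceed_on
            )
            rec.update(
                watershed=s.watershed,
                site=s.site,
                reach=s.reach,
                position=s.position,
                distance_m=s.distance_m,
            )
            rows.append(rec)
    df = pd.DataFrame(rows)
    key = ["watershed", "site", "reach", "position", "distance_m", "water_year", "season"]
    return df[key + [c for c in df.columns if c not in key]].sort_values(key).reset_index(
        drop=True
    )


def descriptor_long(table: pd.DataFrame) -> pd.DataFrame:
    """Melt a descriptor table to long (…, descriptor, value, flag) form."""
    keys = [
        "watershed",
        "site",
        "reach",
        "position",
        "distance_m",
        "water_year",
        "season",
        "flag",
    ]
    value_cols = [c for c in table.columns if c not in keys + ["n_days"]]
    long = table.melt(id_vars=keys, value_vars=value_cols, var_name="descriptor")
    return long.sort_values(keys + ["descriptor"]).reset_index(drop=True)
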
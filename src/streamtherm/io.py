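"""Readers, writers and validated containers for the pipeline's tabular data.

All downstream modules consume the containers defined here; nothing else in
the package touches raw files.  CSVs are comma-separated UTF-8 with "."
decimals, timestamps in ISO 8601 local standard time (loggers run on a fixed
UTC offset, so no DST transitions are assumed).

Hourly water temperatures pass a plausibility screen on read: values outside
[-1, 40] degC are flagged invalid but retained, so the QA report can name
them; daily summaries later treat flagged hours as missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("streamtherm")

REACHES = ("upstream", "thinned", "downstream")
POSITIONS = ("reach_top", "reach_bottom")

#: plausibility bounds for water temperature after QA, degC
TEMP_BOUNDS = (-1.0, 40.0)

TEMP_COLUMNS = [
    "watershed",
    "site",
    "reach",
    "position",
    "distance_m",
    "timestamp",
    "temp_c",
]

SITE_COLUMNS = [
    "watershed",
    "site",
    "distance_upstream_m",
    "reach_length_m",
    "bankfull_width_m",
    "aspect_deg",
    "gradient_pct",
    "elevation_m",
]

SHADE_COLUMNS = ["site", "reach", "year", "photo", "vis_sky", "gsf"]
LIGHT_COLUMNS = ["site", "reach", "year", "pyranometer", "hour", "below_wm2", "above_wm2"]


class SchemaError(ValueError):
    """A table does not match its documented schema."""


@dataclass
class HourlyTempSeries:
    """One logger's hourly water-temperature record.

    ``time`` is strictly increasing at hourly spacing except across recorded
    ``gaps``; ``valid`` marks hours inside the plausibility bounds.
    """

    watershed: str
    site: str
    reach: str
    position: str
    distance_m: float
    time: pd.DatetimeIndex
    temp_c: np.ndarray
    gaps: list = field(default_factory=list)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.reach not in REACHES:
            raise SchemaError(f"unknown reach label {self.reach!r}")
        if self.position not in POSITIONS:
            raise SchemaError(f"unknown sensor position {self.position!r}")
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        if len(self.time) != len(self.temp_c):
            raise SchemaError("time and temperature lengths differ")
        if len(self.time) > 1 and not self.time.is_monotonic_increasing:
            raise SchemaError(f"timestamps not increasing for sensor {self.sensor_id}")
        if self.valid is None:
            lo, hi = TEMP_BOUNDS
            self.valid = (self.temp_c >= lo) & (self.temp_c <= hi)

    @property
    def sensor_id(self) -> str:
        return f"{self.site}:{self.reach}:{self.position}"

    @property
    def n_flagged(self) -> int:
        return int((~self.valid).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "watershed": self.watershed,
                "site": self.site,
                "reach": self.reach,
                "position": self.position,
                "distance_m": self.distance_m,
                "timestamp": self.time,
                "temp_c": self.temp_c,
            }
        )


def _find_gaps(time: pd.DatetimeIndex) -> list:
    """Intervals longer than one hour between consecutive samples."""
    if len(time) < 2:
        return []
    dt = np.diff(time.asi8) / 3.6e12  # hours
    gaps = []
    for i in np.nonzero(dt > 1.0)[0]:
        gaps.append((time[i], time[i + 1]))
    return gaps


def read_hourly_temps(path: str | Path) -> list[HourlyTempSeries]:
    """Read an hourly temperature CSV into per-sensor series.

    Raises on malformed timestamps and duplicate (sensor, timestamp) rows;
    gaps are recorded on each series, out-of-bounds values flagged (never
    silently dropped).
    """
    df = pd.read_csv(path)
    missing = set(TEMP_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: malformed timestamp ({exc})") from None

    out: list[HourlyTempSeries] = []
    for (site, reach, position), grp in df.groupby(
        ["site", "reach", "position"], sort=True
    ):
        grp = grp.sort_values("timestamp")
        dup = grp["timestamp"].duplicated()
        if dup.any():
            first = grp.loc[dup, "timestamp"].iloc[0]
            raise SchemaError(
                f"duplicate timestamp {first} for sensor {site}:{reach}:{position}"
            )
        time = pd.DatetimeIndex(grp["timestamp"])
        series = HourlyTempSeries(
            watershed=str(grp["watershed"].iloc[0]),
            site=str(site),
            reach=str(reach),
            position=str(position),
            distance_m=float(grp["distance_m"].iloc[0]),
            time=time,
            temp_c=grp["temp_c"].to_numpy(float),
            gaps=_find_gaps(time),
        )
        if series.n_flagged:
            logger.warning(
                "%d hour(s) outside plausibility bounds for %s",
                series.n_flagged,
                series.sensor_id,
            )
        out.append(series)
    logger.info("read %d sensor series (%d rows) from %s", len(out), len(df), path)
    return out


def write_hourly_temps(series: Iterable[HourlyTempSeries], path: str | Path) -> None:
    """Write series to the canonical hourly CSV (round-trip stable)."""
    frames = [s.to_frame() for s in series]
    df = pd.concat(frames, ignore_index=True)
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False, float_format="%.4f")


def read_site_covariates(path: str | Path) -> pd.DataFrame:
    """Read and validate the physical site-characteristics table."""
    df = pd.read_csv(path)
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    if (df["gradient_pct"] < 0).any():
        raise SchemaError("gradient must be non-negative")
    if ((df["aspect_deg"] < 0) | (df["aspect_deg"] >= 360)).any():
        raise SchemaError("aspect must lie in [0, 360)")
    return df


def load_site_characteristics() -> pd.DataFrame:
    """Packaged physical characteristics of the ten experimental sites."""
    with resources.as_file(
        resources.files("streamtherm.data") / "site_characteristics.csv"
    ) as p:
        return read_site_covariates(p)


def read_shade_records(path: str | Path) -> pd.DataFrame:
    """Read per-photo hemispherical shade fractions (VisSky, GSF in [0, 1])."""
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("shade file %s is empty", path)
        return pd.DataFrame(columns=SHADE_COLUMNS)
    missing = set(SHADE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    for col in ("vis_sky", "gsf"):
        bad = df[(df[col] < 0) | (df[col] > 1)]
        if len(bad):
            raise SchemaError(
                f"{path}: {col} outside [0, 1] at row(s) {bad.index[:5].tolist()}"
            )
    return df


def read_light_records(path: str | Path) -> pd.DataFrame:
    """Read paired above-/below-canopy hourly irradiance records."""
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("light file %s is empty", path)
        return pd.DataFrame(columns=LIGHT_COLUMNS)
    missing = set(LIGHT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    if (df[["below_wm2", "above_wm2"]] < 0).any().any():
        raise SchemaError(f"{path}: irradiance must be non-negative")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def series_to_long(series: Sequence[HourlyTempSeries]) -> pd.DataFrame:
    """Stack sensor series into one long frame (used by the CLI stages)."""
    return pd.concat([s.to_frame() for s in series], ignore_index=True)
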
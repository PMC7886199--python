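"""Longitudinal profiles of pre-post temperature change along a site.

For each site and season the (post - pre) change in a descriptor (MWMT by
default) is computed at every sensor along the channel and anchored to zero
at the upstream-most sensor, so profiles are comparable across sites.  A
simple trajectory classifier quantifies whether a local increase persists to
the downstream extent, dissipates before it, or is undetectable; the
50%-of-peak rule and the detection tolerance are explicit, configurable
quantifications of patterns that are otherwise described only qualitatively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class LongitudinalProfile:
    site: str
    season: str
    descriptor: str
    distances_m: np.ndarray
    anchored_delta: np.ndarray
    reaches: list[str]
    water_years: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.distances_m = np.asarray(self.distances_m, float)
        self.anchored_delta = np.asarray(self.anchored_delta, float)
        if len(self.distances_m) != len(self.anchored_delta):
            raise ValueError("distances and deltas must align")
        if len(self.distances_m) > 1 and not np.all(np.diff(self.distances_m) > 0):
            raise ValueError("sensor positions must strictly increase downstream")
        if abs(self.anchored_delta[0]) > 1e-12:
            raise ValueError("profile must be anchored to 0 at the upstream-most sensor")


def anchor(deltas: np.ndarray) -> np.ndarray:
    """Subtract the upstream-most value; idempotent."""
    deltas = np.asarray(deltas, float)
    return deltas - deltas[0]


def build_profile(
    descriptor_table: pd.DataFrame,
    site: str,
    season: str,
    descriptor: str = "mwmt",
    pre_year: int | None = None,
    post_year: int | None = None,
) -> LongitudinalProfile:
    """Anchored (post - pre) profile over a site's sensors for one season.

    ``descriptor_table`` is the sensor-level output of
    :func:`streamtherm.descriptors.descriptor_table`.  Requires the chosen
    descriptor pre and post at >= 2 sensors including the upstream-most.
    """
    sub = descriptor_table[
        (descriptor_table["site"] == site) & (descriptor_table["season"] == season)
    ]
    if sub.empty:
        raise ValueError(f"no descriptor rows for site {site!r}, season {season!r}")
    years = sorted(sub["water_year"].unique())
    pre_year = pre_year if pre_year is not None else years[0]
    post_year = post_year if post_year is not None else years[-1]
    wide = sub.pivot_table(
        index=["distance_m", "reach"], columns="water_year", values=descriptor
    ).sort_index()
    wide = wide.dropna(subset=[pre_year, post_year])
    if len(wide) < 2:
        raise ValueError(f"need {descriptor} pre and post at >= 2 sensors")
    dist = wide.index.get_level_values("distance_m").to_numpy(float)
    min_dist = sub["distance_m"].min()
    if dist[0] != min_dist:
        raise ValueError("anchor sensor (upstream-most) is missing this descriptor")
    delta = (wide[post_year] - wide[pre_year]).to_numpy(float)
    return LongitudinalProfile(
        site=site,
        season=season,
        descriptor=descriptor,
        distances_m=dist,
        anchored_delta=anchor(delta),
        reaches=list(wide.index.get_level_values("reach")),
        water_years=(int(pre_year), int(post_year)),
    )


def classify_trajectory(profile: LongitudinalProfile, tol: float = 0.2) -> str:
    """Label a profile 'persists', 'dissipates' or 'undetectable'.

    Undetectable when no anchored change exceeds ``tol`` (degC) in absolute
    value; otherwise 'persists' when the final (downstream-extent) value
    retains at least half the peak change, 'dissipates' when it does not.
    """
    d = profile.anchored_delta
    if len(d) < 3:
        raise ValueError("trajectory classification needs >= 3 points")
    if np.max(np.abs(d)) <= tol:
        return "undetectable"
    peak = d[np.argmax(np.abs(d))]
    return "persists" if d[-1] / peak >= 0.5 else "dissipates"


def profile_table(profiles: list[LongitudinalProfile]) -> pd.DataFrame:
    """Stack profiles into a long CSV-ready frame."""
    rows = []
    for p in profiles:
        for dist, delta, reach in zip(p.distances_m, p.anchored_delta, p.reaches):
            rows.append(
                {
                    "site": p.site,
                    "season": p.season,
                    "descriptor": p.descriptor,
                    "distance_m": dist,
                    "anchored_delta_c": delta,
                    "reach": reach,
                }
            )
    return pd.DataFrame(rows)
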
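"""Riparian shade and below-canopy light metrics.

Hemispherical photographs are classified upstream of this package into two
open-sky fractions per photo: VisSky (open pixels over the whole hemisphere)
and GSF (global site factor; open pixels along the solar track).  Shade is
expressed as their complements in percent.  Light transmission is the ratio
of daily below-canopy to above-canopy irradiance totals from paired
pyranometers: hourly ratios are not averaged because the above-canopy signal
approaches zero at dawn and dusk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _check_fraction(x, name: str):
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError(f"{name} must lie in [0, 1]")
    return x


def canopy_closure(vis_sky) -> np.ndarray | float:
    """Canopy closure (%) = (1 - VisSky) * 100."""
    out = (1.0 - _check_fraction(vis_sky, "vis_sky")) * 100.0
    return float(out) if np.isscalar(vis_sky) else out


def effective_shade(gsf) -> np.ndarray | float:
    """Effective shade (%) = (1 - GSF) * 100."""
    out = (1.0 - _check_fraction(gsf, "gsf")) * 100.0
    return float(out) if np.isscalar(gsf) else out


def percent_transmission(below, above) -> float:
    """Light reaching the stream as a percent of above-canopy light.

    ``below`` and ``above`` are paired hourly irradiance series (W m^-2) over
    the same 24 h window; the statistic is 100 x sum(below) / sum(above).
    """
    below = np.asarray(below, dtype=float)
    above = np.asarray(above, dtype=float)
    if below.shape != above.shape:
        raise ValueError("below- and above-canopy series must have equal length")
    total_above = above.sum()
    if total_above <= 0:
        raise ValueError("above-canopy daily total must be positive")
    return float(100.0 * below.sum() / total_above)


def summarize_reach(shade: pd.DataFrame, light: pd.DataFrame) -> pd.DataFrame:
    """Reach-year means of closure, effective shade and transmission.

    ``shade`` holds one row per photo (site, reach, year, vis_sky, gsf);
    ``light`` one row per pyranometer-hour (site, reach, year, pyranometer,
    below_wm2, above_wm2).  Photos and pyranometers are evenly spaced along
    the reach, so the summary is an unweighted mean.  SD columns are NaN when
    a group holds a single record.
    """
    rows = []
    for (site, reach, year), grp in shade.groupby(["site", "reach", "year"]):
        cc = canopy_closure(grp["vis_sky"].to_numpy())
        es = effective_shade(grp["gsf"].to_numpy())
        rows.append(
            {
                "site": site,
                "reach": reach,
                "year": year,
                "canopy_closure_pct": cc.mean(),
                "canopy_closure_sd": cc.std(ddof=1) if len(cc) > 1 else np.nan,
                "effective_shade_pct": es.mean(),
                "effective_shade_sd": es.std(ddof=1) if len(es) > 1 else np.nan,
                "n_photos": len(grp),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no shade records to summarize")

    if len(light):
        lrows = []
        for (site, reach, year), grp in light.groupby(["site", "reach", "year"]):
            trans = [
                percent_transmission(g["below_wm2"], g["above_wm2"])
                for _, g in grp.groupby("pyranometer")
            ]
            trans = np.asarray(trans)
            lrows.append(
                {
                    "site": site,
                    "reach": reach,
                    "year": year,
                    "transmission_pct": trans.mean(),
                    "transmission_sd": trans.std(ddof=1) if len(trans) > 1 else np.nan,
                    "n_pyranometers": len(trans),
                }
            )
        out = out.merge(pd.DataFrame(lrows), on=["site", "reach", "year"], how="outer")
    return out.sort_values(["site", "reach", "year"]).reset_index(drop=True)
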
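import numpy as np
import pandas as pd
import pytest

import streamtherm as st
from streamtherm import descriptors as de
from streamtherm import pipeline as pl


@pytest.fixture(scope="session")
def default_config():
    return st.SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def study(default_config):
    """One full synthetic study at the default (field-scale) conditions."""
    return pl.generate_study(default_config)


@pytest.fixture(scope="session")
def descriptor_table(study):
    return de.descriptor_table(study.temps)


@pytest.fixture(scope="session")
def reach_descriptors(descriptor_table):
    return pl.reach_rows(descriptor_table)


def make_series(
    temps,
    start="2016-07-01",
    freq="h",
    site="S1",
    reach="upstream",
    position="reach_bottom",
):
    """Small helper: wrap raw values in an HourlyTempSeries."""
    temps = np.asarray(temps, dtype=float)
    time = pd.date_range(start, periods=len(temps), freq=freq)
    return st.HourlyTempSeries(
        watershed="W",
        site=site,
        reach=reach,
        position=position,
        distance_m=0.0,
        time=time,
        temp_c=temps,
    )


def summer_mean_daily_max_table(cfg):
    """Per-(site, reach, year) summer mean daily maximum from one study."""
    series, truth = st.synth.generate_hourly_temperature(cfg)
    rows = []
    for s in series:
        if s.position != "reach_bottom":
            continue
        daily = de.daily_summaries(s)
        wy = int(de.water_year(s.time[[0]])[0])
        arrs = de._season_arrays(daily, wy, "Summer")
        rows.append(
            {
                "site": s.site,
                "reach": s.reach,
                "year": "pre" if wy == cfg.years[0] else "post",
                "value": float(np.nanmean(arrs["tmax"])),
            }
        )
    return pd.DataFrame(rows), truth
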
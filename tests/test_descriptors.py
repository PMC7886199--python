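"""Descriptor suite: frozen examples, independent oracles, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from streamtherm import descriptors as de
from conftest import make_series


# ---------------------------------------------------------------- oracles
def mwmt_oracle(values):
    """Exhaustive scan over every 7-consecutive-day window (NaN-skipping)."""
    best = np.nan
    for i in range(len(values) - 6):
        window = values[i : i + 7]
        if np.any(np.isnan(window)):
            continue
        m = np.mean(window)
        if np.isnan(best) or m > best:
            best = m
    return best


def exceedance_oracle(values, threshold):
    """Run-length encoding of the exceedance indicator."""
    above = [(not np.isnan(v)) and v > threshold for v in values]
    runs, current = [], 0
    for a in above:
        current = current + 1 if a else 0
        runs.append(current)
    return sum(above), max(runs, default=0)


def degree_days_oracle(values):
    total = 0.0
    for v in values:
        if not np.isnan(v):
            total += v
    return total


# ------------------------------------------------------------ daily summaries
def test_constant_day_summary():
    s = make_series([10.0] * 24)
    d = de.daily_summaries(s)
    assert len(d) == 1
    row = d.iloc[0]
    assert row.tmax == row.tmin == row.tmean == 10.0
    assert row.trange == 0.0 and row.tvar == 0.0 and row.qualifies


def test_sinusoid_daily_range_matches_brute_force():
    hours = np.arange(24)
    vals = 10 + 2 * np.sin(2 * np.pi * hours / 24)
    d = de.daily_summaries(make_series(vals))
    # oracle: evaluate the 24 sampled points and take max - min directly
    assert d.iloc[0].trange == pytest.approx(vals.max() - vals.min())
    assert d.iloc[0].trange == pytest.approx(4.0, abs=1e-9)


def test_incomplete_day_flagged():
    s = make_series(np.full(20, 12.0))  # 20 of 24 hours < 0.9 completeness
    d = de.daily_summaries(s, min_completeness=0.9)
    assert not d.iloc[0].qualifies


def test_flagged_hours_treated_as_missing():
    vals = np.full(48, 12.0)
    vals[30] = 99.0  # outside plausibility bounds
    s = make_series(vals)
    d = de.daily_summaries(s)
    assert d.iloc[1].n_hours == 23
    assert d.iloc[1].tmax == 12.0


# ------------------------------------------------------------------ seasons
@pytest.mark.parametrize(
    "date,expected",
    [
        ("2016-07-15", (2016, "Summer")),
        ("2015-10-01", (2016, "Fall")),
        ("2016-03-31", (2016, "Winter")),
        ("2016-04-01", (2016, "Spring")),
        ("2016-09-30", (2016, "Summer")),
        ("2016-10-01", (2017, "Fall")),
    ],
)
def test_water_year_season_assignment(date, expected):
    out = de.assign_season(pd.DatetimeIndex([date]))
    assert (out["water_year"].iloc[0], out["season"].iloc[0]) == expected


def test_seasons_partition_the_water_year():
    days = pd.date_range("2015-10-01", "2016-09-30", freq="D")
    out = de.assign_season(days)
    assert (out["water_year"] == 2016).all()
    counts = out["season"].value_counts()
    assert counts.sum() == len(days) and set(counts.index) == set(de.SEASONS)


# --------------------------------------------------------------- weekly stats
def test_mwmt_single_hot_day_arithmetic():
    # 92 summer days at 10 degC daily max except one 17 degC day
    temps = np.repeat(10.0, 92 * 24).reshape(92, 24)
    temps[45] = 17.0
    s = make_series(temps.ravel(), start="2016-07-01")
    daily = de.daily_summaries(s)
    mwmt, mwat = de.weekly_max_statistics(daily, 2016, "Summer")
    assert mwmt == pytest.approx((6 * 10 + 17) / 7)
    assert mwat == pytest.approx((6 * 10 + 17) / 7)


def test_constant_season_mwmt():
    s = make_series(np.full(92 * 24, 15.0), start="2016-07-01")
    daily = de.daily_summaries(s)
    mwmt, _ = de.weekly_max_statistics(daily, 2016, "Summer")
    assert mwmt == pytest.approx(15.0)


def test_weekly_stats_match_exhaustive_window_scan():
    rng = np.random.default_rng(7)
    for _ in range(50):
        tmax = rng.uniform(5, 20, 92)
        base = np.repeat(tmax, 24)
        s = make_series(base, start="2016-07-01")
        daily = de.daily_summaries(s)
        mwmt, _ = de.weekly_max_statistics(daily, 2016, "Summer")
        assert mwmt == pytest.approx(mwmt_oracle(tmax), abs=1e-9)


def test_windows_spanning_excluded_day_are_skipped():
    temps = np.repeat(12.0, 92 * 24).reshape(92, 24)
    temps[10, :20] = np.nan  # knock out 20 hours -> day 10 unqualified
    flat = temps.ravel()
    keep = ~np.isnan(flat)
    time = pd.date_range("2016-07-01", periods=len(flat), freq="h")[keep]
    import streamtherm as st

    s = st.HourlyTempSeries(
        watershed="W", site="S", reach="upstream", position="reach_bottom",
        distance_m=0.0, time=time, temp_c=flat[keep],
    )
    daily = de.daily_summaries(s)
    assert not daily.iloc[10].qualifies
    arrs = de._season_arrays(daily, 2016, "Summer")
    assert np.isnan(arrs["tmax"][10])
    mwmt, _ = de.weekly_max_statistics(daily, 2016, "Summer")
    assert mwmt == pytest.approx(12.0)  # windows avoiding day 10 still qualify


# ------------------------------------------------------- exceedance / degrees
def test_threshold_exceedance_example():
    maxima = [15.0, 17.0, 18.0, 15.0, 17.0]
    s = make_series(np.repeat(maxima, 24), start="2016-07-01")
    daily = de.daily_summaries(s)
    assert de.threshold_exceedance(daily, 2016, "Summer", 16.0) == (3, 2)


def test_exceedance_matches_rle_oracle():
    rng = np.random.default_rng(21)
    for _ in range(50):
        tmax = rng.uniform(10, 22, 92)
        daily = de.daily_summaries(make_series(np.repeat(tmax, 24), start="2016-07-01"))
        for thr in (16.0, 20.0):
            assert de.threshold_exceedance(daily, 2016, "Summer", thr) == (
                exceedance_oracle(tmax, thr)
            )


def test_degree_days_examples_and_oracle():
    rng = np.random.default_rng(3)
    means = rng.uniform(5, 18, 92)
    daily = de.daily_summaries(make_series(np.repeat(means, 24), start="2016-07-01"))
    assert de.degree_days(daily, 2016, "Summer") == pytest.approx(
        degree_days_oracle(means)
    )
    zero = de.daily_summaries(make_series(np.zeros(92 * 24), start="2016-07-01"))
    assert de.degree_days(zero, 2016, "Summer") == 0.0


# --------------------------------------------------------- composed descriptor
def test_regime_descriptors_constant_season():
    daily = de.daily_summaries(make_series(np.full(92 * 24, 10.0), start="2016-07-01"))
    r = de.regime_descriptors(daily, 2016, "Summer")
    for k in ("avg_daily_max", "mwmt", "avg_daily_mean", "mwat", "avg_daily_min"):
        assert r[k] == pytest.approx(10.0)
    assert r["degree_days"] == pytest.approx(10.0 * 92)
    for k in ("avg_daily_range", "max_daily_range", "avg_variance", "max_variance"):
        assert r[k] == pytest.approx(0.0)
    assert r["days_gt_16"] == r["consec_days_gt_16"] == 0
    assert r["flag"] == "ok"


def test_regime_descriptors_composition_consistency():
    rng = np.random.default_rng(5)
    vals = 12 + rng.normal(0, 2, 92 * 24)
    daily = de.daily_summaries(make_series(vals, start="2016-07-01"))
    r = de.regime_descriptors(daily, 2016, "Summer")
    mwmt, mwat = de.weekly_max_statistics(daily, 2016, "Summer")
    assert r["mwmt"] == pytest.approx(mwmt) and r["mwat"] == pytest.approx(mwat)
    assert r["degree_days"] == pytest.approx(de.degree_days(daily, 2016, "Summer"))
    assert (r["days_gt_16"], r["consec_days_gt_16"]) == de.threshold_exceedance(
        daily, 2016, "Summer", 16.0
    )


def test_descriptor_invariants_on_random_season():
    rng = np.random.default_rng(9)
    vals = 13 + 2 * np.sin(2 * np.pi * np.arange(92 * 24) / 24) + rng.normal(0, 0.5, 92 * 24)
    daily = de.daily_summaries(make_series(vals, start="2016-07-01"))
    r = de.regime_descriptors(daily, 2016, "Summer")
    season_max = float(np.nanmax(de._season_arrays(daily, 2016, "Summer")["tmax"]))
    assert r["mwmt"] <= season_max + 1e-12
    assert r["mwat"] <= r["mwmt"]
    assert r["avg_daily_min"] <= r["avg_daily_mean"] <= r["avg_daily_max"]
    assert r["consec_days_gt_16"] <= r["days_gt_16"]


@given(shift=hst.floats(min_value=0.1, max_value=5.0))
@settings(max_examples=20, deadline=None)
def test_additive_shift_monotonicity(shift):
    """+c shifts magnitude descriptors by c and leaves variability unchanged."""
    rng = np.random.default_rng(17)
    vals = 12 + rng.normal(0, 1.0, 92 * 24)
    d0 = de.daily_summaries(make_series(vals, start="2016-07-01"))
    d1 = de.daily_summaries(make_series(vals + shift, start="2016-07-01"))
    r0 = de.regime_descriptors(d0, 2016, "Summer")
    r1 = de.regime_descriptors(d1, 2016, "Summer")
    for k in ("avg_daily_max", "mwmt", "avg_daily_mean", "mwat", "avg_daily_min"):
        assert r1[k] - r0[k] == pytest.approx(shift, abs=1e-9)
    assert r1["degree_days"] - r0["degree_days"] == pytest.approx(shift * 92, rel=1e-9)
    for k in ("avg_daily_range", "max_daily_range", "avg_variance", "max_variance"):
        assert r1[k] == pytest.approx(r0[k], abs=1e-9)


def test_descriptors_invariant_to_input_row_order(tmp_path):
    """Shuffling CSV rows does not change any descriptor."""
    from streamtherm import io as sio

    rng = np.random.default_rng(31)
    s = make_series(12 + rng.normal(0, 1, 92 * 24), start="2016-07-01")
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    sio.write_hourly_temps([s], p1)
    df = pd.read_csv(p1).sample(frac=1.0, random_state=0)
    df.to_csv(p2, index=False)
    t1 = de.descriptor_table(sio.read_hourly_temps(p1))
    t2 = de.descriptor_table(sio.read_hourly_temps(p2))
    pd.testing.assert_frame_equal(t1, t2)
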
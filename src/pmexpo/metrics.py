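"""Descriptive exposure metrics: daily means, per-microenvironment
summaries, diurnal profiles and daily-guideline compliance counts."""

from __future__ import annotations

import logging
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .config import MetricsParams

log = logging.getLogger(__name__)

# day-of-week levels retained for daily means (partial Fridays dropped)
RETAINED_WEEKDAYS = (0, 1, 2, 3)  # Monday .. Thursday
WEEKDAY_NAMES = {0: "Monday", 1: "Tuesday", 2: "Wednesday", 3: "Thursday"}


def daily_means(
    labeled: pd.DataFrame, params: Optional[MetricsParams] = None
) -> pd.DataFrame:
    """Per child-day arithmetic mean exposure over PM-valid minutes.

    Days with fewer than ``min_day_coverage_min`` valid minutes are omitted
    (and logged), as are days outside Monday-Thursday.  ``labeled`` must
    carry ``child_id``; the calendar day is the local midnight day of
    ``minute_start``.
    """
    params = params or MetricsParams()
    cols = ["child_id", "date", "day_of_week", "pm25_daily_mean",
            "pm10_daily_mean", "valid_minutes"]
    if len(labeled) == 0:
        return pd.DataFrame(columns=cols)
    df = labeled.copy()
    ts = pd.to_datetime(df["minute_start"])
    df["date"] = ts.dt.date
    df["_dow"] = ts.dt.dayofweek

    rows = []
    for (cid, date), day in df.groupby(["child_id", "date"], sort=True):
        valid = day[day["pm_valid"].astype(bool)]
        nv = len(valid)
        dow = int(day["_dow"].iloc[0])
        if nv < params.min_day_coverage_min:
            log.info("dropping %s %s: %d valid minutes < %d",
                     cid, date, nv, params.min_day_coverage_min)
            continue
        if dow not in RETAINED_WEEKDAYS:
            log.info("dropping %s %s: weekday %d outside Monday-Thursday",
                     cid, date, dow)
            continue
        rows.append({
            "child_id": cid,
            "date": date,
            "day_of_week": WEEKDAY_NAMES[dow],
            "pm25_daily_mean": float(valid["pm25_mean"].mean()),
            "pm10_daily_mean": float(valid["pm10_mean"].mean()),
            "valid_minutes": nv,
        })
    return pd.DataFrame(rows, columns=cols)


def microenv_summaries(
    labeled: pd.DataFrame,
    gps_gap_children: set[str] | None = None,
    params: Optional[MetricsParams] = None,
) -> pd.DataFrame:
    """Per child x label exposure summaries and time/exposure proportions.

    Proportions are computed over labelled (non-unknown) PM-valid minutes
    and sum to 1 per child; for children flagged with a >12 h GPS gap the
    proportions are reported missing while the means remain.  The ratio
    statistic is the mean of per-minute PM2.5:PM10 ratios over minutes with
    PM10 >= ``ratio_pm10_floor``; the ratio of means is emitted alongside
    for sensitivity.
    """
    params = params or MetricsParams()
    gps_gap_children = gps_gap_children or set()
    cols = ["child_id", "label", "pm25_mean", "pm25_median", "ratio_mean",
            "ratio_of_means", "minutes", "time_proportion",
            "exposure_proportion"]
    if len(labeled) == 0:
        return pd.DataFrame(columns=cols)
    df = labeled[labeled["pm_valid"].astype(bool)].copy()

    rows = []
    for cid, child in df.groupby("child_id", sort=True):
        known = child[child["label"] != "unknown"]
        tot_minutes = len(known)
        tot_exposure = known["pm25_mean"].sum()
        for lab, sub in child.groupby("label", sort=True):
            ratio_ok = sub[sub["pm10_mean"] >= params.ratio_pm10_floor]
            ratio_mean = (
                float((ratio_ok["pm25_mean"] / ratio_ok["pm10_mean"]).mean())
                if len(ratio_ok) else np.nan
            )
            ratio_of_means = (
                float(ratio_ok["pm25_mean"].mean() / ratio_ok["pm10_mean"].mean())
                if len(ratio_ok) and ratio_ok["pm10_mean"].mean() > 0 else np.nan
            )
            if lab == "unknown" or cid in gps_gap_children or tot_minutes == 0:
                tprop = eprop = np.nan
            else:
                tprop = len(sub) / tot_minutes
                eprop = (
                    sub["pm25_mean"].sum() / tot_exposure
                    if tot_exposure > 0 else np.nan
                )
            rows.append({
                "child_id": cid,
                "label": lab,
                "pm25_mean": float(sub["pm25_mean"].mean()),
                "pm25_median": float(sub["pm25_mean"].median()),
                "ratio_mean": ratio_mean,
                "ratio_of_means": ratio_of_means,
                "minutes": len(sub),
                "time_proportion": tprop,
                "exposure_proportion": eprop,
            })
    return pd.DataFrame(rows, columns=cols)


def diurnal_profiles(
    labeled: pd.DataFrame, city_of_child: Mapping[str, str]
) -> pd.DataFrame:
    """Hour-of-day exposure distribution per city.

    Child-hour means (one value per child x date x hour over PM-valid
    minutes) are pooled within each city, then summarised by mean, median,
    quartiles and the 5th/95th percentiles.  Hours with no child-hours get
    a row of missing statistics.
    """
    cols = ["city_id", "hour", "mean", "median", "q25", "q75", "p5", "p95",
            "n_child_hours"]
    cities = sorted(set(city_of_child.values()))
    if len(labeled) == 0:
        return pd.DataFrame(
            [{"city_id": c, "hour": h, "mean": np.nan, "median": np.nan,
              "q25": np.nan, "q75": np.nan, "p5": np.nan, "p95": np.nan,
              "n_child_hours": 0} for c in cities for h in range(24)],
            columns=cols,
        )
    df = labeled[labeled["pm_valid"].astype(bool)].copy()
    ts = pd.to_datetime(df["minute_start"])
    df["date"] = ts.dt.date
    df["hour"] = ts.dt.hour
    df["city_id"] = df["child_id"].map(city_of_child)

    child_hours = (
        df.groupby(["city_id", "child_id", "date", "hour"])["pm25_mean"]
        .mean()
        .reset_index()
    )
    rows = []
    for city in cities:
        sub = child_hours[child_hours["city_id"] == city]
        for hour in range(24):
            vals = sub.loc[sub["hour"] == hour, "pm25_mean"].to_numpy(float)
            if len(vals) == 0:
                rows.append({"city_id": city, "hour": hour, "mean": np.nan,
                             "median": np.nan, "q25": np.nan, "q75": np.nan,
                             "p5": np.nan, "p95": np.nan, "n_child_hours": 0})
                continue
            q = np.percentile(vals, [5, 25, 50, 75, 95])  # linear interpolation
            rows.append({
                "city_id": city, "hour": hour,
                "mean": float(vals.mean()), "median": float(q[2]),
                "q25": float(q[1]), "q75": float(q[3]),
                "p5": float(q[0]), "p95": float(q[4]),
                "n_child_hours": int(len(vals)),
            })
    return pd.DataFrame(rows, columns=cols)


def guideline_compliance(
    daily: pd.DataFrame, params: Optional[MetricsParams] = None
) -> dict[str, int]:
    """Count days strictly below the daily PM2.5/PM10 guideline values."""
    params = params or MetricsParams()
    if len(daily) == 0:
        return {"pm25_below": 0, "pm10_below": 0, "total_days": 0}
    return {
        "pm25_below": int((daily["pm25_daily_mean"] < params.who_pm25).sum()),
        "pm10_below": int((daily["pm10_daily_mean"] < params.who_pm10).sum()),
        "total_days": int(len(daily)),
    }


def percentage(count: int, total: int) -> int:
    """Integer percentage with round-half-up, as printed in report tables."""
    if total == 0:
        return 0
    return int(np.floor(100.0 * count / total + 0.5))


def compliance_percentages(counts: Mapping[str, int]) -> dict[str, int]:
    total = counts["total_days"]
    return {
        "pm25_pct_below": percentage(counts["pm25_below"], total),
        "pm10_pct_below": percentage(counts["pm10_below"], total),
    }
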
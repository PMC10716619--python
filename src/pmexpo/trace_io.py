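"""Reading, aggregating and writing the pipeline's tabular formats.

Traces are RFC 4180 CSV with columns ``timestamp,pm25,pm10,lat,lon`` at 1-s
cadence, local time, ISO 8601 without offset.  Missing values are empty
fields, never sentinel numbers.  All tables round-trip through
:func:`write_trace` / :func:`read_trace` at 6-decimal precision.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import MinuteRules

TRACE_COLUMNS = ["timestamp", "pm25", "pm10", "lat", "lon"]

MINUTE_COLUMNS = [
    "minute_start", "pm25_mean", "pm10_mean", "lat", "lon",
    "n_samples_valid", "pm_valid", "gps_valid",
]

COHORT_ID_COLUMNS = ["child_id", "city_id", "school_id", "monitoring_start"]
METEOROLOGY_COLUMNS = ["city_id", "date", "temp_c", "rh_pct", "wind_ms"]


class TraceSchemaError(ValueError):
    """Input file does not match the expected column schema."""


class TraceDataError(ValueError):
    """Input file violates a data invariant (e.g. non-monotone timestamps)."""


class OutputCollisionError(FileExistsError):
    """Refusing to overwrite existing outputs without force."""


@dataclass
class TraceData:
    """A parsed trace plus parse bookkeeping."""

    samples: pd.DataFrame  # TRACE_COLUMNS, timestamp as datetime64[ns]
    n_malformed: int  # rows with >=1 unparseable field
    n_capped: int  # PM values above the physical cap, blanked to missing


def read_trace(path: str | os.PathLike, rules: MinuteRules | None = None) -> TraceData:
    """Read a 1-s sensor trace.

    Malformed numeric fields become missing and are counted; a row whose
    timestamp cannot be parsed is dropped and counted.  Timestamps must be
    strictly increasing; the first offending row (0-based, excluding the
    header) is named in the error.
    """
    rules = rules or MinuteRules()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRACE_COLUMNS if c not in raw.columns]
    if missing:
        raise TraceSchemaError(f"{path.name}: missing required column(s) {missing}")
    raw = raw[TRACE_COLUMNS]

    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    numeric = {}
    malformed = pd.Series(False, index=raw.index)
    for col in ("pm25", "pm10", "lat", "lon"):
        s = raw[col].str.strip()
        parsed = pd.to_numeric(s, errors="coerce")
        bad = parsed.isna() & (s != "")
        malformed |= bad
        numeric[col] = parsed
    bad_ts = ts.isna() & (raw["timestamp"].str.strip() != "")
    empty_ts = ts.isna() & ~bad_ts
    malformed |= bad_ts
    n_malformed = int(malformed.sum())

    df = pd.DataFrame({"timestamp": ts, **numeric})
    df = df[~(bad_ts | empty_ts)].reset_index(drop=True)

    if len(df) > 1:
        diffs = df["timestamp"].diff()
        non_mono = diffs.le(pd.Timedelta(0))
        non_mono.iloc[0] = False
        if non_mono.any():
            row = int(non_mono.idxmax())
            raise TraceDataError(
                f"{path.name}: timestamps not strictly increasing at row {row}"
            )

    n_capped = 0
    for col in ("pm25", "pm10"):
        over = (df[col] >= rules.pm_cap) | (df[col] < 0)
        n_capped += int(over.sum())
        df.loc[over, col] = np.nan
    return TraceData(samples=df, n_malformed=n_malformed, n_capped=n_capped)


def write_trace(samples: pd.DataFrame, path: str | os.PathLike) -> None:
    df = samples.copy()
    # datetime64[s] -> str is vectorised ISO 8601, far faster than strftime
    df["timestamp"] = (
        pd.to_datetime(df["timestamp"]).to_numpy().astype("datetime64[s]").astype(str)
    )
    for col in ("pm25", "pm10", "lat", "lon"):
        df[col] = df[col].round(6)
    df.to_csv(path, index=False, lineterminator="\n")


def aggregate_minutes(
    samples: pd.DataFrame, rules: MinuteRules | None = None
) -> pd.DataFrame:
    """Collapse 1-s samples onto a complete grid of calendar minutes.

    One row per minute between the first and last sample (inclusive), even
    across sampling gaps.  A sample is PM-valid when both PM fields are
    finite; a minute's PM is valid when it holds at least
    ``rules.min_valid_samples`` PM-valid samples.  GPS is valid with any
    finite fix.  Minute position is the arithmetic mean of valid fixes.
    """
    rules = rules or MinuteRules()
    if len(samples) == 0:
        return pd.DataFrame(columns=MINUTE_COLUMNS)
    df = samples.copy()
    df["minute_start"] = pd.to_datetime(df["timestamp"]).dt.floor("min")

    pm_ok = np.isfinite(df["pm25"].to_numpy(float)) & np.isfinite(
        df["pm10"].to_numpy(float)
    )
    gps_ok = np.isfinite(df["lat"].to_numpy(float)) & np.isfinite(
        df["lon"].to_numpy(float)
    )
    df["_pm_ok"] = pm_ok
    df["_gps_ok"] = gps_ok
    df.loc[~gps_ok, ["lat", "lon"]] = np.nan

    grouped = df.groupby("minute_start")
    agg = grouped.agg(
        pm25_mean=("pm25", "mean"),
        pm10_mean=("pm10", "mean"),
        lat=("lat", "mean"),
        lon=("lon", "mean"),
        n_samples_valid=("_pm_ok", "sum"),
        _gps_n=("_gps_ok", "sum"),
    )
    full = pd.date_range(
        df["minute_start"].iloc[0], df["minute_start"].iloc[-1], freq="min"
    )
    agg = agg.reindex(full)
    agg.index.name = "minute_start"
    agg["n_samples_valid"] = agg["n_samples_valid"].fillna(0).astype(int)
    agg["pm_valid"] = agg["n_samples_valid"] >= rules.min_valid_samples
    agg["gps_valid"] = agg["_gps_n"].fillna(0).astype(int) >= 1
    out = agg.reset_index().drop(columns="_gps_n")
    return out[MINUTE_COLUMNS]


def read_cohort(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_ID_COLUMNS if c not in df.columns]
    if missing:
        raise TraceSchemaError(f"cohort table missing column(s) {missing}")
    return df


def read_meteorology(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METEOROLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise TraceSchemaError(f"meteorology table missing column(s) {missing}")
    bad_rh = df[(df["rh_pct"] < 0) | (df["rh_pct"] > 100)]
    if len(bad_rh):
        raise TraceDataError("meteorology rh_pct outside [0, 100]")
    if (df["wind_ms"] < 0).any():
        raise TraceDataError("meteorology wind_ms negative")
    return df


def read_diary(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.duplicated(subset=["child_id", "date"]).any():
        raise TraceDataError("diary has more than one entry per child-day")
    return df


def write_outputs(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | os.PathLike,
    force: bool = False,
) -> dict[str, str]:
    """Write named tables as ``<name>.csv`` under ``out_dir``.

    Deterministic byte output for identical inputs.  Existing files are a
    collision unless ``force``.  Returns name -> sha256 of written bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.csv" for name in tables}
    if not force:
        existing = [p.name for p in paths.values() if p.exists()]
        if existing:
            raise OutputCollisionError(
                f"refusing to overwrite {existing}; pass force=True"
            )
    checksums: dict[str, str] = {}
    for name, df in tables.items():
        data = df.to_csv(index=False, float_format="%.6f", lineterminator="\n")
        paths[name].write_text(data)
        checksums[name] = hashlib.sha256(data.encode()).hexdigest()
    return checksums
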
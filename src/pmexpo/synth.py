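"""Synthetic cohort generator with exact ground truth.

Emulates the study's data structure end to end: a multi-city cohort with
categorical exposure determinants, per-city lognormal daily exposure with
nested (city, child) random intercepts and multiplicative planted effects,
weekday home/commute/school schedules, 1-s GPS+PM backpack traces with
jitter and dropout, and city-day meteorology.  Every random quantity is
recorded in :class:`SyntheticTruth` so tagging accuracy and effect recovery
can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import DETERMINANT_LEVELS, GeneratorConfig
from .tagger import equirect_distance_m
from .trace_io import MINUTE_COLUMNS, write_trace

BIOMASS_COOKERS = {"Coal or wood (biomass)", "Open fire and biomass"}
M_PER_DEG_LAT = 111_320.0


class SeedMismatchError(ValueError):
    """Pipeline outputs were produced under a different seed than the truth."""


def _city_log_sds(city_spec, config: GeneratorConfig) -> tuple[float, float]:
    """Split each city's total log-SD ln(GSD) into child and day parts.

    ``sigma_child`` and ``sigma_day`` set the *proportion* of variance at
    each level; the total is pinned to the city's configured GSD so the
    generated daily distribution really has that geometric SD.
    """
    total = float(np.log(city_spec.gsd))
    denom = config.sigma_child**2 + config.sigma_day**2
    if denom == 0:
        return 0.0, 0.0
    share_child = config.sigma_child**2 / denom
    return total * np.sqrt(share_child), total * np.sqrt(1.0 - share_child)


@dataclass
class SyntheticTruth:
    """Everything needed to score pipeline outputs exactly."""

    seed: int
    city_of_child: dict[str, str] = field(default_factory=dict)
    home: dict[str, tuple[float, float]] = field(default_factory=dict)
    school: dict[str, tuple[float, float]] = field(default_factory=dict)
    b_city: dict[str, float] = field(default_factory=dict)
    b_child: dict[str, float] = field(default_factory=dict)
    log_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    met_log_effects: dict[str, float] = field(default_factory=dict)
    daily_log_target: dict[str, dict[str, float]] = field(default_factory=dict)
    true_labels: dict[str, dict] = field(default_factory=dict)

    def labels_frame(self, child_id: str) -> pd.DataFrame:
        rec = self.true_labels[child_id]
        idx = pd.date_range(rec["start"], periods=len(rec["labels"]), freq="min")
        return pd.DataFrame({"minute_start": idx, "true_label": rec["labels"]})

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "city_of_child": self.city_of_child,
            "home": {k: list(v) for k, v in self.home.items()},
            "school": {k: list(v) for k, v in self.school.items()},
            "b_city": self.b_city,
            "b_child": self.b_child,
            "log_effects": self.log_effects,
            "met_log_effects": self.met_log_effects,
            "daily_log_target": self.daily_log_target,
            "true_labels": self.true_labels,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            seed=d["seed"],
            city_of_child=d["city_of_child"],
            home={k: tuple(v) for k, v in d["home"].items()},
            school={k: tuple(v) for k, v in d["school"].items()},
            b_city=d["b_city"],
            b_child=d["b_child"],
            log_effects=d["log_effects"],
            met_log_effects=d["met_log_effects"],
            daily_log_target=d["daily_log_target"],
            true_labels=d["true_labels"],
        )


def _offset_latlon(lat: float, lon: float, dx_m, dy_m):
    return (
        lat + np.asarray(dy_m) / M_PER_DEG_LAT,
        lon + np.asarray(dx_m) / (M_PER_DEG_LAT * np.cos(np.radians(lat))),
    )


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Children, determinants and anchor geography for every city.

    Determinant levels are drawn per child from the configured prevalences
    (school ground surface is drawn per school and shared by its pupils);
    random intercepts are Normal(0, sigma) on the log scale.
    """
    rng = np.random.default_rng([config.seed, 0])
    truth = SyntheticTruth(seed=config.seed)
    truth.log_effects = {
        det: {lvl: float(np.log(f)) for lvl, f in levels.items()}
        for det, levels in config.effects.items()
    }
    truth.met_log_effects = {
        v: float(np.log(f)) for v, f in config.met_effects.items()
    }
    monday = pd.Timestamp(config.schedule.week_monday)
    start = monday + pd.Timedelta(hours=config.schedule.start_weekday_hour)

    rows = []
    for city in config.cities:
        truth.b_city[city.city_id] = float(rng.normal(0.0, config.sigma_location))
        # schools on a ring around the city centre
        school_pos = []
        surfaces = []
        n_schools = max(1, city.n_schools)
        for s in range(n_schools):
            ang = 2 * np.pi * s / n_schools
            lat_s, lon_s = _offset_latlon(
                city.lat0, city.lon0, 3000 * np.cos(ang), 3000 * np.sin(ang)
            )
            school_pos.append((float(lat_s), float(lon_s)))
            surf_levels = list(config.prevalences["school_ground_surface"])
            surf_p = list(config.prevalences["school_ground_surface"].values())
            surfaces.append(str(rng.choice(surf_levels, p=surf_p)))
        for k in range(city.n_children):
            cid = f"{city.city_id}_{k:03d}"
            s = int(rng.integers(n_schools))
            school_id = f"{city.city_id}_S{s}"
            # home 800-2500 m from school, random bearing
            dist = rng.uniform(800.0, 2500.0)
            bearing = rng.uniform(0.0, 2 * np.pi)
            lat_h, lon_h = _offset_latlon(
                *school_pos[s], dist * np.sin(bearing), dist * np.cos(bearing)
            )
            det = {}
            for name, levels in config.prevalences.items():
                if name == "school_ground_surface":
                    det[name] = surfaces[s]
                else:
                    det[name] = str(
                        rng.choice(list(levels), p=list(levels.values()))
                    )
            for name in DETERMINANT_LEVELS:
                det.setdefault(name, DETERMINANT_LEVELS[name][0])
            rows.append({
                "child_id": cid,
                "city_id": city.city_id,
                "school_id": school_id,
                "monitoring_start": start.isoformat(),
                **det,
            })
            truth.city_of_child[cid] = city.city_id
            truth.home[cid] = (float(lat_h), float(lon_h))
            truth.school[cid] = school_pos[s]
            sd_child, _ = _city_log_sds(city, config)
            truth.b_child[cid] = float(rng.normal(0.0, sd_child))
    cohort = pd.DataFrame(
        rows,
        columns=["child_id", "city_id", "school_id", "monitoring_start"]
        + list(DETERMINANT_LEVELS),
    )
    return cohort, truth


def generate_meteorology(
    config: GeneratorConfig, dates: Sequence[pd.Timestamp]
) -> pd.DataFrame:
    rng = np.random.default_rng([config.seed, 1])
    rows = []
    for city in config.cities:
        for d in dates:
            rows.append({
                "city_id": city.city_id,
                "date": pd.Timestamp(d).date().isoformat(),
                "temp_c": float(rng.normal(city.temp_mean, city.temp_sd)),
                "rh_pct": float(np.clip(rng.normal(city.rh_mean, city.rh_sd), 0, 100)),
                "wind_ms": float(np.clip(rng.normal(city.wind_mean, city.wind_sd), 0.05, None)),
            })
    return pd.DataFrame(rows)


def _child_fixed_log_effect(child_row: Mapping, truth: SyntheticTruth) -> float:
    total = 0.0
    for det, levels in truth.log_effects.items():
        total += levels.get(str(child_row[det]), 0.0)
    return total


def _met_log_effect(
    met_row: Mapping, city_spec, truth: SyntheticTruth
) -> float:
    means = {"temp_c": city_spec.temp_mean, "rh_pct": city_spec.rh_mean,
             "wind_ms": city_spec.wind_mean}
    total = 0.0
    for var, beta in truth.met_log_effects.items():
        total += beta * (float(met_row[var]) - means[var])
    return total


def _window_dates(config: GeneratorConfig) -> list[pd.Timestamp]:
    monday = pd.Timestamp(config.schedule.week_monday)
    start = monday + pd.Timedelta(hours=config.schedule.start_weekday_hour)
    end = start + pd.Timedelta(hours=config.schedule.duration_hours)
    return list(pd.date_range(start.normalize(), end.normalize(), freq="D"))


def daily_log_targets(
    cohort: pd.DataFrame,
    truth: SyntheticTruth,
    config: GeneratorConfig,
    met: pd.DataFrame,
) -> None:
    """Draw the day-level lognormal targets into ``truth.daily_log_target``.

    ``log target = log(city GM) + b_city + b_child + planted fixed effects
    + meteorology effects + Normal(0, sigma_day)``.
    """
    rng = np.random.default_rng([config.seed, 2])
    city_specs = {c.city_id: c for c in config.cities}
    met_idx = met.set_index(["city_id", "date"])
    dates = [pd.Timestamp(d) for d in sorted(met["date"].unique())]
    for _, row in cohort.iterrows():
        cid = row["child_id"]
        city = row["city_id"]
        spec = city_specs[city]
        _, sd_day = _city_log_sds(spec, config)
        base = (
            np.log(spec.gm)
            + truth.b_city[city]
            + truth.b_child[cid]
            + _child_fixed_log_effect(row, truth)
        )
        per_day = {}
        for d in dates:
            key = d.date().isoformat()
            m = met_idx.loc[(city, key)]
            per_day[key] = float(
                base + _met_log_effect(m, spec, truth)
                + rng.normal(0.0, sd_day)
            )
        truth.daily_log_target[cid] = per_day


def generate_daily_exposures(
    cohort: pd.DataFrame,
    truth: SyntheticTruth,
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fast path: daily mean exposures drawn directly from the day model.

    Produces one Monday-Thursday row per child with full coverage, for
    model-calibration studies that do not need minute traces.
    """
    monday = pd.Timestamp(config.schedule.week_monday)
    dates = [monday + pd.Timedelta(days=i) for i in range(4)]
    met = generate_meteorology(config, dates)
    daily_log_targets(cohort, truth, config, met)
    dow = {0: "Monday", 1: "Tuesday", 2: "Wednesday", 3: "Thursday"}
    city_specs = {c.city_id: c for c in config.cities}
    rows = []
    for _, row in cohort.iterrows():
        cid = row["child_id"]
        ratio = city_specs[row["city_id"]].home_ratio
        for d in dates:
            key = d.date().isoformat()
            pm25 = float(np.exp(truth.daily_log_target[cid][key]))
            rows.append({
                "child_id": cid,
                "date": key,
                "day_of_week": dow[d.dayofweek],
                "pm25_daily_mean": pm25,
                "pm10_daily_mean": pm25 / ratio,
                "valid_minutes": 1440,
            })
    return pd.DataFrame(rows), met


# ---------------------------------------------------------------------------
# Minute / second-level traces


def _schedule_arrays(minutes: pd.DatetimeIndex, config: GeneratorConfig):
    """Schedule label per minute plus the fraction through a commute leg."""
    sched = config.schedule
    hours = minutes.hour.to_numpy()
    mins = minutes.minute.to_numpy()
    dows = minutes.dayofweek.to_numpy()
    tod = hours * 60 + mins
    school_start = sched.school_start_hour * 60
    school_end = sched.school_end_hour * 60
    c1_start = school_start - sched.commute_minutes
    c2_end = school_end + sched.commute_minutes

    labels = np.array(["home"] * len(minutes), dtype=object)
    frac = np.zeros(len(minutes))
    weekday = dows < 5
    in_school = weekday & (tod >= school_start) & (tod < school_end)
    c1 = weekday & (tod >= c1_start) & (tod < school_start)
    c2 = weekday & (tod >= school_end) & (tod < c2_end)
    labels[in_school] = "school"
    labels[c1] = "commute"
    labels[c2] = "commute"
    frac[c1] = (tod[c1] - c1_start) / sched.commute_minutes  # home -> school
    frac[c2] = 1.0 - (tod[c2] - school_end) / sched.commute_minutes
    return labels, frac


def generate_minute_records(
    cohort: pd.DataFrame,
    truth: SyntheticTruth,
    config: GeneratorConfig,
    child_ids: Optional[Sequence[str]] = None,
    met: Optional[pd.DataFrame] = None,
) -> dict[str, pd.DataFrame]:
    """Minute-cadence records (with ground-truth labels) per child.

    The true minute exposure is ``exp(day target) x microenvironment factor
    x cooking spike x mean-one AR(1) lognormal noise``; PM10 is PM2.5
    divided by the label-specific ratio.  Observed GPS is the true position
    plus Gaussian jitter, with Markov dropout segments at the configured
    rate (plus a forced >12 h outage for ``long_gap_child_ids``).
    """
    sched = config.schedule
    monday = pd.Timestamp(sched.week_monday)
    start = monday + pd.Timedelta(hours=sched.start_weekday_hour)
    minutes = pd.date_range(start, periods=sched.duration_hours * 60, freq="min")
    if met is None:
        met = generate_meteorology(config, _window_dates(config))
    if not truth.daily_log_target:
        daily_log_targets(cohort, truth, config, met)

    city_specs = {c.city_id: c for c in config.cities}
    sched_labels, frac = _schedule_arrays(minutes, config)
    date_keys = minutes.normalize().map(lambda t: t.date().isoformat())
    hours = minutes.hour.to_numpy()
    n = len(minutes)

    if child_ids is None:
        child_ids = list(cohort["child_id"])
    sel = cohort.set_index("child_id", drop=False).loc[list(child_ids)]

    out: dict[str, pd.DataFrame] = {}
    for pos, (_, row) in enumerate(sel.iterrows()):
        cid = row["child_id"]
        rng = np.random.default_rng([config.seed, 3, pos])
        spec = city_specs[row["city_id"]]
        home = truth.home[cid]
        school = truth.school[cid]

        # true positions
        lat = np.full(n, home[0])
        lon = np.full(n, home[1])
        is_school = sched_labels == "school"
        lat[is_school], lon[is_school] = school
        is_comm = sched_labels == "commute"
        lat[is_comm] = home[0] + frac[is_comm] * (school[0] - home[0])
        lon[is_comm] = home[1] + frac[is_comm] * (school[1] - home[1])

        # geometric ground-truth labels (consistent with default geofences)
        d_home = equirect_distance_m(lat, lon, *home)
        d_school = equirect_distance_m(lat, lon, *school)
        true_label = np.where(
            d_home <= 100.0, "home",
            np.where(d_school <= 100.0, "school", sched_labels),
        ).astype(object)

        # exposure
        day_target = np.array(
            [truth.daily_log_target[cid][k] for k in date_keys]
        )
        env_factor = np.array(
            [config.microenv_factors.get(l, 1.0) for l in sched_labels]
        )
        spike = np.ones(n)
        if str(row["cooker_type"]) in BIOMASS_COOKERS:
            at_home = sched_labels == "home"
            for hr in config.cooking_spike_hours:
                spike[at_home & (hours == hr)] = config.cooking_spike_factor
        e = np.empty(n)
        innov = rng.normal(0.0, config.ar1_sigma * np.sqrt(1 - config.ar1_rho**2), n)
        e[0] = rng.normal(0.0, config.ar1_sigma)
        for t in range(1, n):
            e[t] = config.ar1_rho * e[t - 1] + innov[t]
        noise = np.exp(e - 0.5 * config.ar1_sigma**2)
        pm25 = np.exp(day_target) * env_factor * spike * noise
        ratio = np.array([
            {"home": spec.home_ratio, "school": spec.school_ratio,
             "commute": spec.commute_ratio}[l] for l in sched_labels
        ])
        pm10 = pm25 / ratio

        # GPS observation: jitter + dropout
        if config.gps_jitter_m > 0:
            dy = rng.normal(0.0, config.gps_jitter_m, n)
            dx = rng.normal(0.0, config.gps_jitter_m, n)
            obs_lat, obs_lon = _offset_latlon_arr(lat, lon, dx, dy)
        else:
            obs_lat, obs_lon = lat.copy(), lon.copy()
        drop = _dropout_mask(rng, n, config.dropout_rate, config.dropout_mean_min)
        if cid in config.long_gap_child_ids:
            gap_start = int((pd.Timestamp(sched.week_monday)
                             + pd.Timedelta(days=1, hours=15) - start)
                            / pd.Timedelta(minutes=1))
            gap_len = int(config.long_gap_hours * 60)
            drop[max(gap_start, 0): gap_start + gap_len] = True
        obs_lat[drop] = np.nan
        obs_lon[drop] = np.nan

        pm_valid = np.ones(n, dtype=bool)
        if config.pm_dropout_rate > 0:
            pm_valid = rng.random(n) >= config.pm_dropout_rate
        df = pd.DataFrame({
            "minute_start": minutes,
            "pm25_mean": np.where(pm_valid, pm25, np.nan),
            "pm10_mean": np.where(pm_valid, pm10, np.nan),
            "lat": obs_lat,
            "lon": obs_lon,
            "n_samples_valid": np.where(pm_valid, 60, 0),
            "pm_valid": pm_valid,
            "gps_valid": ~drop,
        })[MINUTE_COLUMNS]
        df["true_label"] = true_label
        out[cid] = df
        truth.true_labels[cid] = {
            "start": minutes[0].isoformat(),
            "labels": [str(l) for l in true_label],
        }
    return out


def _offset_latlon_arr(lat, lon, dx_m, dy_m):
    return (
        lat + dy_m / M_PER_DEG_LAT,
        lon + dx_m / (M_PER_DEG_LAT * np.cos(np.radians(lat))),
    )


def _dropout_mask(rng, n: int, rate: float, mean_len_min: float) -> np.ndarray:
    """Two-state Markov dropout with stationary occupancy ``rate``."""
    if rate <= 0:
        return np.zeros(n, dtype=bool)
    p_exit = 1.0 / max(mean_len_min, 1.0)
    p_enter = rate * p_exit / max(1.0 - rate, 1e-9)
    state = rng.random() < rate
    mask = np.empty(n, dtype=bool)
    u = rng.random(n)
    for i in range(n):
        mask[i] = state
        state = (u[i] >= p_exit) if state else (u[i] < p_enter)
    return mask


def generate_traces(
    cohort: pd.DataFrame,
    truth: SyntheticTruth,
    config: GeneratorConfig,
    out_dir: Optional[str | Path] = None,
    child_ids: Optional[Sequence[str]] = None,
) -> dict[str, pd.DataFrame]:
    """Expand minute records to 1-s samples (and optionally write CSVs).

    Within a minute the PM reading is held constant while each second gets
    an independent GPS jitter draw; dropout follows the minute mask.
    """
    minute_recs = generate_minute_records(cohort, truth, config, child_ids)
    out: dict[str, pd.DataFrame] = {}
    for pos, (cid, mdf) in enumerate(minute_recs.items()):
        rng = np.random.default_rng([config.seed, 4, pos])
        n_min = len(mdf)
        n = n_min * 60
        ts = pd.date_range(mdf["minute_start"].iloc[0], periods=n, freq="s")
        pm25 = np.repeat(mdf["pm25_mean"].to_numpy(float), 60)
        pm10 = np.repeat(mdf["pm10_mean"].to_numpy(float), 60)
        base_lat = np.repeat(mdf["lat"].to_numpy(float), 60)
        base_lon = np.repeat(mdf["lon"].to_numpy(float), 60)
        if config.gps_jitter_m > 0:
            dy = rng.normal(0.0, config.gps_jitter_m, n)
            dx = rng.normal(0.0, config.gps_jitter_m, n)
            lat, lon = _offset_latlon_arr(base_lat, base_lon, dx, dy)
        else:
            lat, lon = base_lat, base_lon
        samples = pd.DataFrame({
            "timestamp": ts, "pm25": pm25, "pm10": pm10,
            "lat": lat, "lon": lon,
        })
        if out_dir is not None:
            trace_dir = Path(out_dir)
            trace_dir.mkdir(parents=True, exist_ok=True)
            write_trace(samples, trace_dir / f"{cid}.csv")
        out[cid] = samples
    return out


def score_against_truth(
    labeled_by_child: Mapping[str, pd.DataFrame],
    truth: SyntheticTruth,
    fit_table: Optional[pd.DataFrame] = None,
    seed: Optional[int] = None,
) -> dict:
    """Tagging accuracy per child and (optionally) per-effect recovery.

    ``fit_table`` is the determinants-model table with ``term``, ``level``,
    ``beta``, ``ci_low``/``ci_high`` percent columns.
    """
    if seed is not None and seed != truth.seed:
        raise SeedMismatchError(
            f"outputs were produced with seed {seed}, truth with {truth.seed}"
        )
    per_child = {}
    for cid, labeled in labeled_by_child.items():
        truth_df = truth.labels_frame(cid)
        merged = labeled.drop(columns="true_label", errors="ignore").merge(
            truth_df, on="minute_start", how="inner"
        )
        acc = float((merged["label"] == merged["true_label"]).mean())
        per_child[cid] = acc
    card: dict = {
        "tagging_accuracy": per_child,
        "overall_accuracy": float(np.mean(list(per_child.values())))
        if per_child else np.nan,
    }
    if fit_table is not None:
        recovery = []
        for det, levels in truth.log_effects.items():
            for level, log_eff in levels.items():
                hit = fit_table[
                    (fit_table["term"] == det) & (fit_table["level"] == level)
                ]
                if len(hit) != 1:
                    continue
                r = hit.iloc[0]
                planted_pct = (np.exp(log_eff) - 1) * 100
                recovery.append({
                    "term": det, "level": level,
                    "planted_log_effect": log_eff,
                    "estimated_log_effect": float(r["beta"]),
                    "error_log": float(r["beta"]) - log_eff,
                    "planted_pct": planted_pct,
                    "estimated_pct": float(r["pct_change"]),
                    "ci_covers": bool(r["ci_low"] <= planted_pct <= r["ci_high"]),
                })
        card["effect_recovery"] = recovery
    return card
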
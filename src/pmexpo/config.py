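"""Configuration models.

Every threshold used anywhere in the pipeline lives here, so a single JSON
document can drive an end-to-end run reproducibly.  Defaults follow the
package's documented conventions (50% minute-validity rule, 100 m geofences,
strict >24 h continuous-data filter, WHO 24-h guidelines of 15/45 µg/m³).
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

# ---------------------------------------------------------------------------
# Pipeline-side parameters


class MinuteRules(BaseModel):
    """Second-to-minute aggregation rules."""

    min_valid_samples: int = 30  # >=30 of <=60 1-s samples -> minute PM valid
    pm_cap: float = 10_000.0  # hard physical cap, µg/m³; above -> invalid


class ValidityRules(BaseModel):
    """Inclusion/exclusion thresholds."""

    max_internal_gap_min: int = 5
    min_continuous_valid_minutes: int = 1440  # strict "> 24 h"
    gps_gap_hours: float = 12.0  # cumulative GPS-missing flag
    count_clock_time: bool = False  # False: count valid minutes only


class TagParams(BaseModel):
    """Geofence tagging parameters."""

    home_radius_m: float = 100.0
    school_radius_m: float = 100.0
    commute_window_min: int = 120
    carry_forward_limit_min: int = 60
    anchor_grid_m: float = 50.0
    overnight_window: tuple[int, int] = (22, 5)  # hours, wrapping midnight
    school_window: tuple[int, int] = (10, 14)
    min_window_fixes: int = 30


class MetricsParams(BaseModel):
    min_day_coverage_min: int = 1080  # 75% of a day
    who_pm25: float = 15.0
    who_pm10: float = 45.0
    ratio_pm10_floor: float = 1.0  # µg/m³ guard for per-minute ratios


class PipelineConfig(BaseModel):
    input_dir: Optional[str] = None
    out_dir: Optional[str] = None
    seed: int = 0
    minute_rules: MinuteRules = Field(default_factory=MinuteRules)
    validity: ValidityRules = Field(default_factory=ValidityRules)
    tagging: TagParams = Field(default_factory=TagParams)
    metrics: MetricsParams = Field(default_factory=MetricsParams)
    anchors_file: Optional[str] = None  # optional anchors.json overriding inference

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Synthetic-cohort generator parameters


class CitySpec(BaseModel):
    """One city: exposure distribution, meteorology climate and geography."""

    city_id: str
    gm: float  # geometric mean of daily PM2.5, µg/m³
    gsd: float  # geometric SD (dimensionless, > 1)
    n_children: int
    n_schools: int = 2
    home_ratio: float = 0.65  # PM2.5:PM10 per microenvironment
    school_ratio: float = 0.45
    commute_ratio: float = 0.60
    temp_mean: float = 24.0
    temp_sd: float = 3.0
    rh_mean: float = 65.0
    rh_sd: float = 10.0
    wind_mean: float = 3.0
    wind_sd: float = 1.0
    lat0: float = 0.0
    lon0: float = 30.0

    @field_validator("gm")
    @classmethod
    def _gm_pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("gm must be > 0")
        return v

    @field_validator("gsd")
    @classmethod
    def _gsd_gt1(cls, v: float) -> float:
        if v <= 1:
            raise ValueError("gsd must be > 1")
        return v


def default_cities() -> list[CitySpec]:
    # Six-city defaults: per-city lognormal exposure parameters, cohort sizes
    # and meteorology climatology used to calibrate the generator.
    rows = [
        ("Blantyre", 45.7, 1.6, 24, -15.786, 35.006, 28.2, 4.2, 44.4, 14.2, 3.8, 1.3),
        ("Durban", 18.8, 2.2, 47, -29.858, 31.021, 19.1, 1.9, 72.1, 8.9, 2.8, 0.8),
        ("Harare", 21.4, 1.6, 43, -17.830, 31.053, 22.5, 4.8, 54.8, 18.1, 4.0, 1.2),
        ("Kumasi", 18.3, 1.6, 61, 6.688, -1.624, 27.4, 2.0, 77.1, 8.9, 1.8, 0.6),
        ("Lagos", 24.1, 1.5, 61, 6.524, 3.379, 27.0, 1.2, 82.2, 5.7, 3.1, 0.8),
        ("Moshi", 29.1, 1.5, 61, -3.349, 37.341, 22.5, 2.2, 58.9, 8.9, 3.7, 1.5),
    ]
    return [
        CitySpec(
            city_id=c, gm=gm, gsd=gsd, n_children=n, lat0=lat, lon0=lon,
            temp_mean=tm, temp_sd=ts, rh_mean=rm, rh_sd=rs, wind_mean=wm, wind_sd=ws,
        )
        for c, gm, gsd, n, lat, lon, tm, ts, rm, rs, wm, ws in rows
    ]


COMMUTE_MODES = ["Motorised", "Walk", "Mixed mode", "No commute", "Unclassified"]
COOKER_LOCATIONS = ["Inside", "Outside", "Not reported"]
COOKER_TYPES = [
    "Electric", "Gas", "Gas and biomass", "Coal or wood (biomass)",
    "Kerosene", "Open fire and biomass", "Not reported",
]
LIGHTING_USES = [
    "Electric only", "Candle", "Candle and other", "Kerosene lamp and other",
    "Rechargeable, solar lamp or torch", "Not reported",
]
SMOKING_LEVELS = ["No smokers", "Presence of smokers", "Not reported"]
GENDERS = ["Female", "Male"]
BUSY_ROAD = ["Yes", "No", "Not reported"]
SCHOOL_SURFACES = ["Loose dirt", "Packed dirt", "Broken paving", "Paved"]
YES_NO = ["Yes", "No"]

DETERMINANT_LEVELS: dict[str, list[str]] = {
    "near_waste_burning_site": YES_NO,
    "near_construction_site": YES_NO,
    "help_with_cooking": YES_NO,
    "contact_with_animals": YES_NO,
    "commute_mode": COMMUTE_MODES,
    "cooker_location": COOKER_LOCATIONS,
    "cooker_type": COOKER_TYPES,
    "lighting_use": LIGHTING_USES,
    "smoking_at_home": SMOKING_LEVELS,
    "gender": GENDERS,
    "lives_near_busy_road": BUSY_ROAD,
    "school_ground_surface": SCHOOL_SURFACES,
}

# Reference levels used in the determinants model (one per categorical term).
DETERMINANT_REFERENCES: dict[str, str] = {
    "near_waste_burning_site": "No",
    "near_construction_site": "No",
    "help_with_cooking": "No",
    "contact_with_animals": "No",
    "commute_mode": "Walk",
    "cooker_location": "Inside",
    "cooker_type": "Electric",
    "lighting_use": "Electric only",
    "smoking_at_home": "No smokers",
    "gender": "Female",
    "lives_near_busy_road": "Yes",
    "school_ground_surface": "Loose dirt",
}


def default_prevalences() -> dict[str, dict[str, float]]:
    return {
        "near_waste_burning_site": {"Yes": 0.19, "No": 0.81},
        "near_construction_site": {"Yes": 0.08, "No": 0.92},
        "help_with_cooking": {"Yes": 0.26, "No": 0.74},
        "contact_with_animals": {"Yes": 0.15, "No": 0.85},
        "commute_mode": {
            "Motorised": 0.32, "Walk": 0.46, "Mixed mode": 0.09,
            "No commute": 0.09, "Unclassified": 0.04,
        },
        "cooker_location": {"Inside": 0.72, "Outside": 0.26, "Not reported": 0.02},
        "cooker_type": {
            "Electric": 0.40, "Gas": 0.26, "Gas and biomass": 0.21,
            "Coal or wood (biomass)": 0.06, "Kerosene": 0.02,
            "Open fire and biomass": 0.04, "Not reported": 0.01,
        },
        "lighting_use": {
            "Electric only": 0.33, "Candle": 0.18, "Candle and other": 0.16,
            "Kerosene lamp and other": 0.08,
            "Rechargeable, solar lamp or torch": 0.22, "Not reported": 0.03,
        },
        "smoking_at_home": {
            "No smokers": 0.79, "Presence of smokers": 0.19, "Not reported": 0.02,
        },
        "gender": {"Female": 0.60, "Male": 0.40},
        "lives_near_busy_road": {"Yes": 0.73, "No": 0.25, "Not reported": 0.02},
        "school_ground_surface": {
            "Loose dirt": 0.58, "Packed dirt": 0.06,
            "Broken paving": 0.07, "Paved": 0.29,
        },
    }


def default_effects() -> dict[str, dict[str, float]]:
    """Planted multiplicative determinant effects (calibration defaults)."""
    return {
        "smoking_at_home": {"Presence of smokers": 1.230},
        "cooker_type": {"Coal or wood (biomass)": 1.271},
        "lighting_use": {"Kerosene lamp and other": 1.302},
        "school_ground_surface": {"Paved": 0.628},
        "commute_mode": {"No commute": 0.817},
    }


class Schedule(BaseModel):
    """Weekday activity schedule driving the synthetic traces."""

    school_start_hour: int = 8
    school_end_hour: int = 14
    commute_minutes: int = 60  # commute windows precede/follow school
    start_weekday_hour: int = 10  # Monday ~10:00 deployment
    duration_hours: int = 96
    week_monday: str = "2021-09-06"  # a Monday inside the field campaign window


class GeneratorConfig(BaseModel):
    cities: list[CitySpec] = Field(default_factory=default_cities)
    sigma_location: float = 0.10  # log-scale city random-intercept SD
    sigma_child: float = 0.35  # log-scale child random-intercept SD
    sigma_day: float = 0.30  # log-scale day-level residual SD
    effects: dict[str, dict[str, float]] = Field(default_factory=default_effects)
    met_effects: dict[str, float] = Field(
        default_factory=lambda: {"temp_c": 1.056, "rh_pct": 1.0, "wind_ms": 0.916}
    )
    prevalences: dict[str, dict[str, float]] = Field(default_factory=default_prevalences)
    microenv_factors: dict[str, float] = Field(
        default_factory=lambda: {"home": 1.0, "school": 1.0, "commute": 1.0}
    )
    cooking_spike_factor: float = 4.0  # applied in biomass-cooker homes
    cooking_spike_hours: tuple[int, ...] = (5, 18)  # 05-06 h and 18-19 h
    schedule: Schedule = Field(default_factory=Schedule)
    gps_jitter_m: float = 30.0
    dropout_rate: float = 0.10
    dropout_mean_min: float = 10.0
    pm_dropout_rate: float = 0.0
    ar1_rho: float = 0.9
    ar1_sigma: float = 0.4
    long_gap_child_ids: list[str] = Field(default_factory=list)
    long_gap_hours: float = 14.0
    seed: int = 0

    @model_validator(mode="after")
    def _check_probs(self) -> "GeneratorConfig":
        for det, levels in self.prevalences.items():
            probs = list(levels.values())
            if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1.0) > 1e-6:
                raise ValueError(f"prevalences for {det!r} must lie in [0,1] and sum to 1")
        for det, levels in self.effects.items():
            if any(f <= 0 for f in levels.values()):
                raise ValueError(f"effect factors for {det!r} must be > 0")
        return self
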
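"""Minute-level microenvironment tagging from GPS geofences.

Anchors (home, school) are inferred from the GPS stream — home from the
densest 50 m grid cell of overnight fixes, school from school-hour fixes —
or supplied via configuration.  Each minute is labelled home / school /
commute / other / unknown; GPS-dropout minutes inherit the previous label
for a bounded carry-forward window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import TagParams

LABELS = ["home", "school", "commute", "other", "unknown"]
LABEL_SOURCES = ["geofence", "transition", "carry_forward", "none"]

EARTH_RADIUS_M = 6_371_000.0


class AnchorInferenceError(ValueError):
    """Too few GPS fixes in an anchor window to infer an anchor."""


class AnchorConflictError(ValueError):
    """Home and school anchors closer than the larger geofence radius."""


@dataclass
class AnchorSet:
    home: tuple[float, float]  # (lat, lon)
    school: tuple[float, float]
    home_radius_m: float = 100.0
    school_radius_m: float = 100.0
    provenance: str = "inferred"  # or "config"

    def __post_init__(self) -> None:
        if self.home_radius_m <= 0 or self.school_radius_m <= 0:
            raise ValueError("geofence radii must be > 0")
        sep = equirect_distance_m(*self.home, *self.school)
        if sep <= max(self.home_radius_m, self.school_radius_m):
            raise AnchorConflictError(
                f"home and school anchors {sep:.1f} m apart, closer than the "
                f"larger geofence radius"
            )


def equirect_distance_m(lat1, lon1, lat2, lon2):
    """Equirectangular-approximation distance in metres.

    Error < 0.1% at city scale, which is ample for 100 m geofences.
    Accepts scalars or arrays.
    """
    lat1, lon1 = np.radians(lat1), np.radians(lon1)
    lat2, lon2 = np.radians(lat2), np.radians(lon2)
    x = (lon2 - lon1) * np.cos(0.5 * (lat1 + lat2))
    y = lat2 - lat1
    return EARTH_RADIUS_M * np.hypot(x, y)


def _in_hour_window(hours: pd.Series, window: tuple[int, int]) -> pd.Series:
    lo, hi = window
    if lo <= hi:
        return (hours >= lo) & (hours < hi)
    return (hours >= lo) | (hours < hi)  # wraps midnight


def _densest_cell_centroid(
    lat: np.ndarray, lon: np.ndarray, grid_m: float
) -> tuple[float, float]:
    """Centroid of fixes in the densest grid cell and its 8 neighbours."""
    lat0, lon0 = lat.mean(), lon.mean()
    y = np.radians(lat - lat0) * EARTH_RADIUS_M
    x = np.radians(lon - lon0) * EARTH_RADIUS_M * np.cos(np.radians(lat0))
    ix = np.floor(x / grid_m).astype(int)
    iy = np.floor(y / grid_m).astype(int)
    cells, counts = np.unique(np.stack([ix, iy], axis=1), axis=0, return_counts=True)
    cx, cy = cells[np.argmax(counts)]
    near = (np.abs(ix - cx) <= 1) & (np.abs(iy - cy) <= 1)
    return float(lat[near].mean()), float(lon[near].mean())


def infer_anchors(
    minutes: pd.DataFrame,
    school_days: Iterable,
    params: Optional[TagParams] = None,
    home: Optional[tuple[float, float]] = None,
    school: Optional[tuple[float, float]] = None,
) -> AnchorSet:
    """Infer home/school anchors from GPS-valid minutes.

    Home uses overnight fixes (default 22:00-05:00), school uses
    school-hour fixes (default 10:00-14:00) restricted to ``school_days``.
    Explicit ``home``/``school`` coordinates override inference; provenance
    is ``config`` only when both are supplied.
    """
    params = params or TagParams()
    provenance = "config" if (home is not None and school is not None) else "inferred"
    school_days = {pd.Timestamp(d).date() for d in school_days}
    gps = minutes[minutes["gps_valid"].astype(bool)]
    ts = pd.to_datetime(gps["minute_start"])

    def window_centroid(mask: pd.Series, which: str) -> tuple[float, float]:
        sel = gps[mask.to_numpy()]
        if len(sel) < params.min_window_fixes:
            raise AnchorInferenceError(
                f"only {len(sel)} GPS-valid minutes in the {which} window "
                f"(need >= {params.min_window_fixes})"
            )
        return _densest_cell_centroid(
            sel["lat"].to_numpy(float), sel["lon"].to_numpy(float),
            params.anchor_grid_m,
        )

    if home is None:
        home = window_centroid(_in_hour_window(ts.dt.hour, params.overnight_window),
                               "overnight")
    if school is None:
        mask = _in_hour_window(ts.dt.hour, params.school_window) & ts.dt.date.isin(
            school_days
        )
        school = window_centroid(mask, "school-hours")
    return AnchorSet(
        home=home,
        school=school,
        home_radius_m=params.home_radius_m,
        school_radius_m=params.school_radius_m,
        provenance=provenance,
    )


def anchors_from_config(
    home: tuple[float, float], school: tuple[float, float],
    params: Optional[TagParams] = None,
) -> AnchorSet:
    params = params or TagParams()
    return AnchorSet(
        home=tuple(home), school=tuple(school),
        home_radius_m=params.home_radius_m,
        school_radius_m=params.school_radius_m,
        provenance="config",
    )


def tag_minutes(
    minutes: pd.DataFrame,
    anchors: AnchorSet,
    params: Optional[TagParams] = None,
) -> pd.DataFrame:
    """Label every minute with its microenvironment.

    GPS-valid minutes inside a geofence take that fence's label; minutes
    between a home-fence exit and the next school-fence entry (either
    direction) within ``commute_window_min`` become ``commute``; remaining
    GPS-valid minutes are ``other``.  GPS-invalid minutes carry the last
    label forward for at most ``carry_forward_limit_min`` minutes, then
    become ``unknown``.
    """
    params = params or TagParams()
    out = minutes.reset_index(drop=True).copy()
    n = len(out)
    labels = np.array(["unknown"] * n, dtype=object)
    sources = np.array(["none"] * n, dtype=object)
    if n == 0:
        out["label"], out["label_source"] = labels, sources
        return out

    gps_ok = out["gps_valid"].to_numpy(bool)
    lat = out["lat"].to_numpy(float)
    lon = out["lon"].to_numpy(float)
    d_home = np.full(n, np.inf)
    d_school = np.full(n, np.inf)
    d_home[gps_ok] = equirect_distance_m(lat[gps_ok], lon[gps_ok], *anchors.home)
    d_school[gps_ok] = equirect_distance_m(lat[gps_ok], lon[gps_ok], *anchors.school)

    in_home = gps_ok & (d_home <= anchors.home_radius_m)
    in_school = gps_ok & (d_school <= anchors.school_radius_m) & ~in_home
    labels[in_home] = "home"
    labels[in_school] = "school"
    labels[gps_ok & ~in_home & ~in_school] = "other"
    sources[gps_ok] = "geofence"

    # transition pass: between consecutive fence-labelled minutes of
    # opposite kind, within the commute window, GPS-valid minutes commute
    anchored = np.flatnonzero(in_home | in_school)
    for a, b in zip(anchored[:-1], anchored[1:]):
        if b - a - 1 == 0 or (b - a - 1) > params.commute_window_min:
            continue
        la = "home" if in_home[a] else "school"
        lb = "home" if in_home[b] else "school"
        if la != lb:
            span = slice(a + 1, b)
            mask = gps_ok[span]
            labels[span][mask] = "commute"  # slice views mutate in place
            sources[span][mask] = "transition"

    # carry-forward pass over GPS-invalid minutes
    last_label = None
    carried = 0
    for i in range(n):
        if gps_ok[i]:
            last_label = labels[i]
            carried = 0
        else:
            if last_label is not None and carried < params.carry_forward_limit_min:
                labels[i] = last_label
                sources[i] = "carry_forward"
                carried += 1
            else:
                labels[i] = "unknown"
                sources[i] = "none"

    out["label"] = labels
    out["label_source"] = sources
    return out


def tag_summary(labeled: pd.DataFrame) -> dict[str, int]:
    """Minute counts per label; keys cover all labels, values sum to n rows."""
    counts = {lab: 0 for lab in LABELS}
    if len(labeled):
        for lab, cnt in labeled["label"].value_counts().items():
            counts[str(lab)] = int(cnt)
    return counts


def school_minutes_by_day(
    labeled: pd.DataFrame, school_days: Sequence
) -> dict:
    """School-tagged minute count per school day (for the backpack check)."""
    days = {pd.Timestamp(d).date(): 0 for d in school_days}
    if len(labeled):
        sel = labeled[labeled["label"] == "school"]
        for d, cnt in sel.groupby(pd.to_datetime(sel["minute_start"]).dt.date).size().items():
            if d in days:
                days[d] = int(cnt)
    return days
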
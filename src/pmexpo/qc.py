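"""Inclusion/exclusion rules: the >24 h continuous-validity filter, the
cumulative >12 h GPS-gap flag, and the per-child exclusion ledger."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .config import ValidityRules

EXCLUSION_REASONS = [
    "no_questionnaire",
    "withdrew",
    "backpack_not_taken_to_school",
    "monitor_failure",
    "insufficient_continuous_data",
    "none",
]


class ConsistencyError(ValueError):
    """Cross-table inconsistency (e.g. trace for a child absent from cohort)."""


@dataclass
class ValidityReport:
    child_id: str
    total_minutes: int
    valid_pm_minutes: int
    longest_continuous_valid_minutes: int
    passes_24h: bool
    gps_missing_hours: float
    gps_gap_over_12h: bool

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ExclusionLedgerEntry:
    child_id: str
    status: str  # included | excluded
    reason: str  # from EXCLUSION_REASONS


def longest_valid_run(
    pm_valid: Iterable[bool], max_internal_gap_min: int = 5
) -> int:
    """Longest run of PM-valid minutes, counting valid minutes only.

    Invalid stretches of at most ``max_internal_gap_min`` minutes inside a
    run are tolerated (sensor hiccups) and do not contribute to the count;
    a longer invalid stretch ends the run.
    """
    flags = np.asarray(list(pm_valid), dtype=bool)
    best = cur = gap = 0
    for v in flags:
        if v:
            cur += 1
            gap = 0
            if cur > best:
                best = cur
        elif cur > 0:
            gap += 1
            if gap > max_internal_gap_min:
                cur = 0
                gap = 0
    return best


def validity_report(
    minutes: pd.DataFrame,
    child_id: str = "",
    rules: Optional[ValidityRules] = None,
) -> ValidityReport:
    """Summarise a minute table against the inclusion thresholds.

    ``passes_24h`` requires strictly more than ``min_continuous_valid_minutes``
    (default 1440) continuous valid minutes; ``gps_gap_over_12h`` flags a
    cumulative GPS outage above ``gps_gap_hours``.
    """
    rules = rules or ValidityRules()
    total = len(minutes)
    if total == 0:
        return ValidityReport(child_id, 0, 0, 0, False, 0.0, False)
    pm_valid = minutes["pm_valid"].to_numpy(bool)
    if rules.count_clock_time:
        # alternative interpretation: clock-time span of the longest run
        longest = _longest_run_clock(pm_valid, rules.max_internal_gap_min)
    else:
        longest = longest_valid_run(pm_valid, rules.max_internal_gap_min)
    gps_missing = float((~minutes["gps_valid"].to_numpy(bool)).sum()) / 60.0
    return ValidityReport(
        child_id=child_id,
        total_minutes=total,
        valid_pm_minutes=int(pm_valid.sum()),
        longest_continuous_valid_minutes=int(longest),
        passes_24h=longest > rules.min_continuous_valid_minutes,
        gps_missing_hours=gps_missing,
        gps_gap_over_12h=gps_missing > rules.gps_gap_hours,
    )


def _longest_run_clock(flags: np.ndarray, max_gap: int) -> int:
    best = 0
    start = None
    gap = 0
    last_valid = None
    for i, v in enumerate(flags):
        if v:
            if start is None:
                start = i
            last_valid = i
            gap = 0
            best = max(best, last_valid - start + 1)
        elif start is not None:
            gap += 1
            if gap > max_gap:
                start = None
                gap = 0
    return best


def reports_frame(reports: Iterable[ValidityReport]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in reports])


def build_exclusion_ledger(
    cohort: pd.DataFrame,
    questionnaire_ids: set[str],
    validity_reports: Mapping[str, ValidityReport],
    school_day_minutes: Mapping[str, Mapping] | None = None,
    withdrew_ids: set[str] | None = None,
) -> list[ExclusionLedgerEntry]:
    """One ledger entry per cohort child; reasons applied in a fixed order.

    ``school_day_minutes`` maps child -> {school day -> school-tagged minute
    count}; a child with zero school minutes on every school day is excluded
    as backpack-not-taken.  A monitored child missing from the cohort is a
    consistency error.
    """
    withdrew_ids = withdrew_ids or set()
    school_day_minutes = school_day_minutes or {}
    cohort_ids = list(cohort["child_id"])
    stray = set(validity_reports) - set(cohort_ids)
    if stray:
        raise ConsistencyError(f"trace(s) for child(ren) not in cohort: {sorted(stray)}")

    ledger = []
    for cid in cohort_ids:
        reason = "none"
        if cid not in questionnaire_ids:
            reason = "no_questionnaire"
        elif cid in withdrew_ids:
            reason = "withdrew"
        elif cid not in validity_reports:
            reason = "monitor_failure"
        else:
            days = school_day_minutes.get(cid)
            if days is not None and len(days) > 0 and all(
                v == 0 for v in days.values()
            ):
                reason = "backpack_not_taken_to_school"
            elif not validity_reports[cid].passes_24h:
                reason = "insufficient_continuous_data"
        status = "included" if reason == "none" else "excluded"
        ledger.append(ExclusionLedgerEntry(cid, status, reason))
    return ledger


def ledger_frame(ledger: Iterable[ExclusionLedgerEntry]) -> pd.DataFrame:
    return pd.DataFrame([asdict(e) for e in ledger])
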
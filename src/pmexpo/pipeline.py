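"""End-to-end orchestration: traces -> QC -> tagging -> metrics ->
determinants model, with a run manifest and fixed CSV output schemas."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import DETERMINANT_REFERENCES, PipelineConfig
from . import inference, metrics, qc, tagger, trace_io

log = logging.getLogger(__name__)

MET_TERMS = ["temp_c", "rh_pct", "wind_ms"]


class PipelineError(RuntimeError):
    """A stage failed; message carries stage name and child context."""


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _geometric_stats(values: np.ndarray) -> tuple[float, float]:
    lv = np.log(values[values > 0])
    gm = float(np.exp(lv.mean()))
    gsd = float(np.exp(lv.std(ddof=1))) if len(lv) > 1 else np.nan
    return gm, gsd


def cohort_table(
    cohort: pd.DataFrame,
    daily: pd.DataFrame,
    determinants: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Characteristics table: per-city columns plus an overall column.

    Count rows (children, monitored days, determinant-level day counts) sum
    across cities into the overall column; exposure summaries pool all
    child-days.  Percentages use each city's monitored-day count as the
    denominator, rounded to integer; exposure summaries use 1 decimal.
    """
    determinants = determinants if determinants is not None else [
        c for c in DETERMINANT_REFERENCES if c in cohort.columns
    ]
    cities = sorted(cohort["city_id"].unique())
    det_cols = [c for c in determinants if c in cohort.columns]
    merged = daily.merge(
        cohort[["child_id", "city_id"] + det_cols], on="child_id", how="left"
    )

    def per_city(frame: pd.DataFrame) -> dict[str, pd.DataFrame]:
        return {c: frame[frame["city_id"] == c] for c in cities}

    city_daily = per_city(merged)
    rows: list[dict] = []

    def count_row(name: str, fn) -> None:
        vals = {c: int(fn(city_daily[c])) for c in cities}
        rows.append({"row": name, "All": sum(vals.values()), **vals})

    count_row("n_children_monitored", lambda d: d["child_id"].nunique())
    count_row("n_days_monitored", len)

    day_totals = {c: len(city_daily[c]) for c in cities}
    total_days = sum(day_totals.values())
    for det in det_cols:
        for level in sorted(merged[det].dropna().unique()):
            vals, cells = {}, {}
            for c in cities:
                cnt = int((city_daily[c][det] == level).sum())
                vals[c] = cnt
                cells[c] = f"{cnt} ({metrics.percentage(cnt, day_totals[c])}%)"
            tot = sum(vals.values())
            rows.append({
                "row": f"{det}: {level}",
                "All": f"{tot} ({metrics.percentage(tot, total_days)}%)",
                **cells,
            })

    if len(merged):
        pooled = merged["pm25_daily_mean"].to_numpy(float)
        stats_rows = {
            "pm25_daily_median": lambda v: f"{np.median(v):.1f}",
            "pm25_daily_mean (SD)":
                lambda v: f"{v.mean():.1f} ({v.std(ddof=1):.1f})" if len(v) > 1
                else f"{v.mean():.1f} (..)",
            "pm25_daily_gm (GSD)":
                lambda v: "{:.1f} ({:.1f})".format(*_geometric_stats(v)),
        }
        for name, fn in stats_rows.items():
            cells = {}
            for c in cities:
                v = city_daily[c]["pm25_daily_mean"].to_numpy(float)
                cells[c] = fn(v) if len(v) else ""
            rows.append({"row": name, "All": fn(pooled), **cells})
    return pd.DataFrame(rows, columns=["row", "All", *cities])


def _model_terms(data: pd.DataFrame) -> list[inference.FixedTerm]:
    """Determinant terms observed with variation, plus day-of-week and
    meteorology; references fall back to the modal level when the
    configured reference is unobserved."""
    terms = []
    candidates = dict(DETERMINANT_REFERENCES)
    candidates["day_of_week"] = "Monday"
    for name, ref in candidates.items():
        if name not in data.columns:
            continue
        levels = data[name].value_counts()
        if len(levels) < 2:
            continue
        use_ref = ref if ref in levels.index else str(levels.index[0])
        terms.append(inference.FixedTerm(name, use_ref))
    for met_col in MET_TERMS:
        if met_col in data.columns and data[met_col].nunique() > 1:
            terms.append(inference.FixedTerm(met_col, None))
    return terms


def _fit_with_backoff(data: pd.DataFrame):
    """Fit the determinants model, greedily dropping aliased terms.

    Small (synthetic) cohorts can make school- or city-level determinants
    exactly collinear; the full model contract is to fail loudly, but the
    orchestrated run retries without the offending terms so the rest of the
    outputs still materialise.
    """
    terms = _model_terms(data)
    from .lmm import SingularDesignError

    while True:
        spec = inference.ModelSpec(outcome="pm25_daily_mean", fixed_terms=terms)
        try:
            return spec, inference.fit_lmm(spec, data)
        except SingularDesignError as exc:
            offending = [
                t for t in terms
                if f"Q('{t.name}')" in str(exc) or f"{t.name}" in str(exc)
            ]
            if not offending or len(offending) == len(terms):
                raise
            log.warning("dropping aliased model term(s): %s",
                        [t.name for t in offending])
            terms = [t for t in terms if t not in offending]


def run_pipeline(config: PipelineConfig, force: bool = False) -> Path:
    """Execute every stage on an input directory of traces + tables.

    Expects ``<input_dir>/traces/*.csv``, ``cohort.csv``, ``meteorology.csv``
    and optionally ``questionnaires.csv`` and ``anchors.json``.  Writes the
    full fixed output schema plus ``manifest.json`` to ``out_dir``.
    """
    t0 = time.time()
    in_dir = Path(config.input_dir or ".")
    out_dir = Path(config.out_dir or "out")
    trace_dir = in_dir / "traces"
    if not trace_dir.is_dir():
        raise PipelineError(f"stage=resolve_inputs: trace directory {trace_dir} missing")
    cohort_path = in_dir / "cohort.csv"
    met_path = in_dir / "meteorology.csv"
    for p in (cohort_path, met_path):
        if not p.exists():
            raise PipelineError(f"stage=resolve_inputs: required input {p} missing")
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort = trace_io.read_cohort(cohort_path)
    met = trace_io.read_meteorology(met_path)
    q_path = in_dir / "questionnaires.csv"
    questionnaire_ids = (
        set(pd.read_csv(q_path, dtype=str)["child_id"])
        if q_path.exists() else set(cohort["child_id"])
    )
    anchors_cfg: dict = {}
    a_path = Path(config.anchors_file) if config.anchors_file else in_dir / "anchors.json"
    if a_path.exists():
        anchors_cfg = json.loads(a_path.read_text())

    city_of_child = dict(zip(cohort["child_id"], cohort["city_id"]))
    reports: dict[str, qc.ValidityReport] = {}
    school_minutes: dict[str, dict] = {}
    labeled_frames: list[pd.DataFrame] = []
    failures: list[dict] = []

    def fail(stage: str, cid: str, exc: Exception):
        record = {"stage": stage, "child_id": cid, "error": str(exc)}
        failures.append(record)
        (out_dir / "failures.json").write_text(json.dumps(failures, indent=2))
        raise PipelineError(f"stage={stage} child_id={cid}: {exc}") from exc

    for trace_path in sorted(trace_dir.glob("*.csv")):
        cid = trace_path.stem
        try:
            trace = trace_io.read_trace(trace_path, config.minute_rules)
            minutes = trace_io.aggregate_minutes(trace.samples, config.minute_rules)
        except Exception as exc:  # noqa: BLE001
            fail("trace_io", cid, exc)
        try:
            reports[cid] = qc.validity_report(minutes, cid, config.validity)
        except Exception as exc:  # noqa: BLE001
            fail("qc_validity", cid, exc)
        try:
            ts = pd.to_datetime(minutes["minute_start"])
            school_days = sorted({
                t.date() for t in ts if t.dayofweek < 5
            })
            over = anchors_cfg.get(cid, {})
            anchors = tagger.infer_anchors(
                minutes, school_days, config.tagging,
                home=tuple(over["home"]) if "home" in over else None,
                school=tuple(over["school"]) if "school" in over else None,
            )
            labeled = tagger.tag_minutes(minutes, anchors, config.tagging)
        except Exception as exc:  # noqa: BLE001
            fail("microenv_tagger", cid, exc)
        school_minutes[cid] = tagger.school_minutes_by_day(labeled, school_days)
        labeled = labeled.copy()
        labeled.insert(0, "child_id", cid)
        labeled_frames.append(labeled)

    try:
        ledger = qc.build_exclusion_ledger(
            cohort, questionnaire_ids, reports, school_minutes
        )
    except Exception as exc:  # noqa: BLE001
        fail("qc_validity", "*", exc)
    included = {e.child_id for e in ledger if e.status == "included"}
    labeled_all = (
        pd.concat(labeled_frames, ignore_index=True)
        if labeled_frames else pd.DataFrame()
    )
    labeled_inc = (
        labeled_all[labeled_all["child_id"].isin(included)]
        if len(labeled_all) else labeled_all
    )

    try:
        daily = metrics.daily_means(labeled_inc, config.metrics)
        gap_children = {
            cid for cid, r in reports.items() if r.gps_gap_over_12h
        }
        micro = metrics.microenv_summaries(labeled_inc, gap_children, config.metrics)
        diurnal = metrics.diurnal_profiles(labeled_inc, city_of_child)
        compliance = metrics.guideline_compliance(daily, config.metrics)
        comp_pct = metrics.compliance_percentages(compliance)
    except Exception as exc:  # noqa: BLE001
        fail("exposure_metrics", "*", exc)

    model_table = pd.DataFrame()
    group_rows = []
    diag = pd.DataFrame()
    model_meta: dict = {}
    try:
        data = daily.merge(cohort, on="child_id", how="left")
        met_key = met.copy()
        met_key["date"] = met_key["date"].astype(str)
        data["date"] = data["date"].astype(str)
        data = data.merge(met_key, on=["city_id", "date"], how="left")
        if data["city_id"].nunique() >= 2 and len(data) > 10:
            spec, fit = _fit_with_backoff(data)
            model_table = fit.table
            model_meta = {
                "alpha": fit.alpha, "sigma2_location": fit.sigma2_location,
                "sigma2_child": fit.sigma2_child,
                "sigma2_resid": fit.sigma2_resid, "aic_ml": fit.aic,
                "df_method": fit.df_method, "ci": "wald",
                "converged": fit.converged, "n_obs": fit.n_obs,
            }
            try:
                diag = inference.model_vif(spec, data).rename_axis(
                    "column").reset_index()
                diag["max_vif"] = diag["vif"].max()
            except inference.CollinearityError as exc:
                diag = pd.DataFrame([{"column": "error", "vif": np.nan,
                                      "max_vif": np.nan}])
                model_meta["vif_error"] = str(exc)
        # rank tests: daily exposure across cities; microenv means per child
        city_groups = [
            g["pm25_daily_mean"].to_numpy(float)
            for _, g in data.groupby("city_id") if len(g)
        ]
        if len(city_groups) >= 2 and sum(map(len, city_groups)) >= 3:
            res = inference.group_test(
                city_groups, labels=sorted(data["city_id"].unique())
            )
            group_rows.append({"test": "daily_pm25_by_city", "H": res.H,
                               "df": res.df, "p": res.p})
            for pw in res.pairwise:
                group_rows.append({
                    "test": f"dunn:{pw.group_a}|{pw.group_b}", "H": np.nan,
                    "df": np.nan, "p": pw.p_holm,
                })
    except Exception as exc:  # noqa: BLE001
        fail("inference", "*", exc)

    tables = {
        "validity_report": qc.reports_frame(reports.values()),
        "exclusion_ledger": qc.ledger_frame(ledger),
        "labeled_minutes": labeled_all,
        "daily_exposure": daily,
        "microenv_summary": micro,
        "diurnal_profile": diurnal,
        "compliance": pd.DataFrame([{**compliance, **comp_pct}]),
        "determinants_model": model_table,
        "group_tests": pd.DataFrame(group_rows, columns=["test", "H", "df", "p"]),
        "diagnostics": diag,
        "characteristics_table": cohort_table(cohort, daily),
    }
    checksums = trace_io.write_outputs(tables, out_dir, force=force)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "inputs": {
            p.name: _sha256_file(p)
            for p in sorted(in_dir.rglob("*.csv"))
        },
        "outputs": checksums,
        "model": model_meta,
        "started": t0,
        "finished": time.time(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir
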
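import numpy as np
import pandas as pd
import pytest

from pmexpo import metrics, synth
from pmexpo.config import MetricsParams
from pmexpo.metrics import (
    compliance_percentages,
    daily_means,
    diurnal_profiles,
    guideline_compliance,
    microenv_summaries,
    percentage,
)

from conftest import make_minutes, small_generator_config


def _labeled(n, label="home", child_id="c1", **kw):
    df = make_minutes(n, child_id=child_id, **kw)
    df["label"] = label
    df["label_source"] = "geofence"
    return df


class TestDailyMeans:
    def test_constant_day(self):
        out = daily_means(_labeled(1440, pm25=10.0))
        assert len(out) == 1
        assert out["pm25_daily_mean"].iloc[0] == pytest.approx(10.0)
        assert out["day_of_week"].iloc[0] == "Monday"

    def test_half_and_half(self):
        pm = np.r_[np.full(720, 10.0), np.full(720, 30.0)]
        out = daily_means(_labeled(1440, pm25=pm))
        assert out["pm25_daily_mean"].iloc[0] == pytest.approx(20.0)

    def test_low_coverage_day_omitted(self):
        flags = np.array([True] * 900 + [False] * 540)
        out = daily_means(_labeled(1440, pm_valid=flags))
        assert len(out) == 0

    def test_friday_dropped(self):
        out = daily_means(_labeled(1440, start="2021-09-10 00:00"))  # a Friday
        assert len(out) == 0

    def test_mean_over_valid_minutes_only(self):
        flags = np.array([True] * 1080 + [False] * 360)
        pm = np.r_[np.full(1080, 10.0), np.full(360, 1000.0)]
        out = daily_means(_labeled(1440, pm25=pm, pm_valid=flags))
        assert out["pm25_daily_mean"].iloc[0] == pytest.approx(10.0)
        assert out["valid_minutes"].iloc[0] == 1080


class TestMicroenvSummaries:
    def test_all_home(self):
        out = microenv_summaries(_labeled(1440, pm25=10.0))
        row = out[out["label"] == "home"].iloc[0]
        assert row["time_proportion"] == pytest.approx(1.0)
        assert row["exposure_proportion"] == pytest.approx(1.0)

    def test_equal_minutes_weighted_exposure(self):
        home = _labeled(600, "home", pm25=10.0)
        school = _labeled(600, "school", pm25=30.0,
                          start="2021-09-06 10:00")
        out = microenv_summaries(pd.concat([home, school], ignore_index=True))
        tp = out.set_index("label")["time_proportion"]
        ep = out.set_index("label")["exposure_proportion"]
        assert tp["home"] == pytest.approx(0.5)
        assert ep["home"] == pytest.approx(0.25)
        assert ep["school"] == pytest.approx(0.75)

    def test_ratio_mean(self):
        out = microenv_summaries(_labeled(100, pm25=5.0, pm10=10.0))
        assert out["ratio_mean"].iloc[0] == pytest.approx(0.5)

    def test_ratio_guard_excludes_tiny_pm10(self):
        pm10 = np.r_[np.full(50, 10.0), np.full(50, 0.5)]
        out = microenv_summaries(_labeled(100, pm25=5.0, pm10=pm10))
        assert out["ratio_mean"].iloc[0] == pytest.approx(0.5)

    def test_gps_gap_child_loses_proportions_keeps_means(self):
        out = microenv_summaries(_labeled(200, pm25=12.0),
                                 gps_gap_children={"c1"})
        row = out.iloc[0]
        assert np.isnan(row["time_proportion"])
        assert np.isnan(row["exposure_proportion"])
        assert row["pm25_mean"] == pytest.approx(12.0)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(2)
        frames = []
        for i, lab in enumerate(["home", "school", "commute", "other"]):
            frames.append(_labeled(100 + 40 * i, lab,
                                   pm25=rng.lognormal(3, 0.4, 100 + 40 * i),
                                   start=f"2021-09-0{6+i} 00:00"))
        out = microenv_summaries(pd.concat(frames, ignore_index=True))
        assert out["time_proportion"].sum() == pytest.approx(1.0, abs=1e-9)
        assert out["exposure_proportion"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_conservation_of_total_exposure(self):
        rng = np.random.default_rng(4)
        labels = rng.choice(["home", "school", "commute"], size=1000)
        df = _labeled(1000, pm25=rng.lognormal(3, 0.5, 1000))
        df["label"] = labels
        out = microenv_summaries(df)
        total = (out["minutes"] * out["pm25_mean"]).sum()
        assert total == pytest.approx(df["pm25_mean"].sum(), rel=1e-9)


class TestDiurnalProfiles:
    def test_constant_trace_flat_profile(self):
        prof = diurnal_profiles(_labeled(2880, pm25=15.0), {"c1": "X"})
        filled = prof.dropna(subset=["mean"])
        np.testing.assert_allclose(filled["mean"], 15.0)
        np.testing.assert_allclose(filled["median"], 15.0)

    def test_quantile_ordering(self):
        rng = np.random.default_rng(9)
        df = pd.concat(
            [_labeled(2880, pm25=rng.lognormal(3, 0.6, 2880), child_id=f"c{i}")
             for i in range(5)],
            ignore_index=True,
        )
        prof = diurnal_profiles(df, {f"c{i}": "X" for i in range(5)})
        f = prof.dropna(subset=["mean"])
        assert (f["p5"] <= f["q25"]).all()
        assert (f["q25"] <= f["median"]).all()
        assert (f["median"] <= f["q75"]).all()
        assert (f["q75"] <= f["p95"]).all()

    def test_planted_evening_spike_dominates(self):
        prev = __import__("pmexpo.config", fromlist=["x"]).default_prevalences()
        prev["cooker_type"] = {
            k: (1.0 if k == "Coal or wood (biomass)" else 0.0)
            for k in prev["cooker_type"]
        }
        cfg = small_generator_config(
            seed=11, prevalences=prev, effects={}, cooking_spike_hours=(18,),
        )
        cohort, truth = synth.generate_cohort(cfg)
        recs = synth.generate_minute_records(cohort, truth, cfg)
        frames = []
        for cid, m in recs.items():
            d = m.copy()
            d.insert(0, "child_id", cid)
            d["label"] = d["true_label"]
            frames.append(d)
        prof = diurnal_profiles(pd.concat(frames, ignore_index=True),
                                {c: "A" for c in recs})
        means = prof.groupby("hour")["mean"].mean()
        assert means.idxmax() == 18

    def test_empty_city_gets_missing_rows(self):
        prof = diurnal_profiles(make_minutes(0, child_id=None).assign(label=[]),
                                {"c1": "X"})
        assert len(prof) == 24
        assert prof["n_child_hours"].sum() == 0


class TestGuidelineCompliance:
    def test_pm25_strict_inequality(self):
        daily = pd.DataFrame({
            "pm25_daily_mean": [10.0, 14.9, 15.0, 20.0, 44.9],
            "pm10_daily_mean": [20.0] * 5,
        })
        assert guideline_compliance(daily)["pm25_below"] == 2

    def test_pm10_strict_inequality(self):
        daily = pd.DataFrame({
            "pm25_daily_mean": [5.0] * 5,
            "pm10_daily_mean": [30.0, 44.9, 45.0, 50.0, 10.0],
        })
        assert guideline_compliance(daily)["pm10_below"] == 3

    def test_empty(self):
        counts = guideline_compliance(pd.DataFrame())
        assert counts == {"pm25_below": 0, "pm10_below": 0, "total_days": 0}

    def test_percentage_formatter(self):
        assert percentage(227, 1109) == 20
        assert percentage(1020, 1109) == 92
        assert percentage(1, 2) == 50
        assert percentage(0, 0) == 0
        pcts = compliance_percentages(
            {"pm25_below": 227, "pm10_below": 1020, "total_days": 1109}
        )
        assert pcts == {"pm25_pct_below": 20, "pm10_pct_below": 92}


class TestLognormalRecovery:
    def test_geometric_mean_of_daily_means(self):
        from pmexpo.config import CitySpec

        cfg = small_generator_config(
            cities=[CitySpec(city_id="A", gm=23.4, gsd=1.8, n_children=400,
                             lat0=-15.8, lon0=35.0)],
            seed=2, sigma_location=0.0, effects={},
            met_effects={"temp_c": 1.0, "rh_pct": 1.0, "wind_ms": 1.0},
        )
        cohort, truth = synth.generate_cohort(cfg)
        daily, _ = synth.generate_daily_exposures(cohort, truth, cfg)
        lg = np.log(daily["pm25_daily_mean"])
        gm = np.exp(lg.mean())
        assert gm == pytest.approx(23.4, rel=0.03)
        assert np.median(daily["pm25_daily_mean"]) == pytest.approx(23.4, rel=0.05)
        # the configured geometric SD is honoured too
        assert np.exp(lg.std()) == pytest.approx(1.8, rel=0.05)

    def test_school_ratio_lower_than_home_recovered(self):
        from pmexpo.config import CitySpec

        cfg = small_generator_config(
            cities=[CitySpec(city_id="A", gm=25.0, gsd=1.5, n_children=3,
                             lat0=-15.8, lon0=35.0,
                             home_ratio=0.7, school_ratio=0.4)],
            seed=5,
        )
        cohort, truth = synth.generate_cohort(cfg)
        recs = synth.generate_minute_records(cohort, truth, cfg)
        frames = []
        for cid, m in recs.items():
            d = m.copy()
            d.insert(0, "child_id", cid)
            d["label"] = d["true_label"]
            frames.append(d)
        out = microenv_summaries(pd.concat(frames, ignore_index=True))
        by_label = out.groupby("label")["ratio_mean"].mean()
        assert by_label["school"] < by_label["home"]
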
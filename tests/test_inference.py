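import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pmexpo import inference
from pmexpo.inference import (
    CollinearityError,
    FixedTerm,
    ModelSpec,
    aic_screen,
    dunn_posthoc,
    fit_lmm,
    holm_adjust,
    kruskal_wallis,
    percent_change,
    vif,
)
from pmexpo.lmm import SingularDesignError, fit_nested_lmm

from conftest import small_generator_config


class TestKruskalWallis:
    def test_worked_3x3_example(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)
        assert df == 2

    def test_symmetric_groups_h_zero(self):
        h, _, _ = kruskal_wallis([[1, 2], [1, 2]])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_values(self):
        h, _, p = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert h == 0.0 and p == 1.0

    def test_fewer_than_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])

    def test_empty_group(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1], []])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.integers(0, 6, rng.integers(3, 9)).astype(float)
                  for _ in range(rng.integers(2, 5))]
        h, df, p = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert h == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_p_within_monte_carlo_error_of_permutation_null(self):
        # large enough that the chi-square reference is in its asymptotic
        # regime; the permutation distribution is the exact null
        rng = np.random.default_rng(0)
        groups = [list(rng.normal(0, 1, 10)), list(rng.normal(0.4, 1, 9)),
                  list(rng.normal(0.8, 1, 11))]
        h_obs, _, p = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        n_perm = 20000
        count = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            parts = np.split(pooled, np.cumsum(sizes)[:-1])
            h_p, _, _ = kruskal_wallis(list(parts))
            if h_p >= h_obs - 1e-12:
                count += 1
        p_perm = count / n_perm
        # chi-square reference vs exact permutation null: generous MC band
        assert abs(p - p_perm) < 0.05


class TestDunn:
    def test_worked_pair_z(self):
        pw = dunn_posthoc([[1, 2, 3], [4, 5, 6], [7, 8, 9]],
                          labels=["A", "B", "C"])
        ac = next(c for c in pw if (c.group_a, c.group_b) == ("A", "C"))
        assert ac.z == pytest.approx(-6 / np.sqrt(7.5 * (2 / 3)), rel=1e-12)
        assert ac.z == pytest.approx(-2.683, abs=1e-3)

    def test_identical_groups(self):
        pw = dunn_posthoc([[1, 2, 3], [1, 2, 3]])
        assert pw[0].z == pytest.approx(0.0, abs=1e-12)
        assert pw[0].p_holm == 1.0

    def test_holm_ordering_invariant(self):
        rng = np.random.default_rng(1)
        pw = dunn_posthoc([rng.normal(size=6) for _ in range(4)])
        assert all(c.p_holm >= c.p_raw - 1e-15 for c in pw)
        by_raw = sorted(pw, key=lambda c: c.p_raw)
        holms = [c.p_holm for c in by_raw]
        assert holms == sorted(holms)


class TestHolm:
    def test_worked_example(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])

    def test_caps_at_one(self):
        adj = holm_adjust([0.5, 0.9])
        assert (adj <= 1.0).all()


class TestPercentChange:
    def test_zero(self):
        assert percent_change(0.0)[0] == 0.0

    def test_minus_log2(self):
        assert percent_change(-np.log(2))[0] == pytest.approx(-50.0)

    def test_worked_value(self):
        assert percent_change(0.2070)[0] == pytest.approx(23.0, abs=0.05)

    def test_ci_transform_monotone(self):
        point, lo, hi = percent_change(0.1, 0.05, df=30)
        assert lo < point < hi
        q = sps.t.ppf(0.975, 30)
        assert lo == pytest.approx((np.exp(0.1 - q * 0.05) - 1) * 100)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.1, -1.0)


class TestVif:
    def test_orthogonal_columns(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1], "b": [1, -1, 1, -1]})
        out = vif(X)
        np.testing.assert_allclose(out, [1.0, 1.0], atol=1e-12)

    def test_worked_example(self):
        X = pd.DataFrame({"x1": [1, 2, 3, 4], "x2": [1, 2, 3, 5]})
        out = vif(X)
        np.testing.assert_allclose(out, [29.1667, 29.1667], atol=1e-3)

    def test_exact_collinearity_names_column(self):
        X = pd.DataFrame({
            "x1": [1.0, 2, 3, 4], "x2": [1.0, 2, 3, 5],
        })
        X["x3"] = X["x1"] + X["x2"]
        with pytest.raises(CollinearityError, match="x3"):
            vif(X)


def _toy_daily(rng, n_city=3, n_child=6, n_day=4, beta_smoke=0.25):
    rows = []
    for i in range(n_city):
        ui = rng.normal(0, 0.15)
        for j in range(n_child):
            vj = rng.normal(0, 0.3)
            smoke = rng.random() < 0.3
            for k in range(n_day):
                mu = 3.0 + ui + vj + beta_smoke * smoke + rng.normal(0, 0.25)
                rows.append({
                    "city_id": f"c{i}", "child_id": f"c{i}_k{j}",
                    "pm25_daily_mean": float(np.exp(mu)),
                    "smoking": "yes" if smoke else "no",
                    "noise_cov": float(rng.normal()),
                })
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_constant_outcome_degenerate(self):
        df = pd.DataFrame({
            "city_id": ["a"] * 4 + ["b"] * 4,
            "child_id": list("pqrsPQRS"),
            "pm25_daily_mean": 7.0,
        })
        fit = fit_lmm(ModelSpec(outcome="pm25_daily_mean", fixed_terms=[]), df)
        assert fit.alpha == pytest.approx(np.log(7.0))
        assert fit.sigma2_location == fit.sigma2_child == fit.sigma2_resid == 0.0

    def test_balanced_matches_closed_form_anova(self):
        rng = np.random.default_rng(42)
        a, b, nd = 4, 5, 4
        rows = []
        for i in range(a):
            ui = rng.normal(0, 0.3)
            for j in range(b):
                vj = rng.normal(0, 0.5)
                for k in range(nd):
                    rows.append({
                        "city_id": f"c{i}", "child_id": f"c{i}_k{j}",
                        "y": 2.0 + ui + vj + rng.normal(0, 0.4),
                    })
        df = pd.DataFrame(rows)
        # closed-form nested ANOVA estimator (balanced design oracle)
        gm = df.y.mean()
        cm = df.groupby("city_id").y.mean()
        km = df.groupby(["city_id", "child_id"]).y.mean()
        ms_city = b * nd * ((cm - gm) ** 2).sum() / (a - 1)
        ms_child = (nd * ((km - km.index.get_level_values(0).map(cm)) ** 2).sum()
                    / (a * (b - 1)))
        ms_e = (((df.y - df.set_index(["city_id", "child_id"]).index.map(km)) ** 2)
                .sum() / (a * b * (nd - 1)))
        fit = fit_nested_lmm(
            df.y.to_numpy(), np.ones((len(df), 1)),
            df.city_id.to_numpy(), df.child_id.to_numpy(),
        )
        assert fit.sigma2_resid == pytest.approx(ms_e, abs=1e-6)
        assert fit.sigma2_child == pytest.approx((ms_child - ms_e) / nd, abs=1e-6)
        assert fit.sigma2_city == pytest.approx(
            (ms_city - ms_child) / (b * nd), abs=1e-6)

    def test_cross_checks_against_statsmodels(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(8)
        df = _toy_daily(rng)
        df["y"] = np.log(df["pm25_daily_mean"])
        sm_fit = smf.mixedlm(
            "y ~ C(smoking)", df, groups="city_id", re_formula="1",
            vc_formula={"child": "0 + C(child_id)"},
        ).fit(reml=True)
        fit = fit_lmm(
            ModelSpec(outcome="pm25_daily_mean",
                      fixed_terms=[FixedTerm("smoking", "no")]),
            df,
        )
        row = fit.table.iloc[0]
        assert row["beta"] == pytest.approx(sm_fit.fe_params.iloc[1], abs=2e-4)
        assert row["se"] == pytest.approx(sm_fit.bse_fe.iloc[1], abs=2e-4)
        assert fit.sigma2_resid == pytest.approx(sm_fit.scale, abs=1e-4)

    def test_satterthwaite_df_on_balanced_intercept(self):
        # balanced nested design: intercept df must equal n_cities - 1
        rng = np.random.default_rng(12)
        rows = []
        for i in range(5):
            ui = rng.normal(0, 0.5)
            for j in range(4):
                vj = rng.normal(0, 0.4)
                for k in range(3):
                    rows.append((f"c{i}", f"c{i}k{j}",
                                 1.0 + ui + vj + rng.normal(0, 0.3)))
        df = pd.DataFrame(rows, columns=["city", "child", "y"])
        fit = fit_nested_lmm(df.y.to_numpy(), np.ones((len(df), 1)),
                             df.city.to_numpy(), df.child.to_numpy())
        assert fit.df_method == "satterthwaite"
        assert fit.df[0] == pytest.approx(4.0, abs=0.05)

    def test_percent_change_table_consistency(self):
        rng = np.random.default_rng(3)
        df = _toy_daily(rng)
        fit = fit_lmm(
            ModelSpec(outcome="pm25_daily_mean",
                      fixed_terms=[FixedTerm("smoking", "no")]),
            df,
        )
        row = fit.table.iloc[0]
        assert row["pct_change"] == pytest.approx(
            (np.exp(row["beta"]) - 1) * 100)

    def test_nonpositive_outcome_rejected(self):
        df = _toy_daily(np.random.default_rng(0))
        df.loc[0, "pm25_daily_mean"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            fit_lmm(ModelSpec(outcome="pm25_daily_mean", fixed_terms=[]), df)

    def test_singular_design_names_aliased_column(self):
        df = _toy_daily(np.random.default_rng(1))
        df["dup"] = df["smoking"]
        with pytest.raises(SingularDesignError, match="dup"):
            fit_lmm(
                ModelSpec(outcome="pm25_daily_mean",
                          fixed_terms=[FixedTerm("smoking", "no"),
                                       FixedTerm("dup", "no")]),
                df,
            )


class TestAicScreen:
    def test_planted_kept_noise_dropped(self):
        rng = np.random.default_rng(3)
        df = _toy_daily(rng, n_city=4, n_child=10, beta_smoke=0.5)
        base = ModelSpec(outcome="pm25_daily_mean", fixed_terms=[])
        ledger = aic_screen(
            base,
            [FixedTerm("smoking", "no"), FixedTerm("noise_cov", None)],
            df,
        )
        decisions = dict(zip(ledger["candidate"], ledger["decision"]))
        assert decisions["smoking"] == "kept"
        assert decisions["noise_cov"] == "dropped"

    def test_empty_candidates(self):
        df = _toy_daily(np.random.default_rng(0))
        base = ModelSpec(outcome="pm25_daily_mean", fixed_terms=[])
        assert len(aic_screen(base, [], df)) == 0

    def test_candidate_in_base_rejected(self):
        df = _toy_daily(np.random.default_rng(0))
        base = ModelSpec(outcome="pm25_daily_mean",
                         fixed_terms=[FixedTerm("smoking", "no")])
        with pytest.raises(ValueError, match="already"):
            aic_screen(base, [FixedTerm("smoking", "no")], df)

    def test_candidate_missing_from_data(self):
        df = _toy_daily(np.random.default_rng(0))
        base = ModelSpec(outcome="pm25_daily_mean", fixed_terms=[])
        with pytest.raises(ValueError, match="ghost"):
            aic_screen(base, [FixedTerm("ghost", None)], df)
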
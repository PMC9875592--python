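"""Descriptives, logistic core, subgroups, tertiles, model ladder.

The logistic oracle here is a from-scratch Newton–Raphson iteration on the
log-likelihood written directly from the score and Hessian formulas — no
statsmodels involved — so the agreement check is a genuine dual route.
"""

import logging

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from dii_retinopathy.association import (
    FitError,
    assign_tertiles,
    descriptive_table,
    fit_logistic,
    ladder_terms,
    lrt,
    model_ladder,
    subgroup_analysis,
)


def newton_logistic(y, X, tol=1e-12, maxiter=100):
    """Independent ML logistic fit: Newton on the analytic score/Hessian."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (y - p)
        W = p * (1.0 - p)
        H = X.T @ (X * W[:, None])
        step = np.linalg.solve(H, score)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    ll = np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))
    return beta, ll


class TestDescriptiveTable:
    def frame(self):
        rng = np.random.default_rng(0)
        n = 300
        return pd.DataFrame(
            {
                "retinopathy": rng.integers(0, 2, n).astype(float),
                "edii": rng.normal(size=n),
                "smoking": rng.choice(["never", "ever", "current"], n),
            }
        )

    def test_continuous_t_test_matches_scipy(self):
        df = self.frame()
        out = descriptive_table(df, continuous=["edii"])
        a = df.loc[df.retinopathy == 0, "edii"]
        b = df.loc[df.retinopathy == 1, "edii"]
        assert out.loc[0, "p"] == pytest.approx(
            st.ttest_ind(a, b, equal_var=True).pvalue
        )

    def test_two_by_two_chi_square_published_counts(self):
        # published male/female by outcome cross-tabulation
        df = pd.DataFrame(
            {
                "gender": ["male"] * (1061 + 174) + ["female"] * (1037 + 131),
                "retinopathy": [0.0] * 1061 + [1.0] * 174 + [0.0] * 1037 + [1.0] * 131,
            }
        )
        out = descriptive_table(df, categorical=["gender"])
        p = out["p"].dropna().iloc[0]
        assert p == pytest.approx(0.034, abs=5e-4)

    def test_missing_level_shown_but_excluded_from_test(self):
        df = self.frame()
        df.loc[:20, "smoking"] = "Missing"
        out = descriptive_table(df, categorical=["smoking"])
        assert "Missing" in set(out["level"])
        tested = pd.crosstab(
            df.loc[df.smoking != "Missing", "smoking"],
            df.loc[df.smoking != "Missing", "retinopathy"],
        )
        expected = st.chi2_contingency(tested.to_numpy(), correction=False)[1]
        assert out["p"].dropna().iloc[0] == pytest.approx(expected)

    def test_zero_count_level_dropped_with_warning(self, caplog):
        df = self.frame()
        df["smoking"] = pd.Categorical(
            df["smoking"], categories=["never", "ever", "current", "pipe"]
        )
        with caplog.at_level(logging.WARNING):
            out = descriptive_table(df, categorical=["smoking"])
        assert "pipe" not in set(out["level"])
        assert any("dropping empty level" in r.message for r in caplog.records)


class TestFitLogistic:
    def test_two_by_two_equals_cross_product_ratio(self):
        a, b, c, d = 30, 10, 20, 40  # exposed/event layout
        df = pd.DataFrame(
            {
                "x": [1.0] * (a + b) + [0.0] * (c + d),
                "retinopathy": [1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d,
            }
        )
        fr = fit_logistic(df, ["x"])
        assert fr.term("x")["OR"] == pytest.approx(a * d / (b * c), rel=1e-6)

    def test_matches_independent_newton_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            n, k = 400, 4
            X = np.column_stack([np.ones(n), rng.normal(size=(n, k))])
            beta_true = rng.uniform(-0.7, 0.7, k + 1)
            y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta_true))).astype(float)
            df = pd.DataFrame(X[:, 1:], columns=[f"x{i}" for i in range(k)])
            df["retinopathy"] = y
            fr = fit_logistic(df, [f"x{i}" for i in range(k)])
            beta_o, ll_o = newton_logistic(y, X)
            assert np.allclose(fr.params, beta_o, atol=1e-6)
            assert fr.loglik == pytest.approx(ll_o, abs=1e-6)

    def test_null_ci_covers_one(self):
        rng = np.random.default_rng(7)
        n = 10000
        df = pd.DataFrame(
            {
                "edii": rng.normal(size=n),
                "retinopathy": (rng.random(n) < 0.15).astype(float),
            }
        )
        t = fit_logistic(df, ["edii"]).term("edii")
        assert t["ci_low"] < 1.0 < t["ci_high"]

    def test_separation_raises(self):
        df = pd.DataFrame(
            {"x": np.arange(40.0), "retinopathy": (np.arange(40) >= 20).astype(float)}
        )
        with pytest.raises(FitError):
            fit_logistic(df, ["x"])

    def test_collinear_terms_named(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x1": rng.normal(size=60)})
        df["x2"] = 2.0 * df["x1"]
        df["retinopathy"] = (rng.random(60) < 0.4).astype(float)
        with pytest.raises(FitError, match="collinear.*x2"):
            fit_logistic(df, ["x1", "x2"])

    def test_ci_bounds_ordered_and_or_positive(self, study_cohort):
        df, _ = study_cohort
        frame = fit_logistic(df, ["edii", "age"]).summary_frame()
        assert (frame["ci_low"] < frame["ci_high"]).all()
        assert (frame["OR"] > 0).all()


class TestLRT:
    def test_nonnegative_and_monotone_loglik(self):
        rng = np.random.default_rng(11)
        n = 500
        df = pd.DataFrame(
            {
                "x1": rng.normal(size=n),
                "x2": rng.normal(size=n),
                "retinopathy": (rng.random(n) < 0.3).astype(float),
            }
        )
        f0 = fit_logistic(df, ["x1"])
        f1 = fit_logistic(df, ["x1", "x2"])
        stat, df_, p = lrt(f1, f0)
        assert stat >= 0.0 and df_ == 1 and 0.0 <= p <= 1.0
        assert f1.loglik >= f0.loglik

    def test_wald_and_lrt_agree_on_nulls(self):
        # under the null both p-values should be uniform and nearly equal
        rng = np.random.default_rng(13)
        wald, like = [], []
        for _ in range(500):
            n = 400
            df = pd.DataFrame(
                {
                    "x": rng.normal(size=n),
                    "retinopathy": (rng.random(n) < 0.3).astype(float),
                }
            )
            full = fit_logistic(df, ["x"])
            red = fit_logistic(df, [])
            wald.append(float(full.term("x")["p"]))
            like.append(lrt(full, red)[2])
        wald, like = np.array(wald), np.array(like)
        assert st.kstest(wald, "uniform").pvalue > 0.01
        assert st.kstest(like, "uniform").pvalue > 0.01
        assert np.corrcoef(wald, like)[0, 1] > 0.99


class TestSubgroups:
    def test_identical_strata_give_zero_interaction_statistic(self):
        rng = np.random.default_rng(17)
        half = pd.DataFrame(
            {
                "edii": rng.normal(size=300),
                "retinopathy": (rng.random(300) < 0.3).astype(float),
            }
        )
        df = pd.concat(
            [half.assign(g="A"), half.assign(g="B")], ignore_index=True
        )
        out = subgroup_analysis(df, ["g"])
        assert out.interaction_p["g"] == pytest.approx(1.0, abs=1e-6)

    def test_ns_reconcile_with_cohort_counts(self, study_cohort):
        df, _ = study_cohort
        out = subgroup_analysis(
            df, ["glycemic_status", "age_group", "pir_band", "smoking"]
        )
        analyzed = df["edii"].notna() & df["retinopathy"].notna()
        for g, sub in out.rows.groupby("grouping"):
            assert sub["n"].sum() == int((analyzed & df[g].notna()).sum())

    def test_interaction_p_present_per_grouping(self, study_cohort):
        df, _ = study_cohort
        out = subgroup_analysis(df, ["glycemic_status", "gender"])
        assert set(out.interaction_p) == {"glycemic_status", "gender"}
        assert all(0 <= p <= 1 for p in out.interaction_p.values())

    def test_low_event_stratum_flagged_unstable(self):
        rng = np.random.default_rng(19)
        df = pd.DataFrame(
            {
                "edii": rng.normal(size=400),
                "g": ["A"] * 360 + ["B"] * 40,
                "retinopathy": 0.0,
            }
        )
        df.loc[: 100, "retinopathy"] = 1.0  # events only in A
        df.loc[df.index[-3:], "retinopathy"] = 1.0  # 3 events in B
        out = subgroup_analysis(df, ["g"])
        flag = dict(zip(out.rows["stratum"], out.rows["unstable"]))
        assert flag["B"] and not flag["A"]

    def test_single_stratum_grouping_rejected(self):
        df = pd.DataFrame(
            {"edii": np.arange(60.0), "g": "A", "retinopathy": [0.0, 1.0] * 30}
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            subgroup_analysis(df, ["g"])


class TestTertiles:
    def test_one_to_nine(self):
        t = assign_tertiles(pd.Series(np.arange(1.0, 10.0)))
        assert t.tertile.tolist() == [1, 1, 1, 2, 2, 2, 3, 3, 3]

    def test_999_continuous_split_evenly(self):
        rng = np.random.default_rng(23)
        t = assign_tertiles(pd.Series(rng.normal(size=999)))
        assert sorted(t.tertile.value_counts().tolist()) == [333, 333, 333]

    def test_ties_at_cut_go_to_lower_tertile(self):
        vals = pd.Series([1.0, 2.0, 2.0, 2.0, 3.0, 4.0])
        t = assign_tertiles(vals)
        c1 = t.cuts[0]
        assert (vals[t.tertile == 1] <= c1).all()
        assert 2.0 in vals[t.tertile == 1].values

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            assign_tertiles(pd.Series([1.0, 1.0, 2.0, 2.0]))


class TestModelLadder:
    def test_ladder_term_sets_are_nested(self):
        sets = ladder_terms()
        assert sets["unadjusted"] == []
        assert set(sets["model_i"]) < set(sets["model_ii"]) < set(sets["model_iii"])
        assert "age" in sets["model_i"]
        assert "age" not in ladder_terms(drop_age=True)["model_i"]

    def test_ladder_on_study_cohort(self, study_cohort):
        df, _ = study_cohort
        dm = df["glycemic_status"] == "diabetes"
        lad = model_ladder(df, subset=dm)
        frame = lad.frame()
        assert list(frame.index) == ["unadjusted", "model_i", "model_ii", "model_iii"]
        assert (frame["per_unit_OR"] > 0).all()
        assert frame["p_trend"].between(0, 1).all()
        # cut points come from the total sample, not the subset
        assert lad.cuts == assign_tertiles(df["edii"]).cuts

    def test_tertile_fits_use_lowest_tertile_as_reference(self, study_cohort):
        df, _ = study_cohort
        lad = model_ladder(df)
        tert = lad.models["unadjusted"]["tertiles"]
        labels = [t for t in tert.terms if "Treatment" in t]
        assert len(labels) == 2  # tertiles 2 and 3 vs reference 1

    def test_nested_logliks_monotone(self, study_cohort):
        df, _ = study_cohort
        lad = model_ladder(df)
        lls = [lad.models[m]["continuous"].loglik for m in
               ("unadjusted", "model_i", "model_ii", "model_iii")]
        assert all(b >= a - 1e-8 for a, b in zip(lls, lls[1:]))
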
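"""Cox partial likelihood, spline basis, diagnostics and model comparison."""

import json
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import brecansurv.coxmodel as cx
from brecansurv import (
    Cohort,
    DesignSpec,
    SimulationConfig,
    fit_cox,
    fit_from_json,
    fit_to_json,
    hazard_ratio_table,
    nomogram_points,
    predict_overall_survival,
    rcs_basis,
    simulate_cohort,
)
from brecansurv.coxmodel import (
    CoxFit,
    cox_log_partial_likelihood,
    fit_cox_arrays,
    schoenfeld_diagnostic,
    time_varying_ratio_test,
)


def two_group_exponential(n, rate0, hr, seed, censor=10.0):
    """Exponential event times with a binary covariate multiplying the rate."""
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < 0.5).astype(float)
    t = rng.exponential(1.0 / (rate0 * hr**x))
    stop = np.minimum(t, censor)
    event = t < censor
    return stop, event, x


class TestRcsBasis:
    def test_three_knots_give_two_columns(self):
        ages = np.linspace(30, 80, 200)
        basis = rcs_basis(ages, 3)
        assert basis.transform(ages).shape == (200, 2)
        assert basis.n_terms == 2

    def test_linear_beyond_boundary_knots(self):
        basis = rcs_basis(np.linspace(30, 80, 200), 4)
        for xs in (np.array([20.0, 22.0, 24.0]), np.array([90.0, 92.0, 94.0])):
            mat = basis.transform(xs)
            second_diff = mat[2] - 2 * mat[1] + mat[0]
            assert np.allclose(second_diff, 0.0, atol=1e-9)

    def test_matches_textbook_truncated_power_formula(self):
        """Brute-force evaluation of the restricted-cubic definition."""
        knots = np.array([40.0, 55.0, 75.0])
        basis = cx.SplineBasis(knots)
        x = np.linspace(25, 95, 57)
        t1, t2, t3 = knots

        def plus3(v):
            return np.where(v > 0, v, 0.0) ** 3

        expected = (
            plus3(x - t1)
            - plus3(x - t2) * (t3 - t1) / (t3 - t2)
            + plus3(x - t3) * (t2 - t1) / (t3 - t2)
        ) / (t3 - t1) ** 2
        got = basis.transform(x)
        assert np.allclose(got[:, 0], x)
        assert np.allclose(got[:, 1], expected, atol=1e-12)

    def test_too_few_distinct_ages(self):
        with pytest.raises(ValueError):
            rcs_basis(np.array([50.0, 50.0, 60.0]), 3)


class TestPartialLikelihood:
    def test_null_loglik_is_minus_log_risk_set_sizes(self):
        # 3 subjects, all events at times 1 < 2 < 3: -ln 3 - ln 2 - ln 1
        ll = cox_log_partial_likelihood(
            [0.0], stop=[1.0, 2.0, 3.0], event=[True] * 3, X=[[1.0], [0.0], [1.0]]
        )
        assert ll == -np.log(6)

    def test_null_loglik_general_path_agrees(self):
        stop, event, x = two_group_exponential(80, 0.1, 2.0, seed=3)
        ll_fast = cox_log_partial_likelihood([0.0], stop, event, x)
        ll_gen = cox_log_partial_likelihood(
            [0.0], stop, event, x, start=np.zeros(len(stop))
        )
        # start-stop rows route through the per-event-time path
        assert ll_gen == pytest.approx(ll_fast, abs=1e-10)

    def test_two_group_hazard_ratio_recovery(self):
        stop, event, x = two_group_exponential(2000, 0.05, 2.0, seed=7)
        fit = fit_cox_arrays(stop, event, x)
        assert 1.8 <= np.exp(fit.beta.iloc[0]) <= 2.2

    def test_duplicating_records_halves_variance(self):
        stop, event, x = two_group_exponential(400, 0.08, 1.7, seed=11)
        f1 = fit_cox_arrays(stop, event, x)
        f2 = fit_cox_arrays(np.r_[stop, stop], np.r_[event, event], np.r_[x, x])
        assert f2.beta.iloc[0] == pytest.approx(f1.beta.iloc[0], abs=1e-6)
        assert f2.se().iloc[0] == pytest.approx(f1.se().iloc[0] / np.sqrt(2), rel=0.01)

    def test_affine_recoding_maps_beta(self):
        stop, event, x = two_group_exponential(500, 0.08, 2.0, seed=13)
        f1 = fit_cox_arrays(stop, event, x)
        f2 = fit_cox_arrays(stop, event, 3.0 * x + 5.0)
        assert f2.beta.iloc[0] == pytest.approx(f1.beta.iloc[0] / 3.0, abs=1e-7)

    def test_efron_equals_breslow_without_ties(self):
        stop, event, x = two_group_exponential(300, 0.08, 2.0, seed=17)
        fb = fit_cox_arrays(stop, event, x, ties="breslow")
        fe = fit_cox_arrays(stop, event, x, ties="efron")
        assert fe.beta.iloc[0] == pytest.approx(fb.beta.iloc[0], abs=1e-9)

    def test_separation_raises_informative_error(self):
        # covariate perfectly ordering event times => monotone likelihood
        stop = np.arange(1.0, 21.0)
        event = np.ones(20, bool)
        x = (stop > 10).astype(float)
        with pytest.raises(cx.ConvergenceError):
            fit_cox_arrays(stop, event, x)

    def test_breslow_baseline_martingale_balance(self):
        """Sum of baseline jumps weighted by the risk-set exp(eta) equals
        the event count (martingale residuals sum to zero)."""
        stop, event, x = two_group_exponential(400, 0.08, 2.0, seed=19)
        fit = fit_cox_arrays(stop, event, x)
        eta = x * fit.beta.iloc[0]
        cum0 = np.concatenate([[0.0], fit.baseline_cumhaz])
        lam = cum0[np.searchsorted(fit.baseline_times, stop, side="right")]
        martingale = event.astype(float) - lam * np.exp(eta)
        assert abs(martingale.sum()) < 1e-6
        assert np.all(np.diff(fit.baseline_cumhaz) >= 0)

    def test_lifelines_cross_check(self):
        """Independent oracle: coefficients and profile-level cumulative
        hazard agree with lifelines on untied data."""
        from lifelines import CoxPHFitter

        cfg = replace(SimulationConfig(seed=5), n=500)
        cohort = simulate_cohort(cfg)
        fit = fit_cox(cohort, DesignSpec.C2())
        df = cohort.with_adherence_class()
        ll_df = pd.DataFrame({
            "T": np.maximum(df["followup_years"], 1e-9),
            "E": df["dead"].astype(int),
            "age": df["age_dx"],
            "her2_pos": (df["her2"] == "pos").astype(float),
            "stage_II": (df["stage"] == "II").astype(float),
            "stage_III": (df["stage"] == "III").astype(float),
            "adherent": (df["adherence_class"] == "adherent").astype(float),
        })
        cph = CoxPHFitter()
        cph.fit(ll_df, duration_col="T", event_col="E")
        for term in fit.terms:
            assert fit.beta[term] == pytest.approx(cph.params_[term], abs=1e-4)
        profile = {"age": 62.0, "stage": "II", "her2": "neg",
                   "adherence": "adherent"}
        # compare at exact event times (lifelines interpolates between them)
        times = fit.baseline_times[[10, 40, 70]]
        mine = cx.predict_cumulative_hazard(fit, profile, times)
        row = pd.DataFrame([{"age": 62.0, "her2_pos": 0.0, "stage_II": 1.0,
                             "stage_III": 0.0, "adherent": 1.0}])
        theirs = cph.predict_cumulative_hazard(row, times=times).to_numpy().ravel()
        assert np.allclose(mine, theirs, rtol=1e-6)


class TestDesigns:
    def test_c1_categorical_age_terms(self, sim_bundle):
        cohort, _, _ = sim_bundle
        fit = fit_cox(cohort, DesignSpec.C1())
        assert {"age_50_59", "age_60_74", "age_75_84"} <= set(fit.terms)
        assert fit.aic == pytest.approx(
            2 * len(fit.beta) - 2 * fit.log_partial_likelihood
        )

    def test_c4_episode_split_keeps_event_count(self, sim_bundle):
        cohort, _, fit3 = sim_bundle
        fit4 = fit_cox(cohort, DesignSpec.C4())
        assert fit4.n_events == fit3.n_events
        assert {"adherent_early", "adherent_late"} <= set(fit4.terms)

    def test_c4_with_constant_truth_ratio_ci_covers_one(self, sim_bundle):
        cohort, _, _ = sim_bundle
        fit4 = fit_cox(cohort, DesignSpec.C4())
        tv = time_varying_ratio_test(fit4)
        assert tv.ci_low <= 1.0 <= tv.ci_high  # simulated effect is constant
        assert tv.ratio == pytest.approx(tv.hr_early / tv.hr_late, rel=1e-12)

    def test_time_varying_ratio_arithmetic(self):
        terms = ["adherent_early", "adherent_late"]
        fit = CoxFit(
            design=DesignSpec.C4(),
            beta=pd.Series([np.log(0.58), np.log(0.57)], index=terms),
            vcov=pd.DataFrame(np.diag([0.04, 0.04]), index=terms, columns=terms),
            baseline_times=np.array([1.0]), baseline_cumhaz=np.array([0.1]),
            log_partial_likelihood=0.0, aic=0.0, n_events=100, n=1000,
        )
        tv = time_varying_ratio_test(fit)
        assert round(tv.ratio, 2) == 1.02
        # equal coefficients give ratio exactly 1
        fit.beta["adherent_late"] = fit.beta["adherent_early"]
        assert time_varying_ratio_test(fit).ratio == 1.0


class TestHazardRatioTable:
    def test_reference_rows_and_wald_interval(self):
        terms = ["adherent"]
        fit = CoxFit(
            design=DesignSpec.C3(),
            beta=pd.Series([-0.5447], index=terms),
            vcov=pd.DataFrame([[0.17**2]], index=terms, columns=terms),
            baseline_times=np.array([1.0]), baseline_cumhaz=np.array([0.1]),
            log_partial_likelihood=0.0, aic=0.0, n_events=100, n=1000,
        )
        tab = hazard_ratio_table(fit)
        ref = tab[tab["display"] == "Ref"]
        assert list(ref["variable"]) == ["adherence"]
        row = tab[tab["term"] == "adherent"].iloc[0]
        assert row["hr"] == pytest.approx(0.58, abs=0.005)
        assert row["ci_low"] == pytest.approx(0.42, abs=0.005)
        assert row["ci_high"] == pytest.approx(0.81, abs=0.005)

    def test_zero_beta_gives_unit_hr(self, sim_bundle):
        _, _, fit = sim_bundle
        tab = hazard_ratio_table(fit)
        est = tab.dropna(subset=["hr"])
        assert ((est["ci_low"] <= est["hr"]) & (est["hr"] <= est["ci_high"])).all()


class TestPredictOverallSurvival:
    def test_exponential_large_sample(self):
        rng = np.random.default_rng(23)
        n = 4000
        t = rng.exponential(1 / 0.05, n)
        stop = np.minimum(t, 12.0)
        event = t < 12.0
        x = (rng.random(n) < 0.5).astype(float)  # pure noise covariate
        fit = fit_cox_arrays(stop, event, x)
        cum0 = np.concatenate([[0.0], fit.baseline_cumhaz])
        lam10 = cum0[np.searchsorted(fit.baseline_times, 10.0, side="right")]
        os10 = np.exp(-lam10 * np.exp(0.0))
        assert os10 == pytest.approx(np.exp(-0.5), abs=0.03)

    def test_monotone_and_starts_at_one(self, sim_bundle):
        _, _, fit = sim_bundle
        grid = np.arange(0, 121) / 12.0
        for stage in ("I", "II", "III"):
            os_ = predict_overall_survival(
                fit, {"age": 61.0, "stage": stage, "her2": "pos",
                      "adherence": "non_adherent"}, grid)
            assert os_.iloc[0] == 1.0
            assert np.all(np.diff(os_.values) <= 1e-12)

    def test_extrapolation_warns_and_is_flat(self, sim_bundle):
        _, _, fit = sim_bundle
        t_last = fit.baseline_times[-1]
        with pytest.warns(UserWarning, match="extrapolat"):
            os_ = predict_overall_survival(
                fit, {"age": 61.0, "stage": "I", "her2": "neg",
                      "adherence": "adherent"},
                np.array([0.0, t_last, t_last + 5.0]))
        assert os_.iloc[-1] == os_.iloc[-2]

    def test_incomplete_profile_rejected(self, sim_bundle):
        _, _, fit = sim_bundle
        with pytest.raises(KeyError, match="adherence"):
            predict_overall_survival(fit, {"age": 61.0, "stage": "I",
                                           "her2": "neg"}, [0.0, 1.0])


class TestSchoenfeld:
    def test_residuals_sum_to_zero_at_mle(self, sim_bundle):
        _, _, fit = sim_bundle
        _, resid = fit._pl.schoenfeld(fit.beta.values)
        assert np.max(np.abs(resid.sum(axis=0))) < 1e-8

    def test_constant_effect_flag_mostly_proportional(self):
        hits = 0
        reps = 100
        for s in range(reps):
            stop, event, x = two_group_exponential(400, 0.12, 2.0, seed=1000 + s)
            fit = fit_cox_arrays(stop, event, x, names=["grp"])
            if schoenfeld_diagnostic(fit, "grp").proportional:
                hits += 1
        assert hits >= 0.90 * reps

    def test_reversing_effect_flag_mostly_non_proportional(self):
        def reversing(n, seed):
            # log-HR +1 before t=4, -1 after: strong non-proportionality
            rng = np.random.default_rng(seed)
            x = (rng.random(n) < 0.5).astype(float)
            h1 = 0.15 * np.exp(1.0 * x)
            h2 = 0.15 * np.exp(-1.0 * x)
            e = rng.exponential(size=n)
            t = np.where(e < h1 * 4.0, e / h1, 4.0 + (e - h1 * 4.0) / h2)
            stop = np.minimum(t, 10.0)
            return stop, t < 10.0, x

        flags = 0
        reps = 100
        for s in range(reps):
            stop, event, x = reversing(400, 2000 + s)
            fit = fit_cox_arrays(stop, event, x, names=["grp"])
            if not schoenfeld_diagnostic(fit, "grp").proportional:
                flags += 1
        assert flags >= 0.90 * reps


class TestCompareModels:
    def test_aic_identity_and_ordering(self, sim_bundle):
        cohort, _, fit3 = sim_bundle
        fits = [fit_cox(cohort, DesignSpec.by_id(d)) for d in ("C1", "C2", "C4")]
        tab = cx.compare_models(fits + [fit3])
        assert (tab["aic"].values == np.sort(tab["aic"].values)).all()
        assert tab["selected"].sum() >= 1
        recomputed = 2 * tab["k"] - 2 * tab["log_partial_likelihood"]
        assert np.allclose(recomputed, tab["aic"])

    def test_identical_fits_keep_input_order(self, sim_bundle):
        _, _, fit = sim_bundle
        tab = cx.compare_models([fit, fit])
        assert list(tab["design"]) == ["C3", "C3"]

    def test_different_data_rejected(self, sim_bundle):
        cohort, _, fit = sim_bundle
        other = Cohort(cohort.df.head(400).copy())
        fit_small = fit_cox(other, DesignSpec.C3())
        with pytest.raises(ValueError, match="same data"):
            cx.compare_models([fit, fit_small])

    def test_noise_covariate_usually_raises_aic(self):
        worse = 0
        reps = 100
        for s in range(reps):
            stop, event, x = two_group_exponential(250, 0.1, 2.0, seed=3000 + s)
            rng = np.random.default_rng(9000 + s)
            noise = rng.normal(size=len(stop))
            f1 = fit_cox_arrays(stop, event, x)
            f2 = fit_cox_arrays(stop, event, np.column_stack([x, noise]))
            if f2.aic > f1.aic:
                worse += 1
        assert worse > reps / 2


class TestAdjustedCurves:
    def test_two_identical_strata_coincide(self):
        cfg = replace(SimulationConfig(seed=31), n=300)
        cohort = simulate_cohort(cfg)
        df = pd.concat([cohort.df.assign(grp="a"), cohort.df.assign(grp="b")])
        df["id"] = [f"r{i}" for i in range(len(df))]
        curves = cx.adjusted_survival_curves(Cohort(df.reset_index(drop=True)), "grp")
        assert np.allclose(curves["a"].values, curves["b"].values)

    def test_stage_ordering(self, sim_bundle):
        cohort, _, _ = sim_bundle
        curves = cx.adjusted_survival_curves(cohort, "stage")
        t = curves["I"].index.values
        late = t >= 2.0
        assert np.all(curves["III"].values[late] < curves["I"].values[late])

    def test_eventless_stratum_is_flat_with_warning(self):
        cfg = replace(SimulationConfig(seed=37), n=200)
        cohort = simulate_cohort(cfg)
        df = cohort.df.copy()
        extra = df.head(30).copy()
        extra["id"] = [f"x{i}" for i in range(30)]
        extra["dead"] = False
        extra["grp"] = "quiet"
        df["grp"] = "base"
        full = Cohort(pd.concat([df, extra]).reset_index(drop=True))
        with pytest.warns(UserWarning, match="no events"):
            curves = cx.adjusted_survival_curves(full, "grp")
        assert np.all(curves["quiet"].values == 1.0)


class TestNomogram:
    def make_fit(self, betas: dict):
        terms = list(betas)
        return CoxFit(
            design=DesignSpec.C2(),
            beta=pd.Series(list(betas.values()), index=terms),
            vcov=pd.DataFrame(np.eye(len(terms)) * 0.01, index=terms, columns=terms),
            baseline_times=np.array([1.0]), baseline_cumhaz=np.array([0.1]),
            log_partial_likelihood=0.0, aic=0.0, n_events=50, n=500,
            age_range=(30.0, 80.0),
        )

    def test_single_binary_covariate_spans_0_to_100(self):
        tab = nomogram_points(self.make_fit({"her2_pos": 0.7}))
        pts = dict(zip(tab["level"], tab["points"]))
        assert pts == {"neg": 0.0, "pos": 100.0}

    def test_scale_invariance_under_doubling(self):
        t1 = nomogram_points(self.make_fit({"her2_pos": 0.4, "adherent": -0.8}))
        t2 = nomogram_points(self.make_fit({"her2_pos": 0.8, "adherent": -1.6}))
        pd.testing.assert_series_equal(t1["points"], t2["points"])

    def test_points_ordering_matches_effect_ranges(self, sim_bundle):
        _, _, fit = sim_bundle
        tab = nomogram_points(fit)
        ranges = tab.groupby("variable")["points"].max()
        beta = fit.beta
        expected_order = {
            "stage": abs(beta["stage_III"]),
            "adherence": abs(beta["adherent"]),
            "her2": abs(beta["her2_pos"]),
        }
        got = ranges[list(expected_order)].sort_values(ascending=False).index.tolist()
        want = sorted(expected_order, key=expected_order.get, reverse=True)
        assert got == want


class TestSerialization:
    def test_round_trip_preserves_predictions(self, sim_bundle):
        _, _, fit = sim_bundle
        clone = fit_from_json(fit_to_json(fit))
        grid = np.arange(0, 121) / 12.0
        profile = {"age": 48.0, "stage": "II", "her2": "pos",
                   "adherence": "non_adherent"}
        a = predict_overall_survival(fit, profile, grid)
        b = predict_overall_survival(clone, profile, grid)
        assert np.array_equal(a.values, b.values)
        assert clone.aic == fit.aic
        payload = json.loads(fit_to_json(fit))
        assert payload["design"]["design_id"] == "C3"
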
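"""Barlow expansion, weighted Cox estimation, propensity scores, the
nested covariate models, and the arm-interaction test."""

import numpy as np
import pandas as pd
import pytest

from hlmetsig import CaseCohortDesign, ValidationError, survival
from hlmetsig.lifestyle import compute_hl_score
from hlmetsig.synthetic import (
    SimConfig, draw_case_cohort, generate_cohort, generate_outcomes,
)


def _design(n_cases=2, n_sub=4, overlap=1, f=0.25):
    """Hand-built toy: ids 0,1 are cases (id 1 also in the subcohort),
    ids 1..4 form the subcohort."""
    tab = pd.DataFrame({
        "id": [0, 1, 2, 3, 4],
        "is_case": [True, True, False, False, False],
        "in_subcohort": [False, True, True, True, True],
        "entry_time": 0.0,
        "event_time": [2.0, 3.0, 5.0, 5.0, 4.0],
        "event": [1, 1, 0, 0, 0],
    })
    return CaseCohortDesign(table=tab, sampling_fraction=f, n_full_cohort=16)


class TestBarlowExpansion:
    def test_toy_record_count_by_hand(self):
        # 3 subcohort non-cases -> 3 records; 1 subcohort case -> 2 records;
        # 1 outside case -> 1 record; total 6
        rec = survival.expand_barlow(_design())
        assert len(rec) == 6
        by_id = rec.groupby("id").size()
        assert by_id[1] == 2 and by_id[0] == 1

    def test_subcohort_weight_is_inverse_fraction(self):
        rec = survival.expand_barlow(_design(f=0.25))
        noncase = rec[(rec["event"] == 0) & (rec["id"] >= 2)]
        assert (noncase["weight"] == 4.0).all()
        assert (rec.loc[rec["event"] == 1, "weight"] == 1.0).all()

    def test_case_records_are_short_final_intervals(self):
        rec = survival.expand_barlow(_design())
        ev = rec[rec["event"] == 1]
        assert ((ev["stop"] - ev["start"]) < 1.0).all()
        assert (rec["start"] < rec["stop"]).all()

    def test_case_without_event_time_raises(self):
        d = _design()
        d.table.loc[0, "event_time"] = np.nan
        with pytest.raises(ValidationError):
            survival.expand_barlow(d)


@pytest.fixture(scope="module")
def full_cohort():
    cfg = SimConfig(n_participants=800, n_metabolites=5, n_true_signal=0,
                    logHR_per_unit=-0.6, seed=31)
    cohort, truth = generate_cohort(cfg)
    out = generate_outcomes(cohort, truth, cfg)
    return cohort, truth, out


class TestWeightedCox:
    def test_full_cohort_equivalence_with_plain_cox(self, full_cohort):
        from lifelines import CoxPHFitter

        cohort, truth, out = full_cohort
        design = draw_case_cohort(out, 1.0, seed=1)
        rec = survival.expand_barlow(design)
        sig = pd.Series(truth.true_signature_values, index=cohort.index)
        rec["sig"] = sig.reindex(rec["id"]).to_numpy()
        fit = survival.fit_weighted_cox(rec, ["sig"])
        plain = pd.DataFrame({"time": out["time"], "event": out["event"],
                              "sig": truth.true_signature_values})
        cph = CoxPHFitter().fit(plain, duration_col="time", event_col="event")
        assert fit.term("sig")["logHR"] == pytest.approx(cph.params_["sig"], abs=1e-6)

    def test_weight_rescaling_leaves_loghr_unchanged(self, full_cohort):
        cohort, truth, out = full_cohort
        design = draw_case_cohort(out, 0.3, seed=2)
        rec = survival.expand_barlow(design)
        sig = pd.Series(truth.true_signature_values, index=cohort.index)
        rec["sig"] = sig.reindex(rec["id"]).to_numpy()
        fit1 = survival.fit_weighted_cox(rec, ["sig"])
        rec2 = rec.assign(weight=rec["weight"] * 7.5)
        fit2 = survival.fit_weighted_cox(rec2, ["sig"])
        assert fit1.term("sig")["logHR"] == pytest.approx(
            fit2.term("sig")["logHR"], abs=1e-8)

    def test_estimator_recovers_protective_loghr(self):
        from hlmetsig.experiments import casecohort_estimator_study

        res = casecohort_estimator_study(seed=5, n_sims=40, n=1500)
        assert abs(res["casecohort_loghr_mean_bias"]) < 0.1
        assert res["casecohort_ci_coverage"] >= 0.85

    def test_null_covariate_ci_covers_one(self):
        cover = 0
        n_rep = 40
        for s in range(n_rep):
            cfg = SimConfig(n_participants=1200, n_metabolites=5,
                            n_true_signal=0, logHR_per_unit=0.0, seed=400 + s)
            cohort, truth, = generate_cohort(cfg)
            out = generate_outcomes(cohort, truth, cfg)
            design = draw_case_cohort(out, 0.3, seed=s)
            rec = survival.expand_barlow(design)
            rng = np.random.default_rng(s)
            x = pd.Series(rng.normal(size=len(cohort)), index=cohort.index)
            rec["x"] = x.reindex(rec["id"]).to_numpy()
            fit = survival.fit_weighted_cox(rec, ["x"])
            t = fit.term("x")
            cover += t["ci_low"] <= 1.0 <= t["ci_high"]
        assert cover / n_rep >= 0.85


class TestPropensity:
    def test_probabilities_sum_to_one(self):
        cfg = SimConfig(n_participants=600, n_metabolites=5, n_true_signal=0, seed=41)
        cohort, _ = generate_cohort(cfg)
        ps = survival.estimate_propensity(cohort, ["age", "sex", "energy_kcal"])
        assert ps.shape == (600, 2)
        total = ps.sum(axis=1)
        assert (total <= 1.0 + 1e-9).all()

    def test_null_covariates_give_arm_frequencies(self):
        cfg = SimConfig(n_participants=3000, n_metabolites=5, n_true_signal=0, seed=43)
        cohort, _ = generate_cohort(cfg)
        ps = survival.estimate_propensity(cohort, ["age", "energy_kcal"])
        freqs = cohort["arm"].value_counts(normalize=True)
        for arm in ps.columns:
            observed = freqs[arm.replace("ps_", "")]
            se = np.sqrt(observed * (1 - observed) / len(cohort))
            assert abs(ps[arm].mean() - observed) < 3 * se + 0.01

    def test_known_assignment_model_recovered(self):
        rng = np.random.default_rng(7)
        n = 5000
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        # softmax assignment with known linear scores
        eta = np.column_stack([np.zeros(n), 0.8 * x1, -0.5 * x2])
        p = np.exp(eta) / np.exp(eta).sum(axis=1, keepdims=True)
        u = rng.random(n)
        arm_idx = (u[:, None] > p.cumsum(axis=1)).sum(axis=1)
        cohort = pd.DataFrame({
            "x1": x1, "x2": x2,
            "arm": np.array(["control", "medd_evoo", "medd_nuts"])[arm_idx],
        })
        ps = survival.estimate_propensity(cohort, ["x1", "x2"])
        true_probs = p[:, [1, 2]]
        rmse = np.sqrt(np.mean((ps.to_numpy() - true_probs) ** 2))
        assert rmse < 0.03


@pytest.fixture(scope="module")
def study():
    cfg = SimConfig(n_participants=1200, n_metabolites=5, n_true_signal=0,
                    logHR_per_unit=-0.6, seed=53)
    cohort, truth = generate_cohort(cfg)
    out = generate_outcomes(cohort, truth, cfg)
    design = draw_case_cohort(out, 0.35, seed=53)
    scores = compute_hl_score(cohort)
    # the "signature" is the true standardized HL plus noise
    rng = np.random.default_rng(53)
    sig_cont = pd.Series(
        truth.true_signature_values + rng.normal(scale=0.6, size=len(cohort)),
        index=cohort.index)
    sig_cat = pd.Series(np.where(sig_cont > 0, "high", "low"), index=cohort.index)
    return design, cohort, sig_cont, sig_cat, scores


class TestNestedModels:
    def test_table_shape_covers_models_and_forms(self, study):
        design, cohort, sig_cont, sig_cat, scores = study
        tab, fits = survival.run_models(
            design, cohort, sig_cont, sig_cat,
            scores["hl_total"], scores["hl_category"], outcome="t2d")
        assert len(tab) == 6
        assert set(tab["model"]) == {"1", "2", "3"}
        assert set(tab["form"]) == {"categorical", "continuous"}
        assert (tab["ci_low"] <= tab["HR"]).all() and (tab["HR"] <= tab["ci_high"]).all()

    def test_year1_analysis_drops_early_cases(self, study):
        design, cohort, sig_cont, sig_cat, scores = study
        tab_base, _ = survival.run_models(
            design, cohort, sig_cont, sig_cat,
            scores["hl_total"], scores["hl_category"], outcome="t2d")
        tab_y1, _ = survival.run_models(
            design, cohort, sig_cont, sig_cat,
            scores["hl_total"], scores["hl_category"],
            outcome="t2d", visit="year1")
        early = (design.table["is_case"] & (design.table["event_time"] <= 1.0)).sum()
        assert tab_y1["n_events"].iloc[0] == tab_base["n_events"].iloc[0] - early

    def test_cvd_outcome_adjusts_for_prevalent_diabetes(self, study):
        design, cohort, sig_cont, sig_cat, scores = study
        _, fits = survival.run_models(
            design, cohort, sig_cont, sig_cat,
            scores["hl_total"], scores["hl_category"], outcome="cvd")
        terms = set(fits[("2", "continuous")].summary["term"])
        assert "diabetes_prev" in terms

    def test_missing_covariate_names_model_and_covariate(self, study):
        design, cohort, sig_cont, sig_cat, scores = study
        bad = cohort.drop(columns=["hypertension"])
        with pytest.raises(ValidationError, match="hypertension"):
            survival.run_models(design, bad, sig_cont, sig_cat,
                                scores["hl_total"], scores["hl_category"])

    def test_adjusting_for_true_target_attenuates_signature(self, study):
        """Model 3 conditions on self-reported HL, the very quantity whose
        standardized form drives the hazard, so the signature's log-HR must
        shrink toward 0 relative to model 2."""
        design, cohort, sig_cont, sig_cat, scores = study
        tab, _ = survival.run_models(
            design, cohort, sig_cont, sig_cat,
            scores["hl_total"], scores["hl_category"], outcome="t2d")
        cont = tab[tab["form"] == "continuous"].set_index("model")
        assert abs(np.log(cont.loc["3", "HR"])) < abs(np.log(cont.loc["2", "HR"]))


class TestInteraction:
    def test_null_interaction_p_values_not_extreme(self):
        ps = []
        for s in range(8):
            cfg = SimConfig(n_participants=1500, n_metabolites=5,
                            n_true_signal=0, logHR_per_unit=-0.4, seed=600 + s)
            cohort, truth = generate_cohort(cfg)
            out = generate_outcomes(cohort, truth, cfg)
            design = draw_case_cohort(out, 0.4, seed=s)
            sig_cat = pd.Series(
                np.where(truth.true_signature_values > 0, "high", "low"),
                index=cohort.index)
            it = survival.interaction_test(design, cohort, sig_cat)
            ps.extend(it["p_lrt"].tolist())
        ps = np.asarray(ps)
        # under a common effect, small p-values should be rare
        assert (ps < 0.01).mean() <= 0.2
        assert np.isfinite(ps).all() and (ps <= 1).all()

    def test_arm_specific_effect_is_detected(self):
        detected = 0
        for s in range(5):
            cfg = SimConfig(n_participants=4000, n_metabolites=5,
                            n_true_signal=0, logHR_per_unit=0.0,
                            baseline_hazard=0.03, seed=700 + s)
            cohort, truth = generate_cohort(cfg)
            # hazard depends on the signature only inside the EVOO arm
            s_vals = truth.true_signature_values.copy()
            arm = cohort["arm"].to_numpy()
            rng = np.random.default_rng(700 + s)
            hazard = cfg.baseline_hazard * np.exp(
                np.where((arm == "medd_evoo") & (s_vals > 0), -0.8, 0.0))
            t = rng.exponential(1.0 / hazard)
            out = pd.DataFrame({
                "time": np.minimum(t, cfg.censor_time),
                "event": (t <= cfg.censor_time).astype(int)}, index=cohort.index)
            design = draw_case_cohort(out, 0.4, seed=s)
            sig_cat = pd.Series(np.where(s_vals > 0, "high", "low"),
                                index=cohort.index)
            it = survival.interaction_test(design, cohort, sig_cat)
            p_evoo = float(it.set_index("arm").loc["medd_evoo", "p_lrt"])
            detected += p_evoo < 0.05
        assert detected >= 3

    def test_constant_product_term_raises(self):
        cfg = SimConfig(n_participants=400, n_metabolites=5, n_true_signal=0, seed=71)
        cohort, truth = generate_cohort(cfg)
        out = generate_outcomes(cohort, truth, cfg)
        design = draw_case_cohort(out, 0.5, seed=71)
        all_low = pd.Series("low", index=cohort.index)
        with pytest.raises(ValidationError, match="constant"):
            survival.interaction_test(design, cohort, all_low)
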
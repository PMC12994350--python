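"""Covariate recoding, Kaplan-Meier, log-rank and Cox regression."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter

import stromalyzer as st
from stromalyzer.errors import ParameterError
from stromalyzer.hotspot import STROMA_HIGH, STROMA_LOW
from stromalyzer.survival import MULTIVARIATE_COVARIATES, prognostic_report


class TestRecodeCovariates:
    def test_six_patient_toy_table_matches_hand_recode(self):
        cohort = pd.DataFrame({
            "age": [60, 70, 55, 80, 67, 72],
            "gender": ["female", "male", "male", "female", "male", "female"],
            "pT": [1, 2, 3, 4, 3, 2],
            "pN": [0, 1, 2, 0, 1, 0],
            "grade": ["well", "moderate", "poor", "moderate", "well", "poor"],
            "adjuvant": ["none", "radiotherapy", "chemoradiotherapy",
                         "none", "none", "radiotherapy"],
            "label": [STROMA_LOW, STROMA_HIGH, STROMA_HIGH, STROMA_LOW,
                      STROMA_LOW, STROMA_HIGH],
        })
        mm = st.recode_covariates(cohort, tsr_label_column="label")
        assert mm["male"].tolist() == [0, 1, 1, 0, 1, 0]
        assert mm["pt34"].tolist() == [0, 0, 1, 1, 1, 0]      # pT1-2 vs pT3-4
        assert mm["ln_metastases"].tolist() == [0, 1, 1, 0, 1, 0]
        assert mm["grade_poor"].tolist() == [0, 0, 1, 0, 0, 1]
        assert mm["adjuvant_any"].tolist() == [0, 1, 1, 0, 0, 1]
        assert mm["stroma_high"].tolist() == [0, 1, 1, 0, 0, 1]
        assert mm["age"].tolist() == cohort["age"].astype(float).tolist()

    def test_invalid_category_names_offending_rows(self):
        cohort = pd.DataFrame({
            "age": [60], "gender": ["male"], "pT": [9], "pN": [0],
            "grade": ["moderate"], "adjuvant": ["none"]})
        with pytest.raises(ParameterError, match="pT"):
            st.recode_covariates(cohort)

    def test_missing_column_rejected(self):
        with pytest.raises(ParameterError, match="grade"):
            st.recode_covariates(pd.DataFrame({"age": [1]}))


class TestKMLogrank:
    def _frame(self, times_a, events_a, times_b, events_b):
        return pd.DataFrame({
            "grp": ["a"] * len(times_a) + ["b"] * len(times_b),
            "dss_years": list(times_a) + list(times_b),
            "dss_event": list(events_a) + list(events_b)})

    def test_no_events_reports_p_one_with_warning(self):
        df = self._frame([1, 2, 3], [0, 0, 0], [1, 2, 3], [0, 0, 0])
        with pytest.warns(UserWarning, match="no events"):
            res = st.km_logrank(df, "grp", "dss")
        assert res.logrank_p == 1.0
        for f in res.fitters.values():
            assert (f.survival_function_.to_numpy() == 1.0).all()

    def test_identical_groups_are_indistinguishable(self):
        df = self._frame([1, 2, 3, 4], [1, 0, 1, 0], [1, 2, 3, 4], [1, 0, 1, 0])
        res = st.km_logrank(df, "grp", "dss")
        assert res.logrank_p == pytest.approx(1.0, abs=1e-9)

    def test_single_group_rejected(self):
        df = self._frame([1, 2], [1, 1], [], [])
        with pytest.raises(ParameterError):
            st.km_logrank(df, "grp", "dss")

    def test_power_against_generated_hazard_ratio(self):
        hits = 0
        for seed in range(20):
            p = st.SyntheticCohortParams(n_patients=500, hr_stroma_high=2.5,
                                         seed=seed)
            df = st.simulate_cohort(p)
            res = st.km_logrank(df, "true_label", "dss")
            hits += res.logrank_p < 0.01
        assert hits >= 18  # >= 90% power at this effect size

    def test_km_equals_empirical_survivor_without_censoring(self, rng):
        times = rng.exponential(5.0, 80)
        kmf = KaplanMeierFitter().fit(times, event_observed=np.ones(80))
        for t in [0.5, 2.0, 5.0, 9.0]:
            assert float(kmf.predict(t)) == pytest.approx(
                (times > t).mean(), abs=1e-12)


class TestFiveYearRate:
    def test_no_events_long_followup_is_hundred(self):
        kmf = KaplanMeierFitter().fit([6, 7, 8], event_observed=[0, 0, 0])
        assert st.five_year_rate(kmf) == 100.0

    def test_everyone_dies_before_horizon_is_zero(self):
        kmf = KaplanMeierFitter().fit([1, 2, 3, 4], event_observed=[1, 1, 1, 1])
        assert st.five_year_rate(kmf) == 0.0

    def test_hand_computed_product_limit_value(self):
        # deaths at 1,2,3 among 10; censored at 1.5 and 2.5:
        # S(5) = (9/10)(7/8)(5/6) = 0.65625
        times = [1, 1.5, 2, 2.5, 3, 10, 10, 10, 10, 10]
        events = [1, 0, 1, 0, 1, 0, 0, 0, 0, 0]
        kmf = KaplanMeierFitter().fit(times, event_observed=events)
        assert st.five_year_rate(kmf) == pytest.approx(65.625, abs=1e-9)

    def test_short_followup_warns(self):
        kmf = KaplanMeierFitter().fit([1, 2, 3], event_observed=[1, 0, 0])
        with pytest.warns(UserWarning, match="follow-up ends"):
            st.five_year_rate(kmf)


class TestCoxFit:
    def _sim_matrix(self, seed, n=500, hr=2.5):
        p = st.SyntheticCohortParams(n_patients=n, hr_stroma_high=hr,
                                     seed=seed)
        df = st.simulate_cohort(p)
        return st.recode_covariates(df, tsr_label_column="true_label")

    def test_null_effect_recovered(self):
        hrs = [st.cox_fit(self._sim_matrix(s, n=1000, hr=1.0), "dss",
                          covariates=["stroma_high"]).hr("stroma_high")
               for s in range(10)]
        assert 0.85 <= float(np.mean(hrs)) <= 1.18

    def test_direction_agrees_with_logrank(self):
        p = st.SyntheticCohortParams(n_patients=500, hr_stroma_high=2.5, seed=0)
        df = st.simulate_cohort(p)
        mm = st.recode_covariates(df, tsr_label_column="true_label")
        cox = st.cox_fit(mm, "dss", covariates=["stroma_high"])
        lr = st.km_logrank(df, "true_label", "dss")
        assert cox.hr("stroma_high") > 1
        assert abs(float(cox.table.loc["stroma_high", "p"]) - lr.logrank_p) <= 0.01

    def test_ties_methods_agree_closely_on_continuous_times(self):
        mm = self._sim_matrix(3)
        hr_e = st.cox_fit(mm, "dss", ["stroma_high"], ties="efron")
        hr_b = st.cox_fit(mm, "dss", ["stroma_high"], ties="breslow")
        assert hr_e.hr("stroma_high") == pytest.approx(
            hr_b.hr("stroma_high"), rel=0.05)

    def test_constant_covariate_is_a_named_error(self):
        mm = self._sim_matrix(1)
        mm["flat"] = 1.0
        with pytest.raises(ParameterError, match="flat"):
            st.cox_fit(mm, "dss", covariates=["flat"])

    def test_no_events_rejected(self):
        mm = self._sim_matrix(1)
        mm["dss_event"] = 0
        with pytest.raises(ParameterError, match="no events"):
            st.cox_fit(mm, "dss", covariates=["stroma_high"])

    def test_independent_noise_covariate_ci_covers_one(self):
        covered = 0
        for seed in range(20):
            mm = self._sim_matrix(seed)
            rng = np.random.default_rng(seed + 1000)
            mm["noise"] = rng.normal(size=len(mm))
            res = st.cox_fit(mm, "dss", covariates=["stroma_high", "noise"])
            lo, hi = res.table.loc["noise", ["ci_low", "ci_high"]]
            covered += lo <= 1.0 <= hi
        assert covered >= 17  # ~95% nominal coverage


def test_full_harness_emits_every_covariate_row():
    """The multivariate model carries the complete grouped-covariate set."""
    df = st.simulate_cohort(st.SyntheticCohortParams(seed=5))
    rep = prognostic_report(df, "auto_label_median", "dss")
    rows = set(rep["multivariate"].table.index)
    assert rows == set(MULTIVARIATE_COVARIATES) | {"stroma_high"}
    assert set(rep["five_year_rates"]) == {STROMA_LOW, STROMA_HIGH}
    uni = rep["univariate"].table
    assert (uni["ci_low"] <= uni["HR"]).all() and (uni["HR"] <= uni["ci_high"]).all()
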
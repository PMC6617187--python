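"""Risk-model fitting, predictor transforms, and prediction."""

import math

import numpy as np
import pytest

from pcatriage.risk import (
    BASIC_PREDICTORS,
    PredictorUnavailableError,
    RiskModel,
    SeparationError,
    fit_cspca_model,
    predict_cohort,
    predict_cspca_risk,
    transform_predictors,
)
from pcatriage.synthetic import CohortConfig, generate_biopsy_cohort
from pcatriage.types import BiopsyRecord, PatientProfile


def _model(predictors, coefs=None, intercept=0.0, centering=None):
    coefs = coefs or {p: 0.0 for p in predictors}
    return RiskModel(
        predictor_set=tuple(predictors),
        coefficients=coefs,
        intercept=intercept,
        centering=centering or {},
    )


class TestTransformPredictors:
    def test_value_at_centering_reference_maps_to_zero(self):
        model = _model(["psa"], centering={"psa": 2.0})
        profile = PatientProfile(age=65, psa=4.0, free_psa_pct=0.2)
        assert transform_predictors(profile, model)[0] == pytest.approx(0.0)

    def test_empty_centering_gives_raw_log2(self):
        model = _model(["psa", "free_psa_pct"])
        profile = PatientProfile(age=65, psa=8.0, free_psa_pct=0.25)
        x = transform_predictors(profile, model)
        assert x[0] == pytest.approx(3.0)
        assert x[1] == pytest.approx(math.log2(0.25))

    def test_cspca_median_psa_hand_value(self):
        # log2(7.8) - 2.0, evaluated by hand
        model = _model(["psa"], centering={"psa": 2.0})
        profile = PatientProfile(age=68, psa=7.8, free_psa_pct=0.12)
        assert transform_predictors(profile, model)[0] == pytest.approx(0.9635, abs=1e-4)

    def test_binary_and_raw_encoding(self):
        model = _model(["age", "dre_abnormal"])
        profile = PatientProfile(age=70, psa=5.0, free_psa_pct=0.2, dre_abnormal=True)
        assert list(transform_predictors(profile, model)) == [70.0, 1.0]

    def test_missing_predictor_is_named(self):
        model = _model(["dre_abnormal"])
        profile = PatientProfile(age=65, psa=4.0, free_psa_pct=0.2)
        with pytest.raises(PredictorUnavailableError, match="dre_abnormal"):
            transform_predictors(profile, model)


class TestFitCspcaModel:
    def test_null_signal_gives_zero_slopes_and_prevalence_intercept(self, rng):
        # outcome independent of predictors
        records = []
        for i in range(2000):
            profile = PatientProfile(
                age=int(rng.integers(55, 75)),
                psa=float(rng.lognormal(1.4, 0.5)),
                free_psa_pct=float(min(rng.lognormal(-1.6, 0.4), 1.0)),
            )
            outcome = "cspca" if rng.random() < 0.2 else "no_pca"
            records.append(BiopsyRecord(profile=profile, outcome=outcome))
        model = fit_cspca_model(records, BASIC_PREDICTORS)
        prev = np.mean([r.is_cspca for r in records])
        for beta in model.coefficients.values():
            assert abs(beta) < 0.5
        # intercept at centered covariates approximates logit(prevalence);
        # age is uncentered so compare at the cohort mean age
        mean_age = np.mean([r.profile.age for r in records])
        eta = model.intercept + model.coefficients["age"] * mean_age
        assert eta == pytest.approx(math.log(prev / (1 - prev)), abs=0.25)

    def test_parameter_recovery_from_known_coefficients(self, rng):
        # generate outcomes from a known logistic model on log2 covariates
        n = 3616
        beta = {"psa": 1.0, "age": 0.05, "free_psa_pct": -1.5}
        intercept = -6.0
        records = []
        for i in range(n):
            age = int(rng.integers(55, 76))
            psa = float(rng.lognormal(1.5, 0.6))
            fpsa = float(min(rng.lognormal(-1.7, 0.45), 1.0))
            eta = (intercept + beta["psa"] * math.log2(psa) + beta["age"] * age
                   + beta["free_psa_pct"] * math.log2(fpsa))
            p = 1 / (1 + math.exp(-eta))
            outcome = "cspca" if rng.random() < p else "no_pca"
            records.append(BiopsyRecord(
                profile=PatientProfile(age=age, psa=psa, free_psa_pct=fpsa),
                outcome=outcome))
        model = fit_cspca_model(records, BASIC_PREDICTORS)
        # recovered slopes within 3 SE of truth (centering shifts only
        # the intercept, not the slopes)
        import statsmodels.api as sm
        X = np.column_stack([
            np.ones(n),
            [math.log2(r.profile.psa) for r in records],
            [r.profile.age for r in records],
            [math.log2(r.profile.free_psa_pct) for r in records],
        ])
        y = np.array([1.0 if r.is_cspca else 0.0 for r in records])
        se = sm.Logit(y, X).fit(disp=0).bse
        for j, name in enumerate(("psa", "age", "free_psa_pct"), start=1):
            assert abs(model.coefficients[name] - beta[name]) < 3 * se[j]

    def test_default_cohort_mean_risk_is_nine_percent(self, biopsy_cohort):
        model = fit_cspca_model(biopsy_cohort, BASIC_PREDICTORS)
        preds = predict_cohort(model, biopsy_cohort)
        assert preds.mean() == pytest.approx(0.09, abs=0.01)

    def test_mean_predicted_equals_prevalence(self, biopsy_cohort):
        # logistic score equation: exact up to optimizer tolerance
        model = fit_cspca_model(biopsy_cohort, BASIC_PREDICTORS)
        preds = predict_cohort(model, biopsy_cohort)
        prev = np.mean([r.is_cspca for r in biopsy_cohort])
        assert preds.mean() == pytest.approx(prev, abs=1e-6)

    def test_centering_constants_are_cohort_means(self, biopsy_cohort):
        model = fit_cspca_model(biopsy_cohort, BASIC_PREDICTORS)
        log2_psa = [math.log2(r.profile.psa) for r in biopsy_cohort]
        assert model.centering["psa"] == pytest.approx(np.mean(log2_psa))

    def test_refit_is_deterministic(self, small_biopsy_cohort):
        m1 = fit_cspca_model(small_biopsy_cohort, BASIC_PREDICTORS)
        m2 = fit_cspca_model(small_biopsy_cohort, BASIC_PREDICTORS)
        assert m1.coefficients == m2.coefficients
        assert m1.intercept == m2.intercept

    def test_perfect_separation_names_predictor(self):
        records = [
            BiopsyRecord(
                profile=PatientProfile(age=60 + i, psa=1.0 + i, free_psa_pct=0.2),
                outcome="cspca" if i >= 5 else "no_pca",
            )
            for i in range(10)
        ]
        with pytest.raises(SeparationError, match="psa"):
            fit_cspca_model(records, ["psa"])

    def test_single_class_cohort_rejected(self):
        records = [
            BiopsyRecord(
                profile=PatientProfile(age=60, psa=4.0 + i, free_psa_pct=0.2),
                outcome="no_pca",
            )
            for i in range(20)
        ]
        with pytest.raises(ValueError):
            fit_cspca_model(records, ["psa"])

    def test_indolent_counts_as_negative(self, small_biopsy_cohort):
        # collapsing indolent into the negative class before fitting
        # changes nothing: the fit already does exactly that
        collapsed = [
            BiopsyRecord(profile=r.profile,
                         outcome="cspca" if r.is_cspca else "no_pca")
            for r in small_biopsy_cohort
        ]
        m1 = fit_cspca_model(small_biopsy_cohort, BASIC_PREDICTORS)
        m2 = fit_cspca_model(collapsed, BASIC_PREDICTORS)
        assert m1.coefficients == m2.coefficients


class TestPredict:
    def test_zero_model_gives_half(self):
        model = _model(list(BASIC_PREDICTORS))
        profile = PatientProfile(age=65, psa=4.0, free_psa_pct=0.17)
        assert predict_cspca_risk(model, profile) == pytest.approx(0.5)

    def test_prevalence_only_model(self):
        model = _model(list(BASIC_PREDICTORS),
                       intercept=math.log(0.09 / 0.91))
        profile = PatientProfile(age=70, psa=9.0, free_psa_pct=0.1)
        assert predict_cspca_risk(model, profile) == pytest.approx(0.09)

    def test_fixed_coefficients_match_hand_evaluation(self):
        model = RiskModel(
            predictor_set=("psa", "age", "free_psa_pct"),
            coefficients={"psa": 1.1, "age": 0.04, "free_psa_pct": -1.8},
            intercept=-5.0,
            centering={"psa": 2.0, "free_psa_pct": -2.3},
        )
        profile = PatientProfile(age=65, psa=4.0, free_psa_pct=0.17)
        eta = (-5.0
               + 1.1 * (math.log2(4.0) - 2.0)
               + 0.04 * 65
               - 1.8 * (math.log2(0.17) + 2.3))
        expected = 1 / (1 + math.exp(-eta))
        assert predict_cspca_risk(model, profile) == pytest.approx(expected, rel=1e-12)

    def test_risk_strictly_increasing_in_psa(self, biopsy_cohort):
        model = fit_cspca_model(biopsy_cohort, BASIC_PREDICTORS)
        assert model.coefficients["psa"] > 0
        risks = [
            predict_cspca_risk(
                model, PatientProfile(age=65, psa=psa, free_psa_pct=0.17))
            for psa in (1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
        ]
        assert all(a < b for a, b in zip(risks, risks[1:]))

    def test_probabilities_in_open_unit_interval(self, biopsy_cohort):
        model = fit_cspca_model(biopsy_cohort, BASIC_PREDICTORS)
        preds = predict_cohort(model, biopsy_cohort)
        assert np.all((preds > 0) & (preds < 1))


class TestRiskModelSerialization:
    def test_json_round_trip(self, small_biopsy_cohort, tmp_path):
        model = fit_cspca_model(small_biopsy_cohort, BASIC_PREDICTORS)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = RiskModel.load(path)
        assert loaded == model

    def test_centering_restricted_to_log_predictors(self):
        with pytest.raises(ValueError):
            RiskModel(predictor_set=("age",), coefficients={"age": 0.1},
                      intercept=0.0, centering={"age": 65.0})
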
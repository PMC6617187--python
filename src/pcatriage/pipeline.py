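"""End-to-end triage for one patient: risk, life expectancies, benefit, advice."""

from __future__ import annotations

import json
from importlib import resources
from typing import Optional

from .decision import DecisionThresholds, decide_referral, load_default_thresholds, render_report
from .lifeexp import LifeExpectancyModel
from .risk import RiskModel, predict_cspca_risk
from .treatment import TreatmentEffect, apply_hazard_ratio, le_gain, load_trial_effects
from .types import PatientProfile
from .weibull import weibull_mean

__all__ = ["triage_patient", "load_reference_risk_model", "load_reference_le_model"]


def load_reference_risk_model() -> RiskModel:
    """The shipped risk model, fitted on the seeded default synthetic cohort."""
    with resources.files("pcatriage.data").joinpath("reference_risk_model.json").open() as fh:
        return RiskModel.from_dict(json.load(fh))


def load_reference_le_model() -> LifeExpectancyModel:
    """The shipped life-expectancy model (synthetic-cohort fit + published anchors)."""
    with resources.files("pcatriage.data").joinpath("reference_le_model.json").open() as fh:
        return LifeExpectancyModel.from_dict(json.load(fh))


def triage_patient(
    profile: PatientProfile,
    risk_model: Optional[RiskModel] = None,
    le_model: Optional[LifeExpectancyModel] = None,
    effect: Optional[TreatmentEffect] = None,
    thresholds: Optional[DecisionThresholds] = None,
) -> dict:
    """Full per-patient report.

    Computes the csPCa risk from the logistic model, the Weibull life
    expectancies with untreated csPCa and without csPCa, the treatment
    gain from the trial hazard ratio, and the referral advice; returns
    the rendered report dict (see :func:`pcatriage.decision.render_report`).
    Defaults to the shipped reference models and the PIVOT hazard ratio.
    """
    risk_model = risk_model or load_reference_risk_model()
    le_model = le_model or load_reference_le_model()
    effect = effect or load_trial_effects()["pivot"]
    thresholds = thresholds or load_default_thresholds()

    risk = predict_cspca_risk(risk_model, profile)
    w_untreated = le_model.curve_untreated_cspca(profile.age, profile.charlson)
    w_without = le_model.curve_without_cspca(profile.age, profile.charlson)
    le_untreated = weibull_mean(w_untreated)
    le_without = weibull_mean(w_without)
    gain = le_gain(w_untreated, effect)
    le_treated = le_untreated + gain

    advice = decide_referral(risk, le_without, le_untreated, gain, thresholds)
    report = render_report(profile, risk, le_without, le_untreated, le_treated,
                           gain, advice)
    report["inputs"] = {
        "hr_source": effect.source,
        "hr": effect.hr,
        "thresholds": thresholds.to_dict(),
    }
    return report
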
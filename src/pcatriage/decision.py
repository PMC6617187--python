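"""Referral advice from risk, life expectancy, and treatment benefit.

The three quantities are held against consensus threshold bands
(risk of csPCa on biopsy 5-10%, life expectancy 10-15 years, treatment
benefit 1-2 years).  Risk below its lower limit means no referral.
A large treatment benefit (above its band) with a non-negligible risk
forces referral even when life expectancy is short — the override rule.
When all three quantities clear their lower limits and at least one
reaches the middle of its band, the advice is to refer; in the
remaining grey zone the decision is shared with the patient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Tuple

from .types import PatientProfile
from .treatment import gain_in_months

__all__ = [
    "DecisionThresholds",
    "ReferralAdvice",
    "classify_criterion",
    "decide_referral",
    "render_report",
    "load_default_thresholds",
]

ADVICE_ORDER = ("no_referral", "shared_decision", "refer")


@dataclass(frozen=True)
class DecisionThresholds:
    """Consensus bands for the three referral criteria."""

    risk_band: Tuple[float, float] = (0.05, 0.10)
    le_band: Tuple[float, float] = (10.0, 15.0)  # years
    gain_band: Tuple[float, float] = (1.0, 2.0)  # years

    def __post_init__(self):
        for name, (lo, hi) in (("risk", self.risk_band),
                               ("le", self.le_band),
                               ("gain", self.gain_band)):
            if lo > hi:
                raise ValueError(f"{name} band must satisfy low <= high")

    def to_dict(self) -> dict:
        return {"risk_band": list(self.risk_band),
                "le_band": list(self.le_band),
                "gain_band": list(self.gain_band)}

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionThresholds":
        return cls(risk_band=tuple(d["risk_band"]),
                   le_band=tuple(d["le_band"]),
                   gain_band=tuple(d["gain_band"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "DecisionThresholds":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def load_default_thresholds() -> DecisionThresholds:
    with resources.files("pcatriage.data").joinpath("thresholds.json").open() as fh:
        return DecisionThresholds.from_dict(json.load(fh))


@dataclass(frozen=True)
class ReferralAdvice:
    """The overall recommendation plus its per-criterion breakdown."""

    overall: str  # 'no_referral' | 'shared_decision' | 'refer'
    per_criterion: Dict[str, str]  # criterion -> 'below' | 'within' | 'above'
    override_applied: bool
    narrative: str


def classify_criterion(value: float, band: Tuple[float, float]) -> str:
    """'below' if value < low, 'above' if value > high, else 'within'."""
    lo, hi = band
    if value < lo:
        return "below"
    if value > hi:
        return "above"
    return "within"


def _at_or_past_midpoint(value: float, band: Tuple[float, float]) -> bool:
    lo, hi = band
    return value >= (lo + hi) / 2.0


def decide_referral(
    risk: float,
    le_without_cspca: float,
    le_untreated_cspca: float,
    gain: float,
    thresholds: DecisionThresholds | None = None,
) -> ReferralAdvice:
    """Three-band referral recommendation.

    The life-expectancy criterion is held against the LE *without*
    csPCa (the man's competing-risk horizon); the untreated-csPCa LE is
    reported but not thresholded.

    Rules, in order:

    1. risk below its lower limit -> no referral;
    2. gain above its band (with risk at least at its lower limit)
       -> refer; the override flag is set when life expectancy is below
       its band, the case the rule exists for;
    3. gain and life expectancy both below their bands -> no referral
       (high risk alone does not justify biopsy when nothing can be
       gained);
    4. risk, LE and gain all at/above their lower limits, with at
       least one criterion at or past the middle of its band -> refer;
    5. otherwise -> shared decision.

    The advice is monotone: raising risk or gain never moves the
    recommendation away from referral.
    """
    if not (0 < risk < 1):
        raise ValueError("risk must be a probability in (0, 1)")
    th = thresholds or DecisionThresholds()
    per = {
        "risk": classify_criterion(risk, th.risk_band),
        "life_expectancy": classify_criterion(le_without_cspca, th.le_band),
        "treatment_gain": classify_criterion(gain, th.gain_band),
    }

    override = False
    if per["risk"] == "below":
        overall = "no_referral"
        why = "risk of csPCa is below the referral threshold"
    elif per["treatment_gain"] == "above":
        overall = "refer"
        override = per["life_expectancy"] == "below"
        why = ("expected treatment benefit is large"
               + ("; it outweighs the limited life expectancy" if override else ""))
    elif per["treatment_gain"] == "below" and per["life_expectancy"] == "below":
        overall = "no_referral"
        why = ("life expectancy and expected treatment benefit are both too "
               "low for referral to help, despite the csPCa risk")
    elif (per["life_expectancy"] != "below"
          and per["treatment_gain"] != "below"
          and (_at_or_past_midpoint(risk, th.risk_band)
               or _at_or_past_midpoint(le_without_cspca, th.le_band)
               or _at_or_past_midpoint(gain, th.gain_band))):
        overall = "refer"
        why = "risk, life expectancy and treatment benefit all support referral"
    else:
        overall = "shared_decision"
        why = ("the criteria are in the grey zone; the decision should follow "
               "the patient's preferences")
    return ReferralAdvice(
        overall=overall, per_criterion=per, override_applied=override, narrative=why
    )


_ADVICE_TEXT = {
    "no_referral": "No referral needed",
    "shared_decision": "Discuss: patient preference decides",
    "refer": "Refer to a urologist",
}


def render_report(
    profile: PatientProfile,
    risk: float,
    le_without: float,
    le_untreated: float,
    le_treated: float,
    gain: float,
    advice: ReferralAdvice,
) -> dict:
    """Patient-facing report: numbers as displayed plus machine fields.

    Display rounding: risk to whole percent, life expectancies to one
    decimal year, gain to whole months.  The ``values`` block keeps the
    unrounded numbers so that reports round-trip.
    """
    gain_months = gain_in_months(gain)
    if gain_months > 0:
        gain_line = f"Expected gain from treatment: {gain_months} months"
    else:
        gain_line = "No expected survival benefit from treatment"
    lines = [
        f"Age {profile.age}, PSA {profile.psa:g} ng/mL, "
        f"free PSA {profile.free_psa_pct * 100:.0f}%, Charlson {profile.charlson}",
        f"Risk of csPCa on a current biopsy: {round(risk * 100):.0f}%",
        f"Life expectancy without csPCa: {le_without:.1f} years",
        f"Life expectancy with untreated csPCa: {le_untreated:.1f} years",
        f"Life expectancy with treated csPCa: {le_treated:.1f} years",
        gain_line,
        f"Advice: {_ADVICE_TEXT[advice.overall]}",
    ]
    return {
        "display": {
            "risk_pct": int(round(risk * 100)),
            "le_without_cspca_years": round(le_without, 1),
            "le_untreated_cspca_years": round(le_untreated, 1),
            "le_treated_cspca_years": round(le_treated, 1),
            "gain_months": gain_months,
            "advice": _ADVICE_TEXT[advice.overall],
        },
        "values": {
            "risk": risk,
            "le_without_cspca_years": le_without,
            "le_untreated_cspca_years": le_untreated,
            "le_treated_cspca_years": le_treated,
            "gain_years": gain,
        },
        "advice": {
            "overall": advice.overall,
            "per_criterion": dict(advice.per_criterion),
            "override_applied": advice.override_applied,
            "narrative": advice.narrative,
        },
        "text": "\n".join(lines),
    }
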
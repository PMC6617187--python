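"""Absolute treatment benefit from a trial hazard ratio.

A trial's all-cause-mortality hazard ratio acts on the untreated-csPCa
Weibull curve by proportional hazards: S_treated(t) = S(t)^hr, i.e.
same shape, scale multiplied by hr^(-1/shape).  The absolute benefit is
the difference in mean survival, which has the closed form

    gain = LE_untreated * (hr^(-1/shape) - 1).

Three observation-vs-treatment randomized trials supply hazard ratios:
PIVOT (the primary source, HR 0.84), SPCG-4 (0.74) and ProtecT (0.93);
the latter two drive the sensitivity analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Sequence

from .weibull import WeibullSurvival, weibull_mean

__all__ = [
    "TreatmentEffect",
    "apply_hazard_ratio",
    "le_gain",
    "gain_in_months",
    "sensitivity_across_trials",
    "load_trial_effects",
]


@dataclass(frozen=True)
class TreatmentEffect:
    """A trial's all-cause-mortality hazard ratio with 95% CI."""

    source: str
    hr: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not (self.hr > 0 and self.ci_low > 0 and self.ci_high > 0):
            raise ValueError("hazard ratio and CI bounds must be positive")
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def load_trial_effects() -> Dict[str, TreatmentEffect]:
    """The shipped trial hazard ratios, keyed by lowercase source name."""
    with resources.files("pcatriage.data").joinpath("trial_effects.json").open() as fh:
        raw = json.load(fh)
    return {
        e["source"].lower(): TreatmentEffect(
            source=e["source"], hr=e["hr"], ci_low=e["ci_low"], ci_high=e["ci_high"]
        )
        for e in raw["effects"]
    }


def apply_hazard_ratio(w: WeibullSurvival, hr: float) -> WeibullSurvival:
    """Proportional hazards on a Weibull: same shape, scale * hr^(-1/shape)."""
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    return WeibullSurvival(shape=w.shape, scale=w.scale * hr ** (-1.0 / w.shape))


def le_gain(w: WeibullSurvival, effect: TreatmentEffect | float) -> float:
    """Gain in mean survival (years) from treatment at the trial's HR.

    Equals weibull_mean(apply_hazard_ratio(w, hr)) - weibull_mean(w)
    = LE * (hr^(-1/shape) - 1); positive whenever hr < 1.
    """
    hr = effect.hr if isinstance(effect, TreatmentEffect) else float(effect)
    return weibull_mean(apply_hazard_ratio(w, hr)) - weibull_mean(w)


def gain_in_months(gain_years: float) -> int:
    """Whole months, rounded half away from zero (display convention)."""
    months = gain_years * 12.0
    import math

    return int(math.floor(abs(months) + 0.5)) * (1 if months >= 0 else -1)


def sensitivity_across_trials(
    w: WeibullSurvival, effects: Sequence[TreatmentEffect]
) -> List[dict]:
    """Treated LE and gain per trial; lower HR means larger gain.

    Each row also carries the gain at the CI bounds of the hazard
    ratio (a monotone transform, so the bounds bracket the point gain).
    """
    if not effects:
        raise ValueError("need at least one treatment effect")
    le0 = weibull_mean(w)
    rows = []
    for e in effects:
        gain = le_gain(w, e)
        rows.append({
            "source": e.source,
            "hr": e.hr,
            "le_untreated": le0,
            "le_treated": le0 + gain,
            "gain_years": gain,
            "gain_months": gain_in_months(gain),
            # hr is protective when < 1, so the low CI bound gives the
            # larger gain
            "gain_ci_high": le_gain(w, e.ci_low),
            "gain_ci_low": le_gain(w, e.ci_high),
        })
    return rows
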
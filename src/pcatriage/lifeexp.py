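"""Life-expectancy estimation from censored cohorts and life tables.

Two curves are needed for triage.  The curve *without* clinically
significant cancer comes from a censored Weibull accelerated-failure
regression on screening-cohort follow-up (log scale linear in age and
Charlson stratum, common shape), corrected toward the general
population by a Poisson-regression relative-mortality ratio against a
national life table (the healthy-screenee correction).  The curve
*with* untreated disease comes from registry survival curves fitted per
age-band x Charlson stratum (see :mod:`pcatriage.weibull`).
"""

from __future__ import annotations

import json
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import SurvivalRecord, CHARLSON_LEVELS
from .weibull import WeibullSurvival, apply_relative_mortality, weibull_from_mean

__all__ = [
    "LifeTable",
    "WeibullRegression",
    "LifeExpectancyModel",
    "fit_weibull_regression",
    "fit_relative_mortality",
    "impute_charlson",
    "AGE_BAND_EDGES",
    "age_band_of",
]

AGE_BAND_EDGES = ((55, 59), (60, 64), (65, 69), (70, 74), (75, 200))
_AGE_BAND_NAMES = ("55-59", "60-64", "65-69", "70-74", "75+")


def age_band_of(age: float) -> str:
    """Map an age in years to its five-year band ('55-59' ... '75+')."""
    for (lo, hi), name in zip(AGE_BAND_EDGES, _AGE_BAND_NAMES):
        if lo <= age <= hi:
            return name
    if age < 55:
        return "55-59"  # younger men use the youngest published stratum
    raise ValueError(f"age {age} outside supported range")


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause mortality hazards by single year of age."""

    ages: Tuple[int, ...]
    hazards: Tuple[float, ...]

    def __post_init__(self):
        if len(self.ages) != len(self.hazards) or not self.ages:
            raise ValueError("ages and hazards must be same nonzero length")
        if any(h <= 0 for h in self.hazards):
            raise ValueError("hazards must be positive")
        if list(self.ages) != list(range(self.ages[0], self.ages[0] + len(self.ages))):
            raise ValueError("ages must be contiguous integers")

    def hazard_at(self, age: float) -> float:
        """Annual hazard for the year of age containing ``age``."""
        idx = int(math.floor(age)) - self.ages[0]
        if not (0 <= idx < len(self.hazards)):
            raise ValueError(f"age {age} outside life-table range "
                             f"[{self.ages[0]}, {self.ages[-1]}]")
        return self.hazards[idx]

    def expected_deaths(self, age_at_entry: float, follow_up_years: float) -> float:
        """Cumulative expected hazard over a follow-up window.

        Age advances annually from entry; the final fractional year is
        pro-rated.  This is the person-year contribution to the
        expected-death offset of the relative-mortality regression.
        """
        total = 0.0
        remaining = follow_up_years
        age = age_at_entry
        while remaining > 0:
            step = min(1.0, remaining)
            total += self.hazard_at(age) * step
            remaining -= step
            age += 1.0
        return total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "hazard": self.hazards})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        df = df.sort_values("age")
        return cls(ages=tuple(int(a) for a in df["age"]),
                   hazards=tuple(float(h) for h in df["hazard"]))


class NonIdentifiableError(RuntimeError):
    """The survival model cannot be fit (e.g. no observed deaths)."""


def _records_frame(cohort: Sequence[SurvivalRecord]) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(cohort):
        if r.charlson is None:
            raise ValueError(
                f"record {i} has missing Charlson; impute before fitting"
            )
        rows.append({
            "age": float(r.age_at_entry),
            "charlson_1": 1.0 if r.charlson == "1" else 0.0,
            "charlson_2plus": 1.0 if r.charlson == "2+" else 0.0,
            "duration_years": max(r.follow_up_months / 12.0, 1e-6),
            "event": 1 if r.dead else 0,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class WeibullRegression:
    """Weibull AFT fit: common shape, log scale linear in age and Charlson.

    scale(age, charlson) = exp(intercept + coef_age*(age - age_ref)
                               + coef_charlson_1 + coef_charlson_2plus)
    """

    shape: float
    intercept: float
    coef_age: float
    coef_charlson_1: float
    coef_charlson_2plus: float
    age_ref: float = 65.0
    standard_errors: Dict[str, float] = field(default_factory=dict)
    n: int = 0
    n_events: int = 0

    def curve_for(self, age: float, charlson: str) -> WeibullSurvival:
        eta = self.intercept + self.coef_age * (age - self.age_ref)
        if charlson == "1":
            eta += self.coef_charlson_1
        elif charlson == "2+":
            eta += self.coef_charlson_2plus
        elif charlson != "0":
            raise ValueError(f"unknown Charlson stratum {charlson!r}")
        return WeibullSurvival(shape=self.shape, scale=math.exp(eta))

    def to_dict(self) -> dict:
        return {
            "shape": self.shape,
            "intercept": self.intercept,
            "coef_age": self.coef_age,
            "coef_charlson_1": self.coef_charlson_1,
            "coef_charlson_2plus": self.coef_charlson_2plus,
            "age_ref": self.age_ref,
            "standard_errors": dict(self.standard_errors),
            "n": self.n,
            "n_events": self.n_events,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WeibullRegression":
        return cls(
            shape=float(d["shape"]),
            intercept=float(d["intercept"]),
            coef_age=float(d["coef_age"]),
            coef_charlson_1=float(d["coef_charlson_1"]),
            coef_charlson_2plus=float(d["coef_charlson_2plus"]),
            age_ref=float(d.get("age_ref", 65.0)),
            standard_errors={k: float(v) for k, v in d.get("standard_errors", {}).items()},
            n=int(d.get("n", 0)),
            n_events=int(d.get("n_events", 0)),
        )


def fit_weibull_regression(cohort: Sequence[SurvivalRecord]) -> WeibullRegression:
    """Censored ML Weibull accelerated-failure fit of the no-csPCa cohort.

    Follow-up in months is converted to years internally.  Age is
    centered at 65 so the intercept is the log scale for a 65-year-old
    without comorbidity.

    Raises
    ------
    NonIdentifiableError
        If the cohort contains no deaths.
    RuntimeError
        If the optimizer does not converge.
    """
    from lifelines import WeibullAFTFitter
    from lifelines.exceptions import ConvergenceError as _LLConvergence

    df = _records_frame(cohort)
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise NonIdentifiableError("no deaths in cohort: Weibull scale not identifiable")
    df["age_c"] = df["age"] - 65.0
    fit_df = df[["duration_years", "event", "age_c", "charlson_1", "charlson_2plus"]]
    aft = WeibullAFTFitter()
    try:
        aft.fit(fit_df, duration_col="duration_years", event_col="event")
    except _LLConvergence as exc:
        raise RuntimeError(f"Weibull AFT fit did not converge: {exc}") from exc

    params = aft.params_
    se = aft.standard_errors_

    def _p(col):
        return float(params[("lambda_", col)])

    def _se(col):
        return float(se[("lambda_", col)])

    shape = float(np.exp(params[("rho_", "Intercept")]))
    return WeibullRegression(
        shape=shape,
        intercept=_p("Intercept"),
        coef_age=_p("age_c"),
        coef_charlson_1=_p("charlson_1"),
        coef_charlson_2plus=_p("charlson_2plus"),
        age_ref=65.0,
        standard_errors={
            "intercept": _se("Intercept"),
            "coef_age": _se("age_c"),
            "coef_charlson_1": _se("charlson_1"),
            "coef_charlson_2plus": _se("charlson_2plus"),
            "log_shape": float(se[("rho_", "Intercept")]),
        },
        n=len(cohort),
        n_events=n_events,
    )


def fit_relative_mortality(
    cohort: Sequence[SurvivalRecord], life_table: LifeTable
) -> float:
    """Reference-population vs cohort mortality ratio via Poisson regression.

    Expected deaths per man are accumulated from the life table along
    his follow-up (age advancing annually, final year pro-rated) and
    entered as a log offset in a Poisson regression of observed deaths
    on centered age and Charlson indicators.  The returned ratio is the
    reference-to-cohort rate ratio at reference covariates: a healthy
    screening cohort (lower mortality than the life table) yields a
    ratio above 1.
    """
    import statsmodels.api as sm

    df = _records_frame(cohort)
    expected = np.array([
        life_table.expected_deaths(r.age_at_entry, r.follow_up_months / 12.0)
        for r in cohort
    ])
    if expected.sum() <= 0:
        raise ValueError("zero expected deaths: follow-up or life table degenerate")
    observed = df["event"].to_numpy()
    if observed.sum() == 0:
        raise NonIdentifiableError("no observed deaths: relative mortality undefined")
    keep = expected > 0
    X = sm.add_constant(
        np.column_stack([
            df["age"].to_numpy()[keep] - df["age"].to_numpy()[keep].mean(),
            df["charlson_1"].to_numpy()[keep],
            df["charlson_2plus"].to_numpy()[keep],
        ]),
        has_constant="add",
    )
    model = sm.GLM(
        observed[keep], X,
        family=sm.families.Poisson(),
        offset=np.log(expected[keep]),
    )
    res = model.fit()
    # intercept = log(observed/expected) at reference covariates; invert
    # to report how much higher reference-population mortality is.
    return float(np.exp(-res.params[0]))


def impute_charlson(
    cohort: Sequence[SurvivalRecord], seed: int = 0, k_donors: int = 5
) -> List[SurvivalRecord]:
    """Fill missing Charlson strata by predictive-mean matching.

    The numeric Charlson code (0, 1, 2) is regressed on age and vital
    status among complete records; each missing value takes the
    observed stratum of a donor drawn uniformly from the ``k_donors``
    complete records with nearest predicted mean.  Single imputation
    with a fixed seed; imputed values always lie in the observed
    support.
    """
    complete = [r for r in cohort if r.charlson is not None]
    missing_idx = [i for i, r in enumerate(cohort) if r.charlson is None]
    if not missing_idx:
        return list(cohort)
    if len(complete) < 10:
        raise ValueError("need at least 10 complete records for imputation")

    code = {"0": 0.0, "1": 1.0, "2+": 2.0}
    Xc = np.column_stack([
        np.ones(len(complete)),
        [r.age_at_entry for r in complete],
        [1.0 if r.dead else 0.0 for r in complete],
    ])
    yc = np.array([code[r.charlson] for r in complete])
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    pred_complete = Xc @ beta

    rng = np.random.default_rng(seed)
    out = list(cohort)
    k = min(k_donors, len(complete))
    for i in missing_idx:
        r = cohort[i]
        pred = beta[0] + beta[1] * r.age_at_entry + beta[2] * (1.0 if r.dead else 0.0)
        nearest = np.argsort(np.abs(pred_complete - pred), kind="stable")[:k]
        donor = complete[int(rng.choice(nearest))]
        out[i] = SurvivalRecord(
            age_at_entry=r.age_at_entry,
            charlson=donor.charlson,
            follow_up_months=r.follow_up_months,
            status=r.status,
        )
    return out


@dataclass(frozen=True)
class LifeExpectancyModel:
    """The triage tool's combined life-expectancy model.

    Holds (a) per-stratum untreated-csPCa life expectancies on a fixed
    Weibull shape, as calibrated from registry curve fits after the
    Gleason re-weighting and PSA-era adjustment, and (b) the no-csPCa
    Weibull regression plus the healthy-screenee relative-mortality
    ratio applied to it.
    """

    cspca_shape: float
    cspca_le_years: Mapping[str, Mapping[str, float]]  # age_band -> charlson -> years
    no_cspca: WeibullRegression
    relative_mortality: float
    era_effect: float = 0.79
    metadata: Dict = field(default_factory=dict)

    def curve_untreated_cspca(self, age: float, charlson: str) -> WeibullSurvival:
        band = age_band_of(age)
        try:
            le = self.cspca_le_years[band][charlson]
        except KeyError:
            raise ValueError(f"no csPCa stratum for ({band}, {charlson})") from None
        return weibull_from_mean(le, self.cspca_shape)

    def curve_without_cspca(self, age: float, charlson: str) -> WeibullSurvival:
        base = self.no_cspca.curve_for(age, charlson)
        return apply_relative_mortality(base, self.relative_mortality)

    def to_dict(self) -> dict:
        return {
            "cspca_shape": self.cspca_shape,
            "cspca_le_years": {b: dict(v) for b, v in self.cspca_le_years.items()},
            "no_cspca": self.no_cspca.to_dict(),
            "relative_mortality": self.relative_mortality,
            "era_effect": self.era_effect,
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LifeExpectancyModel":
        return cls(
            cspca_shape=float(d["cspca_shape"]),
            cspca_le_years={b: {c: float(x) for c, x in v.items()}
                            for b, v in d["cspca_le_years"].items()},
            no_cspca=WeibullRegression.from_dict(d["no_cspca"]),
            relative_mortality=float(d["relative_mortality"]),
            era_effect=float(d.get("era_effect", 0.79)),
            metadata=dict(d.get("metadata", {})),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "LifeExpectancyModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
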
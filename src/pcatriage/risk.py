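"""Logistic risk models for clinically significant prostate cancer on biopsy.

The outcome is binary: ISUP grade >= 2 cancer (Gleason >= 3+4) versus
everything else (no cancer and indolent grade-1 cancer pooled).  PSA,
the free-to-total PSA ratio and the rough prostate-volume estimate
enter on the log2 scale, centered at the training-cohort mean of the
log2 value; the centering constants are stored on the model so that
prediction for a new patient needs no cohort.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import BiopsyRecord, PatientProfile

__all__ = [
    "RiskModel",
    "PredictorUnavailableError",
    "SeparationError",
    "ConvergenceError",
    "transform_predictors",
    "fit_cspca_model",
    "predict_cspca_risk",
    "BASIC_PREDICTORS",
    "LOG2_PREDICTORS",
]

#: the "basic model": the predictor set every GP has at hand
BASIC_PREDICTORS = ("psa", "age", "free_psa_pct")

#: predictors entered as centered log2 values
LOG2_PREDICTORS = ("psa", "free_psa_pct", "pv_estimate_cc")

#: predictors encoded 0/1
BINARY_PREDICTORS = ("dre_abnormal", "family_history")

KNOWN_PREDICTORS = ("psa", "age", "free_psa_pct", "dre_abnormal",
                    "pv_estimate_cc", "family_history", "ipss")


class PredictorUnavailableError(ValueError):
    """A predictor required by the model is missing from the profile."""


class SeparationError(RuntimeError):
    """The fit is degenerate because a predictor perfectly separates outcomes."""


class ConvergenceError(RuntimeError):
    """Maximum-likelihood fitting did not converge."""


@dataclass(frozen=True)
class RiskModel:
    """Fitted logistic model for the probability of csPCa on biopsy.

    Attributes
    ----------
    predictor_set : tuple of str
        Ordered predictor names.
    coefficients : dict
        Log-odds-ratio per predictor, on the transformed scale.
    intercept : float
        Log-odds at the centering reference.
    centering : dict
        Constant subtracted from each log2-transformed predictor
        (training-cohort mean of the log2 value).
    fit_metadata : dict
        Provenance (n, seed, date) for shipped model files.
    """

    predictor_set: Tuple[str, ...]
    coefficients: Dict[str, float]
    intercept: float
    centering: Dict[str, float] = field(default_factory=dict)
    fit_metadata: Dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.coefficients) != set(self.predictor_set):
            raise ValueError("coefficients must cover exactly the predictor set")
        extra = set(self.centering) - set(LOG2_PREDICTORS)
        if extra:
            raise ValueError(f"centering only applies to log2 predictors, got {extra}")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "predictor_set": list(self.predictor_set),
            "coefficients": dict(self.coefficients),
            "intercept": self.intercept,
            "centering": dict(self.centering),
            "fit_metadata": dict(self.fit_metadata),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModel":
        return cls(
            predictor_set=tuple(d["predictor_set"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            intercept=float(d["intercept"]),
            centering={k: float(v) for k, v in d.get("centering", {}).items()},
            fit_metadata=dict(d.get("fit_metadata", {})),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "RiskModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _raw_value(profile: PatientProfile, name: str) -> float:
    value = getattr(profile, name, None)
    if value is None:
        raise PredictorUnavailableError(
            f"predictor unavailable: {name!r} is missing from the profile"
        )
    return value


def transform_predictors(profile: PatientProfile, model: RiskModel) -> np.ndarray:
    """Build the model's design vector for one patient, in model order.

    log2 predictors are transformed as log2(x) - centering[name] (no
    centering entry means the raw log2 value); binary predictors are
    encoded 0/1; the rest enter untransformed.
    """
    out = []
    for name in model.predictor_set:
        value = _raw_value(profile, name)
        if name in LOG2_PREDICTORS:
            if value <= 0:
                raise ValueError(f"{name} must be positive for log2 transform, got {value}")
            out.append(math.log2(value) - model.centering.get(name, 0.0))
        elif name in BINARY_PREDICTORS:
            out.append(1.0 if value else 0.0)
        else:
            out.append(float(value))
    return np.array(out, dtype=float)


def _design_matrix(
    cohort: Sequence[BiopsyRecord], predictor_set: Sequence[str]
) -> Tuple[np.ndarray, np.ndarray, Dict[str, float]]:
    """Raw-scale design matrix, binary outcome, and centering constants."""
    rows = []
    y = []
    for i, rec in enumerate(cohort):
        row = []
        for name in predictor_set:
            value = getattr(rec.profile, name, None)
            if value is None:
                raise PredictorUnavailableError(
                    f"predictor unavailable: {name!r} missing in cohort record {i}"
                )
            if name in LOG2_PREDICTORS:
                row.append(math.log2(value))
            elif name in BINARY_PREDICTORS:
                row.append(1.0 if value else 0.0)
            else:
                row.append(float(value))
        rows.append(row)
        y.append(1.0 if rec.is_cspca else 0.0)
    X = np.array(rows, dtype=float)
    yv = np.array(y, dtype=float)
    centering = {
        name: float(X[:, j].mean())
        for j, name in enumerate(predictor_set)
        if name in LOG2_PREDICTORS
    }
    for j, name in enumerate(predictor_set):
        if name in LOG2_PREDICTORS:
            X[:, j] -= centering[name]
    return X, yv, centering


def _check_separation(X: np.ndarray, y: np.ndarray, names: Sequence[str]) -> None:
    pos, neg = y == 1, y == 0
    for j, name in enumerate(names):
        if X[pos, j].min() > X[neg, j].max() or X[neg, j].min() > X[pos, j].max():
            raise SeparationError(
                f"perfect separation: predictor {name!r} completely separates "
                "csPCa from non-csPCa outcomes"
            )


def fit_cspca_model(
    cohort: Sequence[BiopsyRecord],
    predictor_set: Sequence[str] = BASIC_PREDICTORS,
    maxiter: int = 100,
    fit_metadata: Optional[dict] = None,
) -> RiskModel:
    """Maximum-likelihood logistic fit of csPCa vs {no cancer, indolent}.

    Centering constants are set to the cohort means of the log2
    predictors, so the intercept is the log-odds for a man at the
    cohort-average PSA / %freePSA / volume (and zero on the remaining
    predictors).

    Raises
    ------
    SeparationError
        If a predictor perfectly separates the two outcome classes.
    ConvergenceError
        If the optimizer fails to converge within ``maxiter`` iterations.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    unknown = set(predictor_set) - set(KNOWN_PREDICTORS)
    if unknown:
        raise ValueError(f"unknown predictors: {sorted(unknown)}")
    X, y, centering = _design_matrix(cohort, predictor_set)
    if len(np.unique(y)) < 2:
        raise ValueError("cohort must contain both csPCa and non-csPCa outcomes")
    _check_separation(X, y, predictor_set)

    Xc = sm.add_constant(X, has_constant="add")
    try:
        res = sm.Logit(y, Xc).fit(disp=0, maxiter=maxiter)
    except PerfectSeparationError as exc:  # not caught by the marginal check
        raise SeparationError(f"perfect separation during fit: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(
            f"logistic fit did not converge within {maxiter} iterations"
        )
    params = np.asarray(res.params, dtype=float)
    meta = {"n": len(cohort), **(fit_metadata or {})}
    return RiskModel(
        predictor_set=tuple(predictor_set),
        coefficients={name: float(b) for name, b in zip(predictor_set, params[1:])},
        intercept=float(params[0]),
        centering=centering,
        fit_metadata=meta,
    )


def predict_cspca_risk(model: RiskModel, profile: PatientProfile) -> float:
    """Probability of csPCa on a current biopsy; strictly in (0, 1)."""
    x = transform_predictors(profile, model)
    beta = np.array([model.coefficients[n] for n in model.predictor_set])
    eta = model.intercept + float(beta @ x)
    # expit, clipped away from exact 0/1
    p = 1.0 / (1.0 + math.exp(-eta))
    return min(max(p, 1e-12), 1 - 1e-12)


def predict_cohort(model: RiskModel, cohort: Sequence[BiopsyRecord]) -> np.ndarray:
    """Vector of predicted csPCa probabilities over a cohort."""
    return np.array([predict_cspca_risk(model, r.profile) for r in cohort])
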
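"""Model-selection metrics: concordance, bootstrap optimism, IPA, net benefit.

These are the quantities used to choose among candidate csPCa risk
models: the concordance index corrected for optimism by refitting on
bootstrap resamples, the Index of Prediction Accuracy (a Brier-score
skill measure capturing discrimination and calibration jointly), and
decision-curve net benefit against the default biopsy-everyone-with-
PSA>=3 strategy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy.stats import rankdata

from .types import BiopsyRecord

__all__ = [
    "MetricReport",
    "DecisionCurvePoint",
    "UndefinedMetricError",
    "concordance_index",
    "bootstrap_optimism",
    "bootstrap_optimism_matrix",
    "ipa",
    "net_benefit",
    "decision_curve",
    "DEFAULT_THRESHOLD_GRID",
]

#: decision-curve threshold grid: the 3-10% range a patient might
#: require before opting for biopsy, in 0.5% steps
DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.03, 0.10 + 1e-9, 0.005), 4)

#: PSA cutoff of the default referral strategy (ng/mL)
DEFAULT_PSA_CUTOFF = 3.0


class UndefinedMetricError(ValueError):
    """The metric is undefined for the given outcome vector."""


@dataclass(frozen=True)
class MetricReport:
    """Apparent and optimism-corrected discrimination plus IPA."""

    c_index_apparent: float
    c_index_optimism: float
    c_index_corrected: float
    ipa_pct: float
    n_bootstrap: int
    n_skipped: int = 0

    def to_dict(self) -> dict:
        return {
            "c_index_apparent": round(self.c_index_apparent, 3),
            "c_index_optimism": round(self.c_index_optimism, 3),
            "c_index_corrected": round(self.c_index_corrected, 3),
            "ipa_pct": round(self.ipa_pct, 1),
            "n_bootstrap": self.n_bootstrap,
            "n_skipped": self.n_skipped,
        }


@dataclass(frozen=True)
class DecisionCurvePoint:
    """Net benefit of each strategy at one threshold probability."""

    threshold: float
    net_benefit_model: float
    net_benefit_default: float
    net_benefit_all: float
    net_benefit_none: float  # identically 0
    biopsies_avoided_per_1000: float


def _validate_binary(outcomes: np.ndarray) -> np.ndarray:
    y = np.asarray(outcomes, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcomes must be binary 0/1")
    return y


def concordance_index(predictions: Sequence[float], outcomes: Sequence[int]) -> float:
    """Probability that a random case outranks a random control; ties count 1/2.

    Computed via midranks (Mann-Whitney form), which is exactly the
    all-pairs count including half-credit for tied predictions.
    """
    p = np.asarray(predictions, dtype=float)
    y = _validate_binary(outcomes)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            "concordance index undefined: need both positive and negative outcomes"
        )
    ranks = rankdata(p)  # midranks handle ties as 1/2
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def ipa(predictions: Sequence[float], outcomes: Sequence[int]) -> float:
    """Index of Prediction Accuracy in percent: (1 - Brier/Brier_null) * 100.

    The null model predicts the outcome prevalence for everyone; 0%
    means no better than prevalence, 100% means perfect 0/1 predictions.
    """
    p = np.asarray(predictions, dtype=float)
    y = _validate_binary(outcomes)
    prev = y.mean()
    brier_null = float(np.mean((prev - y) ** 2))
    if brier_null == 0.0:
        raise UndefinedMetricError("IPA undefined: outcome prevalence is 0 or 1")
    brier_model = float(np.mean((p - y) ** 2))
    return (1.0 - brier_model / brier_null) * 100.0


def net_benefit(
    predictions: Sequence[float], outcomes: Sequence[int], threshold: float
) -> float:
    """Net benefit of biopsying when predicted risk >= threshold.

    NB = TP/n - (t/(1-t)) * FP/n: true-positive biopsies credited in
    full, unnecessary biopsies debited at the odds of the threshold
    probability (the patient's own harm weighting).
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be strictly between 0 and 1")
    p = np.asarray(predictions, dtype=float)
    y = _validate_binary(outcomes)
    n = len(y)
    advise = p >= threshold
    tp = float(np.sum(advise & (y == 1)))
    fp = float(np.sum(advise & (y == 0)))
    return tp / n - (threshold / (1.0 - threshold)) * fp / n


def decision_curve(
    predictions: Sequence[float],
    outcomes: Sequence[int],
    psa_values: Sequence[float],
    grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    psa_cutoff: float = DEFAULT_PSA_CUTOFF,
) -> List[DecisionCurvePoint]:
    """Net benefit of model vs default (PSA-cutoff), treat-all and treat-none.

    The default strategy advises biopsy iff PSA >= ``psa_cutoff``; its
    TP/FP counts do not depend on the threshold, only the harm weight
    does.  ``biopsies_avoided_per_1000`` is the reduction in biopsies
    advised by the model relative to the default strategy, per 1000 men.
    """
    p = np.asarray(predictions, dtype=float)
    y = _validate_binary(outcomes)
    psa = np.asarray(psa_values, dtype=float)
    if len(psa) != len(y):
        raise ValueError("psa_values must align with outcomes")
    n = len(y)
    prev = y.mean()
    default_sel = psa >= psa_cutoff
    tp_d = float(np.sum(default_sel & (y == 1)))
    fp_d = float(np.sum(default_sel & (y == 0)))
    out = []
    for t in np.asarray(grid, dtype=float):
        w = t / (1.0 - t)
        nb_model = net_benefit(p, y, t)
        nb_default = tp_d / n - w * fp_d / n
        nb_all = prev - w * (1.0 - prev)
        n_model = float(np.sum(p >= t))
        avoided = 1000.0 * (float(default_sel.sum()) - n_model) / n
        out.append(
            DecisionCurvePoint(
                threshold=float(t),
                net_benefit_model=nb_model,
                net_benefit_default=nb_default,
                net_benefit_all=nb_all,
                net_benefit_none=0.0,
                biopsies_avoided_per_1000=avoided,
            )
        )
    return out


def _logit_linear_predictor(X: np.ndarray, y: np.ndarray, maxiter: int = 100):
    """Fit logistic MLE on (X, y); return the fitted params or None if degenerate."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    Xc = sm.add_constant(X, has_constant="add")
    try:
        res = sm.Logit(y, Xc).fit(disp=0, maxiter=maxiter)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return None
    if not res.mle_retvals.get("converged", False):
        return None
    return np.asarray(res.params, dtype=float)


def bootstrap_optimism_matrix(
    X: np.ndarray, y: np.ndarray, n_boot: int = 1000, seed: int = 0
) -> MetricReport:
    """Optimism-corrected concordance on a raw design matrix.

    For each of ``n_boot`` resamples drawn with replacement, the
    logistic model is refit on the resample; the optimism of that
    replicate is the concordance on the resample minus the concordance
    of the refit model evaluated on the original data.  The corrected
    index is the apparent concordance minus the mean optimism.
    Degenerate resamples (single outcome class, separation,
    non-convergence) are skipped and counted; more than 10% skipped is
    an error.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = _validate_binary(y)
    params = _logit_linear_predictor(X, y)
    if params is None:
        raise RuntimeError("apparent model fit is degenerate")
    Xc = np.column_stack([np.ones(len(y)), X])
    preds = 1.0 / (1.0 + np.exp(-(Xc @ params)))
    apparent = concordance_index(preds, y)
    ipa_pct = ipa(preds, y)

    rng = np.random.default_rng(seed)
    n = len(y)
    optimisms = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ys = y[idx]
        if ys.min() == ys.max():
            skipped += 1
            continue
        pb = _logit_linear_predictor(X[idx], ys)
        if pb is None:
            skipped += 1
            continue
        eta_boot = np.column_stack([np.ones(n), X[idx]]) @ pb
        eta_orig = Xc @ pb
        c_boot = concordance_index(eta_boot, ys)  # c is rank-invariant to expit
        c_orig = concordance_index(eta_orig, y)
        optimisms.append(c_boot - c_orig)
    if skipped > 0.10 * n_boot:
        raise RuntimeError(
            f"bootstrap failed: {skipped}/{n_boot} resamples were degenerate"
        )
    optimism = float(np.mean(optimisms)) if optimisms else 0.0
    return MetricReport(
        c_index_apparent=apparent,
        c_index_optimism=optimism,
        c_index_corrected=apparent - optimism,
        ipa_pct=ipa_pct,
        n_bootstrap=n_boot,
        n_skipped=skipped,
    )


def bootstrap_optimism(
    cohort: Sequence[BiopsyRecord],
    predictor_set: Sequence[str],
    n_boot: int = 1000,
    seed: int = 0,
) -> MetricReport:
    """Optimism-corrected concordance for a biopsy cohort and predictor set.

    Builds the transformed design matrix once (centering is
    rank-invariant so per-resample re-centering cannot change the
    concordance) and delegates to :func:`bootstrap_optimism_matrix`.
    """
    from .risk import _design_matrix

    X, y, _ = _design_matrix(cohort, predictor_set)
    return bootstrap_optimism_matrix(X, y, n_boot=n_boot, seed=seed)
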
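"""Weibull survival curves and the adjustments applied to them.

The life-expectancy machinery represents every survival curve as a
two-parameter Weibull, S(t) = exp(-(t/scale)^shape), fitted either to
published curve points (complementary log-log least squares) or to
individual censored follow-up (see :mod:`pcatriage.lifeexp`).  Mean
survival -- the life expectancy -- is scale * Gamma(1 + 1/shape).

Proportional hazards acts on a Weibull by rescaling: multiplying the
hazard by r keeps the shape and divides the scale by r^(1/shape),
equivalently S(t) -> S(t)^r.  Both the healthy-screenee correction and
the treatment hazard ratio use this identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from scipy.special import gamma as _gamma

__all__ = [
    "WeibullSurvival",
    "SurvivalCurvePoints",
    "GleasonWeights",
    "fit_weibull_to_points",
    "weibull_mean",
    "weibull_from_mean",
    "gleason_mixture_adjust",
    "psa_era_adjust",
    "apply_relative_mortality",
]

AGE_BANDS = ("55-59", "60-64", "65-69", "70-74", "75+")
GLEASON_BANDS = ("5-7", "8-10")


@dataclass(frozen=True)
class WeibullSurvival:
    """A survival curve S(t) = exp(-(t/scale)^shape), t in years."""

    shape: float
    scale: float

    def __post_init__(self):
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError(
                f"shape and scale must be positive, got ({self.shape}, {self.scale})"
            )

    def survival(self, t):
        """S(t); accepts scalars or arrays, vectorized."""
        t = np.asarray(t, dtype=float)
        return np.exp(-np.power(t / self.scale, self.shape))

    def hazard(self, t):
        """Instantaneous hazard h(t) = (shape/scale) (t/scale)^(shape-1)."""
        t = np.asarray(t, dtype=float)
        return (self.shape / self.scale) * np.power(t / self.scale, self.shape - 1)

    @property
    def mean(self) -> float:
        return weibull_mean(self)

    def restricted_mean(self, horizon: float = 25.0) -> float:
        """Mean survival restricted to [0, horizon] years.

        The unrestricted mean extrapolates the fitted curve far beyond
        the data for very old or very comorbid men; the restricted mean
        caps that extrapolation.
        """
        from scipy.integrate import quad

        val, _ = quad(lambda t: float(self.survival(t)), 0.0, horizon, limit=200)
        return val


@dataclass(frozen=True)
class SurvivalCurvePoints:
    """Published (t, S) points for one age-band x Charlson x Gleason stratum."""

    age_band: str
    charlson: str
    gleason_band: str
    points: Tuple[Tuple[float, float], ...]

    def __post_init__(self):
        if len(self.points) < 2:
            raise ValueError("need at least 2 survival points per stratum")
        last_t, last_s = -np.inf, np.inf
        for t, s in self.points:
            if t <= 0:
                raise ValueError(f"time points must be positive, got {t}")
            if not (0 < s < 1):
                raise ValueError(f"survival must be strictly in (0, 1), got {s}")
            if t <= last_t:
                raise ValueError("time points must be strictly increasing")
            if s > last_s:
                raise ValueError("survival must be nonincreasing in time")
            last_t, last_s = t, s


@dataclass(frozen=True)
class GleasonWeights:
    """Source (registry) and target (screening-cohort) Gleason-band weights.

    The registry curves are stratified by Gleason band; the screening
    cohort defining clinically significant disease (ISUP grade >= 2) has
    a different band composition, so the mixture is re-weighted to the
    target composition before computing life expectancy.
    """

    source: Mapping[str, float]
    target: Mapping[str, float]

    def __post_init__(self):
        for name, w in (("source", self.source), ("target", self.target)):
            if any(not (0 <= v <= 1) for v in w.values()):
                raise ValueError(f"{name} weights must lie in [0, 1]")
            if abs(sum(w.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} weights must sum to 1")


def fit_weibull_to_points(points) -> WeibullSurvival:
    """Fit a Weibull curve to (t, S) points by complementary log-log regression.

    log(-log S) is linear in log t for a Weibull: slope = shape and
    intercept = -shape * log(scale).  Ordinary least squares on that
    line inverts exact Weibull tabulations perfectly and is the standard
    way to approximate a published survival curve.

    Parameters
    ----------
    points : SurvivalCurvePoints or sequence of (t, S) pairs

    Returns
    -------
    WeibullSurvival
    """
    if isinstance(points, SurvivalCurvePoints):
        pts = points.points
    else:
        pts = list(points)
        if len(pts) < 2:
            raise ValueError("need at least 2 survival points")
    t = np.array([p[0] for p in pts], dtype=float)
    s = np.array([p[1] for p in pts], dtype=float)
    if np.any(t <= 0):
        raise ValueError("time points must be positive")
    if np.any((s <= 0) | (s >= 1)):
        raise ValueError("survival values must be strictly in (0, 1)")
    if np.any(np.diff(s) > 1e-12):
        raise ValueError("survival values must be nonincreasing in time")
    x = np.log(t)
    y = np.log(-np.log(s))
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise ValueError("fitted shape is nonpositive; points are not Weibull-like")
    shape = float(slope)
    scale = float(math.exp(-intercept / shape))
    return WeibullSurvival(shape=shape, scale=scale)


def weibull_mean(w: WeibullSurvival) -> float:
    """Life expectancy: the unrestricted mean scale * Gamma(1 + 1/shape)."""
    return float(w.scale * _gamma(1.0 + 1.0 / w.shape))


def weibull_from_mean(mean: float, shape: float) -> WeibullSurvival:
    """Weibull curve with the given shape whose mean equals ``mean`` years."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    return WeibullSurvival(shape=shape, scale=mean / float(_gamma(1.0 + 1.0 / shape)))


_DEFAULT_GRID = np.arange(1.0, 21.0)


def _refit_on_grid(survival_fn, grid=None) -> WeibullSurvival:
    grid = _DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    s = np.clip(survival_fn(grid), 1e-12, 1 - 1e-12)
    return fit_weibull_to_points(list(zip(grid, s)))


def gleason_mixture_adjust(
    curves: Mapping[str, WeibullSurvival],
    weights: GleasonWeights,
    grid: Sequence[float] | None = None,
) -> WeibullSurvival:
    """Re-weight per-Gleason-band survival curves to the target composition.

    The adjusted survival is the target-weighted mixture
    S_adj(t) = sum_b w_target(b) S_b(t), tabulated on a yearly grid and
    refit to a single Weibull.  The mixture lies pointwise between the
    component curves.

    Raises
    ------
    ValueError
        If the weight keys do not match the provided bands exactly.
    """
    if set(weights.target) != set(curves):
        raise ValueError(
            f"weight bands {sorted(weights.target)} do not match "
            f"curve bands {sorted(curves)}"
        )
    bands = sorted(curves)
    w = np.array([weights.target[b] for b in bands])
    comps = [curves[b] for b in bands]

    def mixture(t):
        return sum(wi * c.survival(t) for wi, c in zip(w, comps))

    return _refit_on_grid(mixture, grid)


def psa_era_adjust(
    overall: WeibullSurvival,
    other_cause: WeibullSurvival,
    rel_effect: float = 0.79,
    grid: Sequence[float] | None = None,
) -> WeibullSurvival:
    """Apply a relative effect on cancer-specific mortality to an overall curve.

    Overall survival is decomposed under independent competing hazards as
    S_overall = S_other * S_pca; the cause-specific component is powered
    by ``rel_effect`` (a relative hazard on prostate-cancer mortality,
    0.79 by default for the PSA-era mortality reduction) and the product
    is re-assembled:  S_adj = S_other * S_pca^rel_effect.

    With ``rel_effect < 1`` the adjusted survival is pointwise >= the
    original.  Requires S_other >= S_overall on the tabulation grid so
    the implied cancer-specific survival stays in (0, 1].
    """
    if rel_effect <= 0:
        raise ValueError("rel_effect must be positive")
    grid_arr = _DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    s_all = overall.survival(grid_arr)
    s_other = other_cause.survival(grid_arr)
    s_pca = s_all / s_other
    if np.any(s_pca > 1 + 1e-9):
        raise ValueError(
            "other-cause survival falls below overall survival: "
            "cause-specific decomposition is invalid"
        )
    s_pca = np.clip(s_pca, 1e-12, 1.0)
    s_adj = np.clip(s_other * np.power(s_pca, rel_effect), 1e-12, 1 - 1e-12)
    return fit_weibull_to_points(list(zip(grid_arr, s_adj)))


def apply_relative_mortality(w: WeibullSurvival, ratio: float) -> WeibullSurvival:
    """Multiply the hazard by ``ratio``: same shape, scale / ratio^(1/shape).

    Equivalent to S'(t) = S(t)^ratio.  A ratio > 1 (e.g. the healthy
    screenee correction toward the general population) strictly lowers
    life expectancy; applying ratios a then b equals applying a*b.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return WeibullSurvival(shape=w.shape, scale=w.scale * ratio ** (-1.0 / w.shape))
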
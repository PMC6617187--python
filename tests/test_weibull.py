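"""Weibull curve fitting, means, and the survival-curve adjustments."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from pcatriage.weibull import (
    GleasonWeights,
    SurvivalCurvePoints,
    WeibullSurvival,
    apply_relative_mortality,
    fit_weibull_to_points,
    gleason_mixture_adjust,
    psa_era_adjust,
    weibull_from_mean,
    weibull_mean,
)


def numeric_mean(w: WeibullSurvival) -> float:
    """Independent oracle: mean survival = integral of S(t) over [0, inf)."""
    val, _ = quad(lambda t: float(w.survival(t)), 0, np.inf, limit=500)
    return val


class TestFitToPoints:
    def test_exact_inversion(self):
        w = WeibullSurvival(shape=1.4, scale=13.5)
        pts = [(t, float(w.survival(t))) for t in range(2, 15)]
        fit = fit_weibull_to_points(pts)
        assert fit.shape == pytest.approx(1.4, abs=1e-9)
        assert fit.scale == pytest.approx(13.5, abs=1e-9)

    def test_exponential_recovers_unit_shape(self):
        w = WeibullSurvival(shape=1.0, scale=10.0)
        pts = [(t, float(w.survival(t))) for t in (1, 3, 5, 8, 12)]
        assert fit_weibull_to_points(pts).shape == pytest.approx(1.0, abs=1e-9)

    def test_noisy_points_recover_shape_within_tenth(self, rng):
        w = WeibullSurvival(shape=1.4, scale=13.5)
        ts = np.linspace(2, 14, 8)
        noise = rng.normal(0, 0.01, size=8)  # 1% multiplicative noise
        pts = [(t, float(w.survival(t)) * (1 + e)) for t, e in zip(ts, noise)]
        pts = [(t, min(s, 1 - 1e-9)) for t, s in pts]
        pts = [(t, s) for t, s in zip(ts, np.minimum.accumulate([s for _, s in pts]))]
        assert fit_weibull_to_points(pts).shape == pytest.approx(1.4, abs=0.1)

    def test_degenerate_survival_rejected(self):
        with pytest.raises(ValueError):
            fit_weibull_to_points([(1.0, 1.0), (2.0, 0.5)])
        with pytest.raises(ValueError):
            fit_weibull_to_points([(1.0, 0.5), (2.0, 0.6)])

    def test_stratum_container_validates_monotonicity(self):
        with pytest.raises(ValueError):
            SurvivalCurvePoints(age_band="65-69", charlson="0", gleason_band="5-7",
                                points=((1.0, 0.5), (2.0, 0.7)))


class TestWeibullMean:
    def test_exponential_mean_is_scale(self):
        assert weibull_mean(WeibullSurvival(shape=1.0, scale=10.0)) == pytest.approx(10.0)

    def test_shape_two_matches_integration_oracle(self):
        w = WeibullSurvival(shape=2.0, scale=10.0)
        assert weibull_mean(w) == pytest.approx(8.8623, abs=1e-4)
        assert weibull_mean(w) == pytest.approx(numeric_mean(w), abs=1e-6)

    def test_closed_form_matches_integration_over_grid(self):
        for k in np.linspace(0.5, 5.0, 5):
            for lam in np.linspace(1.0, 50.0, 4):
                w = WeibullSurvival(shape=float(k), scale=float(lam))
                assert weibull_mean(w) == pytest.approx(numeric_mean(w), rel=1e-6)

    def test_from_mean_round_trip(self):
        w = weibull_from_mean(12.3, 1.4)
        assert weibull_mean(w) == pytest.approx(12.3, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(k=st.floats(0.5, 5.0), lam=st.floats(1.0, 50.0))
    def test_tabulate_then_refit_is_identity(self, k, lam):
        w = WeibullSurvival(shape=k, scale=lam)
        # tabulate at scale-relative times so S stays far from 0 and 1
        pts = [(lam * f, float(w.survival(lam * f)))
               for f in (0.5, 0.8, 1.0, 1.2, 1.5)]
        fit = fit_weibull_to_points(pts)
        assert fit.shape == pytest.approx(k, rel=1e-6)
        assert fit.scale == pytest.approx(lam, rel=1e-6)


class TestGleasonMixture:
    def test_all_weight_on_one_band_returns_that_curve(self):
        curves = {"5-7": WeibullSurvival(1.4, 14.0), "8-10": WeibullSurvival(1.4, 7.0)}
        weights = GleasonWeights(source={"5-7": 0.6, "8-10": 0.4},
                                 target={"5-7": 1.0, "8-10": 0.0})
        mixed = gleason_mixture_adjust(curves, weights)
        assert mixed.shape == pytest.approx(1.4, abs=1e-6)
        assert mixed.scale == pytest.approx(14.0, rel=1e-6)

    def test_equal_weight_exponentials_hand_value(self):
        # S_adj(5) = (e^-1 + e^-1/3)/2 for exponentials with scales 5 and 15
        curves = {"5-7": WeibullSurvival(1.0, 15.0), "8-10": WeibullSurvival(1.0, 5.0)}
        weights = GleasonWeights(source={"5-7": 0.5, "8-10": 0.5},
                                 target={"5-7": 0.5, "8-10": 0.5})
        grid = np.arange(1.0, 21.0)
        mixture_at_5 = 0.5 * (math.exp(-1.0) + math.exp(-1.0 / 3.0))
        s_adj = 0.5 * (curves["5-7"].survival(5.0) + curves["8-10"].survival(5.0))
        assert float(s_adj) == pytest.approx(mixture_at_5, abs=1e-12)
        # the refit curve approximates the tabulated mixture
        mixed = gleason_mixture_adjust(curves, weights, grid=grid)
        assert float(mixed.survival(5.0)) == pytest.approx(mixture_at_5, abs=0.02)

    def test_mixture_mean_between_component_means(self):
        curves = {"5-7": WeibullSurvival(1.4, 14.0), "8-10": WeibullSurvival(1.4, 7.0)}
        weights = GleasonWeights(source={"5-7": 0.65, "8-10": 0.35},
                                 target={"5-7": 0.8, "8-10": 0.2})
        mixed = gleason_mixture_adjust(curves, weights)
        means = sorted(weibull_mean(c) for c in curves.values())
        assert means[0] <= weibull_mean(mixed) <= means[1]

    def test_band_mismatch_rejected(self):
        curves = {"5-7": WeibullSurvival(1.4, 14.0)}
        weights = GleasonWeights(source={"5-7": 0.5, "8-10": 0.5},
                                 target={"5-7": 0.5, "8-10": 0.5})
        with pytest.raises(ValueError):
            gleason_mixture_adjust(curves, weights)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            GleasonWeights(source={"5-7": 0.5, "8-10": 0.4},
                           target={"5-7": 0.5, "8-10": 0.5})


class TestEraAdjust:
    def test_unit_effect_is_identity(self):
        overall = WeibullSurvival(1.4, 12.0)
        other = WeibullSurvival(1.4, 20.0)
        adj = psa_era_adjust(overall, other, rel_effect=1.0)
        grid = np.arange(1.0, 21.0)
        np.testing.assert_allclose(adj.survival(grid), overall.survival(grid),
                                   rtol=1e-6)

    def test_exponential_components_closed_form(self):
        # h_other=0.02, h_pca=0.05, rel=0.79 -> adjusted hazard 0.0595
        other = WeibullSurvival(1.0, 1 / 0.02)
        overall = WeibullSurvival(1.0, 1 / 0.07)
        adj = psa_era_adjust(overall, other, rel_effect=0.79)
        assert adj.shape == pytest.approx(1.0, abs=1e-9)
        assert 1.0 / adj.scale == pytest.approx(0.02 + 0.79 * 0.05, abs=1e-9)

    def test_protective_effect_raises_life_expectancy(self):
        overall = WeibullSurvival(1.4, 12.0)
        other = WeibullSurvival(1.4, 25.0)
        adj = psa_era_adjust(overall, other, rel_effect=0.79)
        assert weibull_mean(adj) >= weibull_mean(overall)

    def test_invalid_decomposition_rejected(self):
        # other-cause curve heavier than overall: S_pca would exceed 1
        overall = WeibullSurvival(1.4, 20.0)
        other = WeibullSurvival(1.4, 5.0)
        with pytest.raises(ValueError):
            psa_era_adjust(overall, other)


class TestRelativeMortality:
    def test_unit_ratio_is_identity(self):
        w = WeibullSurvival(1.4, 13.0)
        assert apply_relative_mortality(w, 1.0) == w

    def test_exponential_closed_form(self):
        w = WeibullSurvival(1.0, 20.0)
        assert apply_relative_mortality(w, 1.6).scale == pytest.approx(12.5)

    def test_power_identity_pointwise(self):
        w = WeibullSurvival(1.4, 13.0)
        adj = apply_relative_mortality(w, 1.6)
        grid = np.linspace(0.5, 30, 40)
        np.testing.assert_allclose(adj.survival(grid), w.survival(grid) ** 1.6,
                                   rtol=1e-12)

    def test_multiplicative_composition(self):
        w = WeibullSurvival(1.4, 13.0)
        ab = apply_relative_mortality(apply_relative_mortality(w, 1.2), 1.5)
        direct = apply_relative_mortality(w, 1.8)
        assert ab.scale == pytest.approx(direct.scale, rel=1e-12)

    def test_ratio_above_one_lowers_life_expectancy(self):
        w = WeibullSurvival(1.4, 13.0)
        assert weibull_mean(apply_relative_mortality(w, 1.6)) < weibull_mean(w)
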
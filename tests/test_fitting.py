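"""Least-squares fits, goodness-of-fit statistics and information criteria."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sadoctave import (
    FitOptions,
    OctaveHistogram,
    adjusted_r_squared,
    chi_square_gof,
    expected_histogram,
    fit_model,
    information_criteria,
)
from sadoctave.fitting import InsufficientDataError


class TestAdjustedRSquared:
    def test_perfect_fit_scores_one(self):
        y = [3.0, 2.0, 1.0]
        assert adjusted_r_squared(y, y, k=2) == 1.0

    def test_constant_model_scores_zero(self, hollow_histogram):
        y = hollow_histogram.counts
        fit = np.full_like(y, y.mean())
        assert adjusted_r_squared(y, fit, k=1) == pytest.approx(0.0, abs=1e-14)

    def test_hand_computed_negative_value(self):
        # SS_res = 18, SS_tot = 14/3; 1 - (18/1)/((14/3)/2) = -6.714...
        val = adjusted_r_squared([4, 2, 1], [1, 2, 4], k=2)
        assert val == pytest.approx(1 - 18.0 / ((14.0 / 3.0) / 2.0), rel=1e-12)
        assert val == pytest.approx(-6.714, abs=5e-4)

    def test_plain_r2_variant(self):
        val = adjusted_r_squared([4, 2, 1], [1, 2, 4], k=2, adjusted=False)
        assert val == pytest.approx(1 - 18.0 / (14.0 / 3.0), rel=1e-12)

    def test_undefined_cases(self):
        with pytest.raises(InsufficientDataError):
            adjusted_r_squared([1, 2], [1, 2], k=2)
        with pytest.raises(ValueError):
            adjusted_r_squared([2, 2, 2], [1, 2, 3], k=1)


class TestChiSquare:
    def test_perfect_fit(self):
        chi2, df, p = chi_square_gof([5, 3, 2], [5, 3, 2], k=1)
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        chi2, df, p = chi_square_gof([10, 5], [8, 7], k=1, floor=0.0)
        assert chi2 == pytest.approx(4 / 8 + 4 / 7, rel=1e-12)
        assert df == 1
        assert p == pytest.approx(0.3006, abs=2e-4)

    def test_low_expectation_classes_are_pooled(self):
        # tail classes with expectation < 1 merge inward before the test
        chi2, df, p = chi_square_gof(
            [9, 4, 1, 0, 1], [8.0, 4.0, 1.5, 0.5, 0.2], k=1, floor=1.0
        )
        assert df == 2  # 5 classes pool to 3 (0.2 joins 0.5, then 0.7 joins 1.5)
        merged_chi2 = (9 - 8) ** 2 / 8 + 0.0 + (2 - 2.2) ** 2 / 2.2
        assert chi2 == pytest.approx(merged_chi2, rel=1e-12)

    def test_df_convention_switch(self):
        _, df_a, _ = chi_square_gof([5, 4, 3, 2], [5, 4, 3, 2], k=1, floor=0.0)
        _, df_b, _ = chi_square_gof([5, 4, 3, 2], [5, 4, 3, 2], k=1, floor=0.0,
                                    df_convention="n-k-1")
        assert (df_a, df_b) == (3, 2)

    def test_undefined_probability_when_df_below_one(self):
        _, df, p = chi_square_gof([5, 4], [5, 4], k=2, floor=0.0)
        assert df == 0 and math.isnan(p)


class TestInformationCriteria:
    def test_hand_computed_values(self):
        aic, bic = information_criteria(1.0, n=8, k=3)
        assert aic == pytest.approx(6 - 8 * math.log(8), rel=1e-12)
        assert bic == pytest.approx(3 * math.log(8) - 8 * math.log(8), rel=1e-12)

    def test_perfect_fit_sentinel(self):
        assert information_criteria(0.0, 5, 2) == (-math.inf, -math.inf)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(1e-6, 1e6), st.integers(2, 40), st.integers(1, 3))
    def test_aic_minus_bic_identity(self, ss, n, k):
        aic, bic = information_criteria(ss, n, k)
        assert aic - bic == pytest.approx(k * (2 - math.log(n)), rel=1e-9,
                                          abs=1e-9)


NOISELESS_CASES = [
    ("bs", {"Sm": 20.0, "alpha": 0.15}, None),
    ("lser", {"Sm": 35.0, "alpha": 0.45}, None),
    ("ln", {"Sm": 14.0, "alpha": 0.5, "Rm": 2.0}, None),
    ("lc", {"Sm": 12.0, "alpha": 0.8, "Rm": 1.0}, None),
    ("ls", {"Sm": 16.0, "alpha": 0.6, "Rm": 2.0}, None),
]


class TestFitModel:
    @pytest.mark.parametrize("name,theta,consts", NOISELESS_CASES)
    def test_noiseless_curves_are_fixed_points(self, name, theta, consts):
        """A histogram generated by the model itself is recovered exactly."""
        h = expected_histogram(name, theta, np.arange(1, 9), consts)
        fit = fit_model(name, h)
        assert fit.ss_residual < 1e-10
        for p, truth in theta.items():
            assert fit.theta[p] == pytest.approx(truth, abs=1e-6)
        assert fit.r_d2 == pytest.approx(1.0, abs=1e-9)

    def test_on_noiseless_recovery(self):
        # choose N_oct self-consistently: N = Sm * sum(4**R) - Sm * sum(8**R)/N,
        # so the expected histogram's own octave total equals the constant used
        octaves = np.arange(1, 6)
        Sm = 0.4
        A, B = np.sum(4.0**octaves), np.sum(8.0**octaves)
        N = (Sm * A + math.sqrt((Sm * A) ** 2 - 4 * Sm * B)) / 2.0
        h = expected_histogram("on", {"Sm": Sm}, octaves,
                               {"N_oct": N, "R_max": octaves.max()})
        assert h.N_oct == pytest.approx(N, rel=1e-12)
        fit = fit_model("on", h)
        assert fit.ss_residual < 1e-10
        assert fit.theta["Sm"] == pytest.approx(Sm, abs=1e-6)

    def test_gs_closed_form(self, hollow_histogram):
        fit = fit_model("gs", hollow_histogram)
        y = hollow_histogram.counts
        assert fit.theta["Sm"] == pytest.approx(y.mean())
        assert fit.ss_residual == pytest.approx(np.sum((y - y.mean()) ** 2))
        assert fit.r_d2 == pytest.approx(0.0, abs=1e-14)

    def test_statistics_are_mutually_consistent(self, hollow_histogram):
        fit = fit_model("lc", hollow_histogram)
        aic, bic = information_criteria(fit.ss_residual, fit.n, fit.k)
        assert (fit.aic, fit.bic) == (aic, bic)
        assert fit.s_star == pytest.approx(
            math.pi * fit.theta["Sm"] / fit.theta["alpha"])

    def test_insufficient_octaves_rejected(self):
        h = OctaveHistogram([1, 2], [5.0, 3.0], "halfopen")
        with pytest.raises(InsufficientDataError):
            fit_model("lc", h)

    def test_refit_from_fit_is_a_fixed_point(self, hollow_histogram):
        fit1 = fit_model("lc", hollow_histogram)
        h2 = OctaveHistogram(hollow_histogram.octaves, fit1.fitted_values,
                             "halfopen")
        fit2 = fit_model("lc", h2)
        for p in fit1.theta:
            assert fit2.theta[p] == pytest.approx(fit1.theta[p], abs=1e-4)

    @pytest.mark.parametrize("c", [0.5, 3.0])
    def test_scale_equivariance(self, hollow_histogram, c):
        """Scaling all counts by c scales Sm by c, leaves alpha and Rm."""
        scaled = OctaveHistogram(
            hollow_histogram.octaves, c * hollow_histogram.counts, "halfopen"
        )
        for name in ("gs", "ln", "lc", "ls"):
            f1 = fit_model(name, hollow_histogram)
            f2 = fit_model(name, scaled)
            assert f2.theta["Sm"] == pytest.approx(c * f1.theta["Sm"], rel=1e-3)
            for p in ("alpha", "Rm"):
                if p in f1.theta:
                    assert f2.theta[p] == pytest.approx(f1.theta[p], rel=1e-2,
                                                        abs=1e-3)

    def test_fractional_counts_accepted(self):
        h = OctaveHistogram([0, 1, 2], [1.5, 1.0, 0.5], "preston_halving")
        fit = fit_model("gs", h)
        assert fit.theta["Sm"] == pytest.approx(1.0)


def _grid_best_ss(name, h, grids):
    from sadoctave import evaluate_model

    best = np.inf
    for theta in grids:
        resid = np.asarray(evaluate_model(name, theta, h.octaves)) - h.counts
        best = min(best, float(np.sum(resid**2)))
    return best


class TestSolverBeatsBruteForce:
    def test_lm_ss_not_worse_than_dense_grid(self, rng):
        """The solver's SS never exceeds a dense brute-force grid search."""
        for _ in range(8):
            octaves = np.arange(1, rng.integers(7, 11))
            counts = rng.uniform(0.5, 30.0, octaves.size)
            h = OctaveHistogram(octaves, counts, "halfopen")
            fit = fit_model("lc", h)
            grids = [
                {"Sm": Sm, "alpha": a, "Rm": Rm}
                for Sm in np.linspace(1.0, 2 * counts.max(), 24)
                for a in np.geomspace(0.05, 5.0, 24)
                for Rm in np.linspace(0.0, octaves.max(), 16)
            ]
            assert fit.ss_residual <= _grid_best_ss("lc", h, grids) + 1e-6
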
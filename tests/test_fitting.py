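"""Least-squares estimation of (B, C1, C2, H) and the admissibility routes."""

import numpy as np
import pytest

from extmr import (
    DigitizationEmulator,
    DSample,
    ExtMRCoefficients,
    FitRoute,
    NoiseModel,
    StressStrainCurve,
    compute_D,
    estimate_B_window,
    fit_cubic,
    fit_D_quadratic,
    fit_pipeline,
    generate_curve,
    map_cubic,
    r_squared,
    strain_brackets,
)
from extmr.errors import (
    DegenerateVarianceError,
    InsufficientDataError,
    NonpositiveInterceptError,
)

from conftest import LAM_C, REFERENCE, random_admissible_coeffs


def normal_equations_polyfit(eps, y, deg):
    """Independent oracle: solve the normal equations X'X a = X'y directly."""
    X = np.vander(np.asarray(eps, float), deg + 1, increasing=True)
    return np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))


def curve_from_cubic(a, eps):
    sigma_ext = a[0] + a[1] * eps + a[2] * eps**2 + a[3] * eps**3
    return StressStrainCurve.from_ext_mooney(eps, sigma_ext)


class TestFitCubic:
    def test_recovers_exact_cubic(self, rng):
        a = np.array([2.0e4, -3.0e5, 1.8e6, 4.0e4])
        eps = np.linspace(0.05, 3.0, 25)
        fit = fit_cubic(curve_from_cubic(a, eps))
        np.testing.assert_allclose(fit.coef, a, rtol=1e-8)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 40))
            eps = np.sort(rng.uniform(0.01, 3.0, n))
            eps += np.arange(n) * 1e-9  # guarantee distinctness
            y = rng.normal(0, 1e5, n)
            curve = StressStrainCurve.from_ext_mooney(eps, y)
            fit = fit_cubic(curve)
            oracle = normal_equations_polyfit(eps, y, 3)
            np.testing.assert_allclose(fit.coef, oracle, rtol=1e-8,
                                       atol=1e-8 * np.abs(oracle).max())

    def test_least_squares_optimality(self, rng):
        """The fitted residual sum of squares beats random perturbations."""
        eps = np.linspace(0.05, 3.0, 30)
        y = 1e4 + 2e5 * eps + rng.normal(0, 1e4, 30)
        curve = StressStrainCurve.from_ext_mooney(eps, y)
        fit = fit_cubic(curve)

        def rss(coef):
            pred = np.polynomial.polynomial.polyval(eps, coef)
            return np.sum((y - pred) ** 2)

        best = rss(fit.coef)
        for _ in range(100):
            perturbed = fit.coef * (1 + rng.normal(0, 1e-3, 4))
            assert rss(perturbed) >= best

    def test_insufficient_points(self):
        curve = StressStrainCurve([0.1, 0.2, 0.3], [1.0, 2.0, 3.0])
        with pytest.raises(InsufficientDataError):
            fit_cubic(curve)


class TestMapCubic:
    def test_hand_solved_brackets(self):
        from extmr.fitting import CubicFit
        fit = CubicFit(a0=0.4655, a1=0.0, a2=0.0, a3=0.0, r_squared=1.0,
                       n_points=10)
        c = map_cubic(fit, LAM_C)
        assert c.b == pytest.approx(1.0)
        assert c.c1 == pytest.approx(0.0, abs=1e-12)
        assert c.c2 == pytest.approx(1.0)
        assert c.h == pytest.approx(0.0, abs=1e-12)

    def test_negative_intercept_is_inadmissible(self):
        from extmr.fitting import CubicFit
        fit = CubicFit(a0=-5.0, a1=1.0, a2=1.0, a3=1.0, r_squared=0.99,
                       n_points=10)
        assert map_cubic(fit, LAM_C) is None

    def test_inverts_bracket_construction(self, rng):
        """map_cubic is the exact inverse of the affine bracket map."""
        from extmr.fitting import CubicFit
        for c in random_admissible_coeffs(rng, 1000):
            a0, a1, a2, a3 = strain_brackets(c)
            fit = CubicFit(a0=a0, a1=a1, a2=a2, a3=a3, r_squared=1.0,
                           n_points=10)
            back = map_cubic(fit, c.lam_c)
            for attr in ("b", "c1", "c2", "h"):
                assert getattr(back, attr) == pytest.approx(
                    getattr(c, attr), rel=1e-10, abs=1e-6)


class TestWindowB:
    def test_recovers_B_from_exact_data(self, rng):
        for c in random_admissible_coeffs(rng, 10):
            curve = generate_curve(c, DigitizationEmulator(
                n_points=60, eps_range=(0.01, 3.0)))
            assert estimate_B_window(curve, 0.5, c.lam_c) == pytest.approx(
                c.b, rel=1e-6)

    def test_constant_curve_intercept(self):
        eps = np.linspace(0.05, 0.4, 10)
        curve = StressStrainCurve.from_ext_mooney(eps, np.full(10, 0.4655))
        assert estimate_B_window(curve, 0.5, LAM_C) == pytest.approx(1.0)

    def test_negative_everywhere_errors(self):
        eps = np.linspace(0.05, 3.0, 20)
        curve = StressStrainCurve.from_ext_mooney(eps, np.full(20, -5.0))
        with pytest.raises(NonpositiveInterceptError):
            estimate_B_window(curve, 0.5, LAM_C)

    def test_sparse_window_errors(self):
        eps = np.array([1.0, 2.0, 2.5, 3.0])
        curve = StressStrainCurve.from_ext_mooney(eps, np.ones(4))
        with pytest.raises(InsufficientDataError):
            estimate_B_window(curve, 0.5, LAM_C)


class TestDStatistic:
    def test_zero_numerator(self):
        eps = np.array([0.2, 0.5, 1.0, 2.0])
        curve = StressStrainCurve.from_ext_mooney(
            eps, np.full(4, 1.0 * (LAM_C - 1.0)))
        d = compute_D(curve, b=1.0, lam_c=LAM_C)
        assert all(s.d_value == pytest.approx(0.0, abs=1e-12) for s in d)

    def test_matches_quadratic_brackets(self, rng):
        """On noise-free forward data, D(eps) is exactly the quadratic
        [C2+C1+H-B] + eps [C1+2H] + eps^2 [H]."""
        for c in random_admissible_coeffs(rng, 10):
            curve = generate_curve(c, DigitizationEmulator(n_points=40))
            d = compute_D(curve, c.b, lam_c=c.lam_c)
            _, a1, a2, a3 = strain_brackets(c)
            for s in d:
                expected = a1 + a2 * s.eps + a3 * s.eps**2
                assert s.d_value == pytest.approx(expected, rel=1e-9,
                                                  abs=1e-6)

    def test_zero_strain_sample_dropped(self):
        eps = np.array([0.0, 0.5, 1.0, 2.0])
        curve = StressStrainCurve.from_ext_mooney(eps, np.ones(4))
        d = compute_D(curve, b=1.0, lam_c=LAM_C)
        assert len(d) == 3
        assert min(s.eps for s in d) == pytest.approx(0.5)


class TestFitDQuadratic:
    def test_all_zero_d(self):
        samples = [DSample(e, 0.0) for e in (0.2, 0.5, 1.0, 2.0)]
        fit = fit_D_quadratic(samples, b=1.0, lam_c=LAM_C)
        c = fit.coefficients
        assert (c.c1, c.h) == (pytest.approx(0.0, abs=1e-12),
                               pytest.approx(0.0, abs=1e-12))
        assert c.c2 == pytest.approx(1.0)
        assert fit.route is FitRoute.WINDOW_B_PLUS_D

    def test_reference_noise_free_recovery(self, reference_coeffs):
        curve = generate_curve(reference_coeffs, DigitizationEmulator())
        d = compute_D(curve, reference_coeffs.b)
        fit = fit_D_quadratic(d, reference_coeffs.b)
        for attr in ("c1", "c2", "h"):
            assert getattr(fit.coefficients, attr) == pytest.approx(
                REFERENCE[attr], rel=1e-6)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            eps = np.sort(rng.uniform(0.05, 3.0, 20))
            d_vals = rng.normal(0, 1e5, 20)
            samples = [DSample(float(e), float(v))
                       for e, v in zip(eps, d_vals)]
            fit = fit_D_quadratic(samples, b=1.0e4)
            oracle = normal_equations_polyfit(eps, d_vals, 2)
            h = oracle[2]
            c1 = oracle[1] - 2 * h
            c2 = oracle[0] - c1 - h + 1.0e4
            assert fit.coefficients.h == pytest.approx(h, rel=1e-8)
            assert fit.coefficients.c1 == pytest.approx(c1, rel=1e-8)
            assert fit.coefficients.c2 == pytest.approx(c2, rel=1e-8)

    def test_noise_calibrated_accuracy(self, reference_coeffs):
        """Median relative error of C1, C2, H over 200 replicates at 1%
        multiplicative noise, with B fixed to truth. Thresholds frozen from
        a calibration run of this exact protocol (C1, C2 medians near 1%;
        H near 11% — it multiplies the smallest term of a curve spanning
        ~1e7 Pa)."""
        errs = {"c1": [], "c2": [], "h": []}
        for rep in range(200):
            curve = generate_curve(
                reference_coeffs, DigitizationEmulator(),
                NoiseModel("multiplicative_gaussian", 0.01, seed=1234 + rep))
            d = compute_D(curve, reference_coeffs.b)
            fit = fit_D_quadratic(d, reference_coeffs.b)
            for attr in errs:
                errs[attr].append(
                    abs(getattr(fit.coefficients, attr) - REFERENCE[attr])
                    / abs(REFERENCE[attr]))
        assert np.median(errs["c1"]) < 0.05
        assert np.median(errs["c2"]) < 0.05
        assert np.median(errs["h"]) < 0.2


class TestFitPipeline:
    def test_noise_free_exact_recovery(self, rng):
        """The model class is closed under its own fitting: noise-free
        forward data of any admissible coefficient set is recovered."""
        for c in random_admissible_coeffs(rng, 20):
            curve = generate_curve(c, DigitizationEmulator(n_points=20))
            fit = fit_pipeline(curve, lam_c=c.lam_c)
            for attr in ("b", "c1", "c2", "h"):
                assert getattr(fit.coefficients, attr) == pytest.approx(
                    getattr(c, attr), rel=1e-6, abs=1e-4)

    def test_reference_round_trip_direct_route(self, reference_curve):
        fit = fit_pipeline(reference_curve)
        assert fit.route is FitRoute.DIRECT_CUBIC
        for attr in ("b", "c1", "c2", "h"):
            assert getattr(fit.coefficients, attr) == pytest.approx(
                REFERENCE[attr], rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_window_route_on_negative_intercept(self, window_route_curve):
        fit = fit_pipeline(window_route_curve)
        assert fit.route is FitRoute.WINDOW_B_PLUS_D
        assert fit.coefficients.b > 0
        assert fit.window_eps_max == pytest.approx(0.5)

    def test_routes_agree_on_noise_free_data(self, reference_coeffs):
        """When both routes are applicable to noise-free data they return
        the same coefficients."""
        curve = generate_curve(reference_coeffs, DigitizationEmulator())
        direct = fit_pipeline(curve)
        b = estimate_B_window(curve, 0.5)
        via_d = fit_D_quadratic(compute_D(curve, b), b)
        for attr in ("b", "c1", "c2", "h"):
            assert getattr(direct.coefficients, attr) == pytest.approx(
                getattr(via_d.coefficients, attr), rel=1e-6)

    def test_single_sample_curve_errors(self):
        curve = StressStrainCurve([0.1], [1.0])
        with pytest.raises(InsufficientDataError):
            fit_pipeline(curve)

    def test_unbiased_under_noise(self):
        """Full-pipeline estimates under 1% multiplicative noise are
        unbiased within 3 Monte-Carlo standard errors at a coefficient set
        whose intercept is well resolved (midshaft-scale B)."""
        c = ExtMRCoefficients(b=1.05e5, c1=1.0e6, c2=-2.3e6, h=5.2e4)
        ests = {k: [] for k in ("b", "c1", "c2", "h")}
        for rep in range(200):
            curve = generate_curve(
                c, DigitizationEmulator(),
                NoiseModel("multiplicative_gaussian", 0.01, seed=5000 + rep))
            fit = fit_pipeline(curve)
            for k in ests:
                ests[k].append(getattr(fit.coefficients, k))
        for k, vals in ests.items():
            vals = np.array(vals)
            se = vals.std(ddof=1) / np.sqrt(vals.size)
            assert abs(vals.mean() - getattr(c, k)) < 3 * se, k

    def test_raw_cubic_estimates_unbiased(self, reference_coeffs):
        """The unconstrained least-squares cubic coefficients themselves
        are unbiased at the reference set (no admissibility truncation)."""
        true = np.array(strain_brackets(reference_coeffs))
        coefs = []
        for rep in range(200):
            curve = generate_curve(
                reference_coeffs, DigitizationEmulator(),
                NoiseModel("multiplicative_gaussian", 0.01, seed=9000 + rep))
            coefs.append(fit_cubic(curve).coef)
        coefs = np.array(coefs)
        for i in range(4):
            se = coefs[:, i].std(ddof=1) / np.sqrt(coefs.shape[0])
            assert abs(coefs[:, i].mean() - true[i]) < 3 * se


class TestRSquared:
    def test_reference_points(self):
        obs = np.array([0.0, 1.0, 2.0])
        assert r_squared(obs, obs) == pytest.approx(1.0)
        assert r_squared(obs, np.full(3, obs.mean())) == pytest.approx(0.0)
        assert r_squared(obs, np.array([0.0, 1.0, 1.0])) == pytest.approx(0.5)

    def test_degenerate_variance(self):
        with pytest.raises(DegenerateVarianceError):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_bounds_and_exactness(self, rng):
        for _ in range(20):
            obs = rng.normal(0, 1, 30)
            pred = obs + rng.normal(0, 0.5, 30)
            r2 = r_squared(obs, pred)
            assert r2 <= 1.0
            assert (r2 == 1.0) == bool(np.all(obs == pred))
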
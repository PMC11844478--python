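"""Constrained spline / polynomial reconstruction from pairwise distances."""

import numpy as np
import pytest
from scipy import linalg, optimize

import genarc as g
from genarc.errors import (
    EmptyFitError,
    InsufficientSupportError,
    TransformDomainError,
    UnderdeterminedFitError,
)
from genarc.fitting import (
    _constraint_matrix,
    default_knots,
    spline_design,
)

from .conftest import make_distances


def centered_match(curve, fn, grid):
    """Max deviation between curve and fn after removing the mean offset."""
    yv = g.evaluate_curve(curve, grid)
    tv = fn(grid)
    return np.max(np.abs((yv - yv.mean()) - (tv - tv.mean())))


class TestKnotsAndDesign:
    @pytest.mark.parametrize(
        "span,expected",
        [((0.0, 3.0), (1.0, 2.0)), ((15.0, 45.0), (25.0, 35.0))],
    )
    def test_default_knots_at_thirds(self, span, expected):
        xs = np.linspace(*span, 8)
        assert default_knots(xs) == pytest.approx(expected)

    def test_default_knots_on_simulated_bin_medians(self):
        rng = np.random.default_rng(11)
        values = rng.normal(27, 5, size=6_000)
        table = g.assign_bins(values, g.build_scheme(g.BMI_30_WIDTHS),
                              min_count=1)
        reps = table.x_rep
        i, j = default_knots(reps)
        lo, hi = reps.min(), reps.max()
        assert i == pytest.approx(lo + (hi - lo) / 3)
        assert j == pytest.approx(lo + 2 * (hi - lo) / 3)

    def test_too_few_distinct_points(self):
        with pytest.raises(InsufficientSupportError):
            default_knots([1.0, 1.0, 2.0, 3.0])

    def test_design_row_within_segment_cancels_intercept(self):
        row = spline_design([(0.2, 0.8)], knots=(1.5, 2.5))[0]
        assert row[3] == 0.0  # b4 entries cancel
        assert row[0:3].any()  # cubic/quadratic/linear terms remain
        assert (row[4:] == 0).all()

    def test_design_row_straddling_segments(self):
        row = spline_design([(1.0, 2.0)], knots=(1.5, 2.5))[0]
        # f2(2) − f1(1) = 8b5 + 4b6 + 2b7 + b8 − (b1 + b2 + b3 + b4)
        np.testing.assert_allclose(
            row, [-1, -1, -1, -1, 8, 4, 2, 1, 0, 0, 0, 0]
        )

    def test_design_row_touching_outer_segments(self):
        row = spline_design([(0.5, 3.0)], knots=(1.5, 2.5))[0]
        assert row[0:4].any() and row[8:12].any()
        assert (row[4:8] == 0).all()


class TestSplineFit:
    def test_exact_recovery_of_global_cubic(self):
        fn = lambda x: x ** 3 - 2 * x
        xs = np.linspace(0, 3, 10)
        curve, report = g.fit_spline(make_distances(fn, xs))
        assert report.objective_value <= 1e-16 * max(1.0, np.var(xs))
        assert centered_match(curve, fn, np.linspace(0, 3, 101)) < 1e-6

    def test_knot_smoothness_of_fitted_curve(self):
        fn = lambda x: np.sin(x)  # not representable: generic noisy-ish fit
        xs = np.linspace(0, 3, 12)
        curve, _ = g.fit_spline(make_distances(fn, xs))
        for t in curve.knots:
            for order in (0, 1, 2):
                left = np.polyval(
                    np.polyder(
                        np.asarray(curve.coefficients[0:4])
                        if t == curve.knots[0]
                        else np.asarray(curve.coefficients[4:8]),
                        order,
                    ),
                    t - curve.x0,
                )
                right = np.polyval(
                    np.polyder(
                        np.asarray(curve.coefficients[4:8])
                        if t == curve.knots[0]
                        else np.asarray(curve.coefficients[8:12]),
                        order,
                    ),
                    t - curve.x0,
                )
                assert left == pytest.approx(right, abs=1e-8)

    def test_zero_distances_give_constant_anchored_curve(self):
        xs = np.linspace(0, 3, 10)
        curve, _ = g.fit_spline(make_distances(lambda x: 5.0, xs))
        yv = g.evaluate_curve(curve, np.linspace(0, 3, 50))
        np.testing.assert_allclose(yv, 0.0, atol=1e-10)

    def test_linear_data_has_negligible_curvature(self):
        xs = np.linspace(0, 3, 10)
        curve, _ = g.fit_spline(make_distances(lambda x: 2 * x, xs))
        f2 = curve.derivative(np.linspace(0, 3, 101), 2)
        assert np.max(np.abs(f2)) <= 1e-6

    def test_shift_invariance_of_generating_function(self):
        fn = lambda x: x ** 3 - x
        xs = np.linspace(0, 3, 9)
        c1, _ = g.fit_spline(make_distances(fn, xs))
        c2, _ = g.fit_spline(make_distances(lambda x: fn(x) + 17.3, xs))
        grid = np.linspace(0, 3, 60)
        np.testing.assert_allclose(
            g.evaluate_curve(c1, grid), g.evaluate_curve(c2, grid), atol=1e-8
        )

    def test_empty_segment_falls_back_to_polynomial(self):
        fn = lambda x: x ** 3 - 2 * x
        xs = np.linspace(1.6, 2.4, 8)  # all inside the middle knot interval
        with pytest.warns(UserWarning, match="falling back"):
            curve, report = g.fit_spline(make_distances(fn, xs),
                                         knots=(1.5, 2.5))
        assert report.fell_back_to_polynomial
        assert curve.kind == "polynomial"
        assert report.objective_value <= 1e-16
        assert centered_match(curve, fn, np.linspace(1.6, 2.4, 40)) < 1e-6

    def test_orientation_flag_flips_curve(self):
        fn = lambda x: x ** 2
        xs = np.linspace(0, 3, 9)
        cased, _ = g.fit_spline(make_distances(fn, xs, "case_minus_control"))
        ctrl, _ = g.fit_spline(
            make_distances(fn, xs, "control_minus_case"),
            dy_sign="control_minus_case",
        )
        grid = np.linspace(0, 3, 40)
        np.testing.assert_allclose(
            g.evaluate_curve(cased, grid), g.evaluate_curve(ctrl, grid),
            atol=1e-9,
        )

    def test_all_excluded_raises_empty_fit(self):
        dists = make_distances(lambda x: x, np.linspace(0, 3, 8))
        dead = [
            type(d)(**{**d.__dict__, "included": False,
                       "exclusion_reason": "out_of_bounds"})
            for d in dists
        ]
        with pytest.raises(EmptyFitError):
            g.fit_spline(dead)

    def test_too_few_distinct_points_is_underdetermined(self):
        xs = np.linspace(0, 3, 5)  # 5 points: spline rank 4 < 5
        with pytest.raises(UnderdeterminedFitError):
            g.fit_spline(make_distances(lambda x: x ** 2, xs))

    def test_constrained_solution_matches_brute_force_optimizer(self):
        """Oracle: numerical minimisation of the same objective, restarts."""
        rng = np.random.default_rng(5)
        xs = np.linspace(0, 3, 8)
        dists = make_distances(lambda x: np.cos(2 * x), xs)
        curve, report = g.fit_spline(dists)
        knots, x0 = curve.knots, curve.x0
        pairs = [(d.x_case, d.x_control) for d in dists]
        target = -np.array([d.dy for d in dists])
        A = spline_design(pairs, knots, x0)
        N = linalg.null_space(_constraint_matrix(knots, x0))

        def objective(z):
            r = target - A @ (N @ z)
            return r @ r

        best = np.inf
        for _ in range(8):
            res = optimize.minimize(objective, rng.normal(size=N.shape[1]),
                                    method="Powell",
                                    options={"maxiter": 40_000,
                                             "xtol": 1e-12, "ftol": 1e-14})
            best = min(best, res.fun)
        assert report.objective_value <= best + 1e-6


class TestPolynomialFit:
    def test_quadratic_coefficients_recovered(self):
        xs = np.linspace(0, 3, 9)
        curve, _ = g.fit_polynomial(make_distances(lambda x: x * x, xs))
        # coefficients are in powers of (x − x0): quadratic term must be 1
        assert curve.coefficients[-3] == pytest.approx(1.0, abs=1e-8)
        assert np.max(np.abs(curve.coefficients[:3])) <= 1e-6

    def test_zero_distances_constant(self):
        xs = np.linspace(0, 3, 9)
        curve, _ = g.fit_polynomial(make_distances(lambda x: 3.0, xs))
        np.testing.assert_allclose(
            g.evaluate_curve(curve, np.linspace(0, 3, 30)), 0.0, atol=1e-10
        )

    def test_degree5_exact_recovery(self):
        fn = lambda x: 0.1 * x ** 5 - x ** 3 + x
        xs = np.linspace(-1.5, 1.5, 10)
        curve, report = g.fit_polynomial(make_distances(fn, xs))
        assert report.objective_value <= 1e-12
        assert centered_match(curve, fn, np.linspace(-1.5, 1.5, 60)) < 1e-6

    def test_cross_estimator_curvature_agreement(self):
        """Spline and polynomial agree on convexity for a U-shaped truth."""
        fn = lambda x: (x - 1.5) ** 2
        xs = np.linspace(0, 3, 10)
        dists = make_distances(fn, xs)
        spline_curve, _ = g.fit_spline(dists)
        poly_curve, _ = g.fit_polynomial(dists)
        grid = np.linspace(0.75, 2.25, 41)  # central half
        assert np.all(spline_curve.derivative(grid, 2) > 0)
        assert np.all(poly_curve.derivative(grid, 2) > 0)


class TestEvaluate:
    def test_continuity_at_knots(self):
        xs = np.linspace(0, 3, 11)
        curve, _ = g.fit_spline(make_distances(lambda x: np.exp(x), xs))
        for t in curve.knots:
            below = g.evaluate_curve(curve, np.nextafter(t, -np.inf))
            above = g.evaluate_curve(curve, np.nextafter(t, np.inf))
            assert below == pytest.approx(above, abs=1e-10)

    def test_out_of_domain_rejected(self):
        curve, _ = g.fit_spline(
            make_distances(lambda x: x, np.linspace(0, 3, 8))
        )
        with pytest.raises(TransformDomainError):
            g.evaluate_curve(curve, 3.5)

    def test_anchor_centers_curve_on_pair_endpoints(self):
        xs = np.linspace(0, 3, 9)
        curve, _ = g.fit_spline(make_distances(lambda x: x ** 2, xs))
        assert np.mean(g.evaluate_curve(curve, xs)) == pytest.approx(
            0.0, abs=1e-9
        )
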
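import math

import numpy as np
import pytest

from nutrigeo.landscape import (
    DegenerateSplineError,
    DesignMatrixError,
    LackOfFit,
    NoPureErrorError,
    ResponseSurfaceFit,
    fit_rsm,
    fmn_region,
    lack_of_fit,
    maximize_surface,
    tps_landscape,
)

SURVIVAL_COEFFS = (0.0, 0.225, 7.120, 0.0, -0.058, -0.079)


def _replicated(points, reps=5):
    return np.repeat(points, reps, axis=0)


class TestFitRsm:
    def test_noise_free_linear_drops_quadratics(self, rmt_points):
        pts = _replicated(rmt_points)
        y = 2.0 + 0.5 * pts[:, 0] + 1.2 * pts[:, 1] + 0.01 * pts[:, 0] * pts[:, 1]
        rng = np.random.default_rng(0)
        fit = fit_rsm(pts, y + rng.normal(0, 1e-10, len(y)))
        assert set(fit.dropped_terms) == {"P2", "C2"}
        assert fit.coefficients["P"] == pytest.approx(0.5, abs=1e-6)
        assert fit.coefficients["C"] == pytest.approx(1.2, abs=1e-6)
        assert fit.coefficients["PC"] == pytest.approx(0.01, abs=1e-8)

    def test_noise_free_full_quadratic_r2_one(self, rmt_points):
        pts = _replicated(rmt_points)
        y = (
            1.0 + 0.3 * pts[:, 0] + 0.8 * pts[:, 1]
            - 0.01 * pts[:, 0] ** 2 - 0.02 * pts[:, 1] ** 2
            + 0.005 * pts[:, 0] * pts[:, 1]
        )
        fit = fit_rsm(pts, y)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert not fit.dropped_terms

    def test_too_few_design_points(self):
        pts = np.repeat(np.array([[10.0, 10.0], [40.0, 40.0], [80.0, 10.0]]), 3, axis=0)
        with pytest.raises(DesignMatrixError):
            fit_rsm(pts, np.arange(len(pts), dtype=float))

    def test_coefficient_recovery_unbiased(self, rmt_points):
        # 200 replicates of the 35-colony design: mean estimates within 2 SE
        truth = dict(const=10.0, P=0.5, C=1.3, PC=0.009)
        pts = _replicated(rmt_points)
        ests = {k: [] for k in truth}
        rng = np.random.default_rng(1)
        for _ in range(200):
            y = (
                truth["const"] + truth["P"] * pts[:, 0] + truth["C"] * pts[:, 1]
                + truth["PC"] * pts[:, 0] * pts[:, 1]
                + rng.normal(0, 8.0, len(pts))
            )
            fit = fit_rsm(pts, y, with_lack_of_fit=False)
            for k in truth:
                ests[k].append(fit.coefficients.get(k, 0.0))
        for k, v in truth.items():
            mean = np.mean(ests[k])
            se = np.std(ests[k], ddof=1) / math.sqrt(len(ests[k]))
            assert abs(mean - v) < 2 * se + 1e-12, k

    def test_refit_never_increases_r2(self, rmt_points):
        pts = _replicated(rmt_points)
        rng = np.random.default_rng(2)
        for _ in range(10):
            y = 5 + 0.2 * pts[:, 0] + rng.normal(0, 5, len(pts))
            fit_full = fit_rsm(pts, y, alpha=1.0 - 1e-12, with_lack_of_fit=False)
            fit_pruned = fit_rsm(pts, y, alpha=0.05, with_lack_of_fit=False)
            assert fit_pruned.r_squared <= fit_full.r_squared + 1e-12

    def test_order_invariance(self, rmt_points):
        pts = _replicated(rmt_points)
        rng = np.random.default_rng(3)
        y = 5 + 0.4 * pts[:, 0] + 0.9 * pts[:, 1] + rng.normal(0, 4, len(pts))
        perm = rng.permutation(len(y))
        a = fit_rsm(pts, y)
        b = fit_rsm(pts[perm], y[perm])
        for k in a.coefficients:
            assert a.coefficients[k] == pytest.approx(b.coefficients[k], rel=1e-9)


class TestLackOfFit:
    def _linear_fit(self, b0, bP, bC):
        return ResponseSurfaceFit(
            response_name="r",
            coefficients={"const": b0, "P": bP, "C": bC},
            se={}, t={}, p={}, overall_p=0.0, r_squared=0.0,
            dropped_terms=[], max_composition=(0, 0, 100), max_value=0.0,
        )

    def test_hand_computed_instance(self):
        # 3 design points, 2 reps each, linear surface y = x (C ignored)
        pts = np.array([[0, 0], [1, 0], [2, 0]] * 2, dtype=float)
        y = np.array([0.0, 1.1, 1.9, 0.2, 0.9, 2.1])
        fit = self._linear_fit(0.0, 1.0, 0.0)
        # by hand: group means 0.1, 1.0, 2.0; predictions 0, 1, 2
        # SS_pure = sum within-group squares = 0.02 + 0.02 + 0.02
        # SS_lof = 2*(0.1-0)^2 + 0 + 0 = 0.02; df_lof = 3-3 = 0 -> error
        with pytest.raises(NoPureErrorError):
            lack_of_fit(fit, pts, y)
        # with an intercept-plus-P model only (2 params), df_lof = 1
        fit2 = ResponseSurfaceFit(
            response_name="r", coefficients={"const": 0.0, "P": 1.0},
            se={}, t={}, p={}, overall_p=0.0, r_squared=0.0,
            dropped_terms=[], max_composition=(0, 0, 100), max_value=0.0,
        )
        res = lack_of_fit(fit2, pts, y)
        ss_pure = 0.02 + 0.02 + 0.02
        ss_lof = 2 * 0.1**2
        f_hand = (ss_lof / 1) / (ss_pure / 3)
        assert res.F == pytest.approx(f_hand, rel=1e-9)
        assert (res.df_lof, res.df_pure) == (1, 3)

    def test_means_on_surface_give_p_one(self):
        pts = np.array([[0, 0], [1, 0], [2, 0], [3, 0]] * 2, dtype=float)
        y = 2.0 + 3.0 * pts[:, 0] + np.tile([0.5, -0.5], 4)[: len(pts)]
        # make replicate pairs symmetric around the line so means sit on it
        y = np.concatenate([2.0 + 3.0 * pts[:4, 0] + 0.5, 2.0 + 3.0 * pts[:4, 0] - 0.5])
        fit = self._linear_fit(2.0, 3.0, 0.0)
        res = lack_of_fit(fit, pts, y)
        assert res.ss_lof == pytest.approx(0.0, abs=1e-18)
        assert res.p == pytest.approx(1.0)

    def test_unreplicated_rejected(self):
        pts = np.array([[0, 0], [1, 0], [2, 0]], dtype=float)
        with pytest.raises(NoPureErrorError):
            lack_of_fit(self._linear_fit(0, 1, 0), pts, pts[:, 0])

    def test_df_sum_to_residual(self, rmt_points):
        pts = _replicated(rmt_points)
        rng = np.random.default_rng(4)
        y = 5 + 0.3 * pts[:, 0] + rng.normal(0, 3, len(pts))
        fit = fit_rsm(pts, y)
        lof = fit.lack_of_fit
        assert lof.df_lof + lof.df_pure == len(y) - len(fit.coefficients)
        assert 0.0 <= lof.p <= 1.0


class TestMaximizeSurface:
    def test_survival_surface_on_protein_free_edge(self):
        (p, c, l), val = maximize_surface(SURVIVAL_COEFFS)
        assert p == 0.0
        assert c == pytest.approx(7.120 / (2 * 0.058), rel=1e-9)  # 61.379
        assert l == pytest.approx(100.0 - c)

    def test_increasing_surface_hits_hypotenuse(self):
        (p, c, l), _ = maximize_surface((0.0, 1.0, 1.0, 0.0, 0.0, 0.0))
        assert p + c == pytest.approx(100.0)
        assert l == pytest.approx(0.0, abs=1e-9)

    def test_interior_maximum(self):
        # concave paraboloid centered at (30, 40)
        coeffs = (0.0, 2 * 0.01 * 30, 2 * 0.01 * 40, -0.01, -0.01, 0.0)
        (p, c, l), _ = maximize_surface(coeffs)
        assert (p, c) == pytest.approx((30.0, 40.0), rel=1e-9)

    def test_brute_force_grid_agreement(self):
        # random quadratics vs exhaustive 0.1%-step simplex evaluation
        step = 0.1
        axis = np.arange(0.0, 100.0 + step / 2, step)
        P, C = np.meshgrid(axis, axis)
        mask = P + C <= 100.0 + 1e-9
        Pm, Cm = P[mask], C[mask]
        rng = np.random.default_rng(5)
        for _ in range(150):
            b = rng.normal(0, [5, 1, 1, 0.02, 0.02, 0.02])
            vals = (
                b[0] + b[1] * Pm + b[2] * Cm
                + b[3] * Pm**2 + b[4] * Cm**2 + b[5] * Pm * Cm
            )
            (p, c, l), v = maximize_surface(tuple(b))
            assert v >= vals.max() - 1e-6
            i = vals.argmax()
            assert math.hypot(p - Pm[i], c - Cm[i]) <= step * math.sqrt(2) + 1e-9

    def test_hull_restriction(self):
        # increasing in C: full simplex peaks at C=100, the design hull at 80
        (p, c, l), _ = maximize_surface((0, 0, 1, 0, 0, 0), domain=(10.0, 80.0))
        assert c == pytest.approx(80.0)
        assert p == pytest.approx(10.0)


class TestTpsLandscape:
    def test_interpolates_design_means_at_small_lambda(self, rmt_points):
        rng = np.random.default_rng(6)
        pts = _replicated(rmt_points)
        y = 10 + 0.5 * pts[:, 0] + rng.normal(0, 2, len(pts))
        grid = tps_landscape(pts, y, lam=1e-9, grid_resolution=1.0)
        uniq = np.unique(pts, axis=0)
        from scipy.interpolate import RBFInterpolator

        means = np.array([y[(pts == u).all(axis=1)].mean() for u in uniq])
        pred = RBFInterpolator(
            uniq, means, kernel="thin_plate_spline", smoothing=1e-9
        )(uniq)
        assert np.abs(pred - means).max() < 1e-6 * max(1.0, np.abs(means).max())

    def test_constant_responses_constant_surface(self, rmt_points):
        grid = tps_landscape(rmt_points, np.full(len(rmt_points), 7.0), lam=0.001)
        vals = grid.values[grid.mask]
        assert vals == pytest.approx(np.full(vals.shape, 7.0), abs=1e-6)

    def test_against_hand_coded_radial_basis_solve(self):
        # independent TPS oracle: solve [[K + lam*I, P], [P.T, 0]] directly
        pts = np.array([[10.0, 10.0], [60.0, 20.0], [20.0, 60.0], [40.0, 40.0]])
        y = np.array([1.0, 3.0, -2.0, 5.0])
        lam = 1e-9

        def phi(r):
            with np.errstate(divide="ignore", invalid="ignore"):
                return np.where(r > 0, r**2 * np.log(r), 0.0)

        n = len(pts)
        K = phi(np.linalg.norm(pts[:, None] - pts[None, :], axis=2))
        P = np.column_stack([np.ones(n), pts])
        A = np.block([[K + lam * np.eye(n), P], [P.T, np.zeros((3, 3))]])
        sol = np.linalg.solve(A, np.concatenate([y, np.zeros(3)]))
        w, a = sol[:n], sol[n:]
        query = np.array([[25.0, 25.0], [50.0, 30.0], [12.0, 48.0]])
        r = np.linalg.norm(query[:, None] - pts[None, :], axis=2)
        oracle = phi(r) @ w + a[0] + query @ a[1:]

        from scipy.interpolate import RBFInterpolator

        ours = RBFInterpolator(
            pts, y, kernel="thin_plate_spline", smoothing=lam
        )(query)
        assert np.abs(ours - oracle).max() < 1e-8

    def test_collinear_points_rejected(self):
        pts = np.array([[0.0, 0.0], [10.0, 10.0], [20.0, 20.0]])
        with pytest.raises(DegenerateSplineError):
            tps_landscape(pts, np.array([1.0, 2.0, 3.0]))

    def test_zero_lambda_rejected(self, rmt_points):
        with pytest.raises(ValueError):
            tps_landscape(rmt_points, np.arange(7.0), lam=0.0)


class TestFmnRegion:
    def _grid(self, rmt_points):
        y = 100 - ((rmt_points[:, 0] - 40) ** 2 + (rmt_points[:, 1] - 40) ** 2) / 50
        return tps_landscape(rmt_points, y, lam=0.001)

    def test_zero_quantile_covers_simplex(self, rmt_points):
        region = fmn_region(self._grid(rmt_points), q=0.0)
        assert region.area_pct == pytest.approx(100.0)

    def test_high_quantile_contains_argmax(self, rmt_points):
        grid = self._grid(rmt_points)
        region = fmn_region(grid, q=0.9)
        flat = np.where(grid.mask, grid.values, -np.inf)
        i, j = np.unravel_index(np.nanargmax(flat), flat.shape)
        assert region.mask[i, j]
        assert 0.0 < region.area_pct <= 100.0

    def test_area_double_counting_agreement(self, rmt_points):
        grid = self._grid(rmt_points)
        region = fmn_region(grid, q=0.7)
        # recount: cell count ratio vs mean of the indicator over the mask
        indicator = region.mask[grid.mask].astype(float)
        assert region.area_pct == pytest.approx(100.0 * indicator.mean(), rel=1e-12)
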
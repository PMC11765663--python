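import numpy as np
import pytest

from fuzzycyl import (
    CylinderGeometry,
    FitConfig,
    els_fit,
    em_optimize,
    fuzzy_fit_loop,
    make_fuzzy_cloud,
    ransac_els_fit,
    sample_replicate,
)
from fuzzycyl.errors import FitFailureError


def exact_cylinder_points(r=1.0, n_ang=12, n_z=3, z_half=1.0):
    # keep the cylinder longer than wide: the PCA axis initialization
    # assumes the dominant variance direction is the axis
    ang = np.linspace(0, 2 * np.pi, n_ang, endpoint=False)
    zs = np.linspace(-z_half, z_half, n_z)
    pts = np.array([[r * np.cos(a), r * np.sin(a), z] for z in zs for a in ang])
    return pts


class TestElsFit:
    def test_exact_recovery_zero_residual_fixed_point(self):
        pts = exact_cylinder_points(r=1.0)
        res = els_fit(pts)
        assert abs(res.geometry.radius - 1.0) < 1e-8
        assert np.abs(res.geometry.axis @ [0, 0, 1]) > 1 - 1e-8
        assert res.objective_value < 1e-10  # residual RMS

    def test_small_noise_small_parameter_error(self):
        rng = np.random.default_rng(0)
        pts = exact_cylinder_points(r=1.0, n_ang=40, n_z=10, z_half=2.0)
        noisy = pts + 1e-4 * rng.standard_normal(pts.shape)
        res = els_fit(noisy)
        assert abs(res.geometry.radius - 1.0) < 1e-3

    def test_too_few_points(self):
        with pytest.raises(FitFailureError):
            els_fit(np.zeros((5, 3)))

    def test_rigid_motion_equivariance(self):
        rng = np.random.default_rng(1)
        pts = exact_cylinder_points(r=0.7, n_ang=24, n_z=6)
        pts += 1e-3 * rng.standard_normal(pts.shape)
        res = els_fit(pts)
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]
        shift = np.array([0.5, -2.0, 1.0])
        res_t = els_fit(pts @ Q.T + shift)
        assert np.isclose(res_t.geometry.radius, res.geometry.radius, atol=1e-6)
        assert np.abs(res_t.geometry.axis @ (Q @ res.geometry.axis)) > 1 - 1e-6
        # transformed original axis point lies on the new fitted axis line
        p = Q @ res.geometry.center + shift
        d = p - res_t.geometry.center
        v = res_t.geometry.axis
        assert np.linalg.norm(d - (d @ v) * v) < 1e-6


class TestRansac:
    def test_clean_data_agrees_with_els(self):
        pts = exact_cylinder_points(r=1.0, n_ang=20, n_z=5)
        rng = np.random.default_rng(2)
        a = els_fit(pts)
        b = ransac_els_fit(pts, rng=rng)
        assert np.isclose(a.geometry.radius, b.geometry.radius, atol=1e-6)
        assert np.abs(a.geometry.axis @ b.geometry.axis) > 1 - 1e-6
        assert b.method == "RELS"

    def test_outlier_robustness(self):
        rng = np.random.default_rng(3)
        pts = exact_cylinder_points(r=1.0, n_ang=30, n_z=6)
        pts = pts + 5e-3 * rng.standard_normal(pts.shape)
        n_out = int(0.2 * len(pts))
        outliers = 10.0 * rng.standard_normal((n_out, 3))
        data = np.vstack([pts, outliers])
        els_err = abs(els_fit(data).geometry.radius - 1.0)
        ransac_err = abs(ransac_els_fit(data, rng=np.random.default_rng(4)).geometry.radius - 1.0)
        assert ransac_err < els_err

    def test_fewer_points_than_subset(self):
        with pytest.raises(FitFailureError):
            ransac_els_fit(np.zeros((8, 3)), rng=np.random.default_rng(0))


class TestEmOptimize:
    def test_descent_never_worse_than_init(self, truth, fuzzy_50m, scan_50m):
        points, ids, scanners = scan_50m
        pts, rep_ids = sample_replicate(fuzzy_50m, 77)
        fc = make_fuzzy_cloud(pts, rep_ids, scanners, truth)
        init = els_fit(pts).geometry
        res = em_optimize(fc, init, t=200)
        assert res.objective_value <= 1.0 + 1e-12

    def test_near_stationary_at_truth_noiseless(self, truth, scan_50m):
        points, ids, scanners = scan_50m
        fc = make_fuzzy_cloud(points, ids, scanners, truth)
        res = em_optimize(fc, truth, t=1000)
        # envelope discretization displaces the optimum only slightly
        assert abs(res.geometry.radius - truth.radius) / truth.radius < 5e-3

    def test_recovers_against_perturbed_init(self, truth, scan_50m):
        points, ids, scanners = scan_50m
        fc = make_fuzzy_cloud(points, ids, scanners, truth)
        init = truth.replace(radius=truth.radius * 1.15)
        res = em_optimize(fc, init, t=500)
        assert abs(res.geometry.radius - truth.radius) < abs(init.radius - truth.radius)
        assert res.objective_value < 1.0


class TestCurvatureBias:
    def test_envelope_removes_curvature_inflation_isotropic(self):
        """On a full ring with isotropic homoscedastic noise, least squares
        overestimates the radius by ~sigma^2/(2 r) (curvature bias).  The
        tangent-line envelope objective does not inflate the radius; it
        overshoots into a negative bias of comparable (bounded) magnitude."""
        from fuzzycyl.fuzzy import FuzzyPointCloud, GaussianPoint

        truth = CylinderGeometry(radius=0.05, azimuth=0.0, elevation=np.pi / 2, length=0.25)
        rng = np.random.default_rng(0)
        n, sig = 120, 5e-3
        ang = rng.uniform(0, 2 * np.pi, n)
        z = rng.uniform(-0.125, 0.125, n)
        base = np.column_stack([0.05 * np.cos(ang), 0.05 * np.sin(ang), z])
        els_errs, em_errs = [], []
        for k in range(25):
            rk = np.random.default_rng(100 + k)
            pts = base + sig * rk.standard_normal((n, 3))
            fc = FuzzyPointCloud([GaussianPoint(p, sig**2 * np.eye(3)) for p in pts], truth)
            init = els_fit(pts).geometry
            em = em_optimize(fc, init, t=300)
            els_errs.append(init.radius - 0.05)
            em_errs.append(em.geometry.radius - 0.05)
        els_bias = np.mean(els_errs)
        em_bias = np.mean(em_errs)
        assert els_bias > 0  # least squares inflates the radius
        # ~ sigma^2 / (2 r) = 0.25 mm expected inflation
        assert 0.1e-3 < els_bias < 0.5e-3
        assert em_bias < els_bias  # no inflation under the envelope objective
        assert abs(em_bias) < 3 * els_bias  # overshoot bounded


class TestFuzzyFitLoop:
    def test_noiseless_exits_after_one_update(self, truth, scan_50m):
        points, ids, scanners = scan_50m
        res = fuzzy_fit_loop(points, ids, scanners, config=FitConfig(tangent_lines=1000))
        assert res.converged
        assert res.outer_iterations == 1
        assert res.method == "EM"

    def test_outer_iterations_bounded(self, truth, fuzzy_50m, scan_50m):
        points, ids, scanners = scan_50m
        pts, rep_ids = sample_replicate(fuzzy_50m, 5)
        res = fuzzy_fit_loop(pts, rep_ids, scanners, config=FitConfig(tangent_lines=100, max_updates=10))
        assert res.outer_iterations <= 10

    def test_deterministic(self, truth, fuzzy_50m, scan_50m):
        points, ids, scanners = scan_50m
        pts, rep_ids = sample_replicate(fuzzy_50m, 6)
        cfg = FitConfig(tangent_lines=100)
        a = fuzzy_fit_loop(pts, rep_ids, scanners, config=cfg)
        b = fuzzy_fit_loop(pts, rep_ids, scanners, config=cfg)
        assert a.geometry.radius == b.geometry.radius
        assert np.array_equal(a.geometry.center, b.geometry.center)
        assert a.outer_iterations == b.outer_iterations

    def test_rem_variant_runs(self, truth, fuzzy_50m, scan_50m):
        points, ids, scanners = scan_50m
        pts, rep_ids = sample_replicate(fuzzy_50m, 7)
        res = fuzzy_fit_loop(
            pts, rep_ids, scanners, config=FitConfig(tangent_lines=100), method="rem",
            rng=np.random.default_rng(0),
        )
        assert res.method == "REM"
        assert abs(res.geometry.radius - truth.radius) / truth.radius < 0.5

    def test_unknown_method_rejected(self, scan_50m):
        points, ids, scanners = scan_50m
        with pytest.raises(ValueError):
            fuzzy_fit_loop(points, ids, scanners, method="nonsense")
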
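import numpy as np
import pytest

from fuzzycyl import (
    CylinderGeometry,
    FuzzyPointCloud,
    GaussianPoint,
    envelope_expected_sq_mahalanobis,
    expected_sq_mahalanobis_line,
    mahalanobis,
    tau,
    total_objective,
    whiten,
)
from fuzzycyl.errors import DegenerateLineError, InvalidPrecisionError
from fuzzycyl.geometry import TangentLine2D
from fuzzycyl.objective import envelope_values

from conftest import random_spd


def line_at(cx, cy):
    c = np.array([cx, cy], float)
    return TangentLine2D(tangent_point=c, unit_normal=c / np.linalg.norm(c))


class TestMahalanobis:
    def test_identity_precision_is_euclidean(self):
        x, y = np.array([1.0, 2.0]), np.array([4.0, 6.0])
        assert np.isclose(mahalanobis(x, y, np.eye(2)), 5.0)

    def test_zero_iff_equal(self):
        x = np.array([0.3, 0.4])
        assert mahalanobis(x, x, np.diag([2.0, 3.0])) == 0.0

    def test_diagonal_formula(self):
        assert np.isclose(mahalanobis(np.array([1.0, 1.0]), np.zeros(2), np.diag([4.0, 1.0])), np.sqrt(5))

    def test_rejects_non_spd_precision(self):
        with pytest.raises(InvalidPrecisionError):
            mahalanobis(np.zeros(2), np.ones(2), np.diag([1.0, -2.0]))


class TestTau:
    def test_isotropic_center_of_unit_circle(self):
        assert np.isclose(tau(line_at(1, 0), np.zeros(2), np.eye(2)), 1.0)

    def test_mean_on_line_gives_zero(self):
        # mean on the tangent line at (1, 0): any (1, y)
        assert np.isclose(tau(line_at(1, 0), np.array([1.0, 0.7]), np.diag([2.0, 0.5])), 0.0)

    def test_anisotropic_half(self):
        # sigma_x = 2 shrinks the distance to the vertical tangent line by 2
        val = tau(line_at(1, 0), np.zeros(2), np.diag([4.0, 1.0]))
        assert np.isclose(val, 0.5)

    def test_matches_whitened_line_distance(self):
        """tau equals the Euclidean distance from the whitened mean to the
        whitened tangent line (independent route via the whitening map)."""
        rng = np.random.default_rng(14)
        for _ in range(20):
            cov = random_spd(rng, 2)
            mean = rng.standard_normal(2)
            ang = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(0.5, 2.0)
            c = r * np.array([np.cos(ang), np.sin(ang)])
            line = TangentLine2D(tangent_point=c, unit_normal=c / r)
            T = whiten(mean, cov)
            # two points spanning the line, whitened
            direction = np.array([-c[1], c[0]]) / r
            a, b = T(c - 3 * direction), T(c + 3 * direction)
            u = (b - a) / np.linalg.norm(b - a)
            w = T(mean) - a
            dist = np.linalg.norm(w - (w @ u) * u)
            assert np.isclose(tau(line, mean, cov), dist, atol=1e-9)

    def test_degenerate_tangent_point(self):
        with pytest.raises(DegenerateLineError):
            tau(TangentLine2D(np.zeros(2), np.array([1.0, 0.0])), np.zeros(2), np.eye(2))


class TestExpectedSquaredLine:
    @pytest.mark.parametrize("t, expected", [(0.0, 1.0), (1.0, 2.0), (0.5, 1.25)])
    def test_closed_form(self, t, expected):
        assert expected_sq_mahalanobis_line(t) == expected

    def test_matches_monte_carlo(self):
        """Closed form tau^2 + 1 vs brute-force expectation of the squared
        whitened distance to the line, for random configurations."""
        rng = np.random.default_rng(15)
        n = 200_000
        for _ in range(8):
            cov = random_spd(rng, 2)
            mean = rng.standard_normal(2)
            ang = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(0.5, 2.0)
            c = r * np.array([np.cos(ang), np.sin(ang)])
            line = TangentLine2D(tangent_point=c, unit_normal=c / r)
            t_val = tau(line, mean, cov)
            closed = expected_sq_mahalanobis_line(t_val)
            L = np.linalg.cholesky(cov)
            draws = mean + rng.standard_normal((n, 2)) @ L.T
            T = whiten(mean, cov)
            direction = np.array([-c[1], c[0]]) / r
            a, b = T(c - direction), T(c + direction)
            u = (b - a) / np.linalg.norm(b - a)
            w = T(draws) - a
            d2 = np.sum((w - np.outer(w @ u, u)) ** 2, axis=1)
            se = d2.std(ddof=1) / np.sqrt(n)
            assert abs(d2.mean() - closed) < 3 * se + 1e-12


class TestEnvelope:
    def test_full_symmetry_gives_two(self):
        for t in (3, 10, 1000):
            val = envelope_expected_sq_mahalanobis(np.zeros(2), 1.0, np.zeros(2), np.eye(2), t=t)
            assert np.isclose(val, 2.0, atol=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(16)
        cov = random_spd(rng, 2)
        mu = np.array([1.3, -0.4])
        base = envelope_expected_sq_mahalanobis(np.zeros(2), 1.0, mu, cov, t=500)
        for s in (0.01, 3.0, 100.0):
            scaled = envelope_expected_sq_mahalanobis(np.zeros(2), s, s * mu, s**2 * cov, t=500)
            assert np.isclose(scaled, base, rtol=1e-12)

    def test_term_by_term_oracle(self):
        """Vectorized envelope value vs independent per-line summation using
        the scalar tau/expected-distance/mahalanobis operations."""
        mu = np.array([2.0, 0.0])
        cov = np.eye(2)
        P = np.eye(2)
        t = 1000
        for normalize in (True, False):
            fast = envelope_values(mu[None, :], cov[None, :, :], 1.0, t, normalize_weights=normalize)[0]
            num = 0.0
            den = 0.0
            for k in range(t):
                ang = 2 * np.pi * k / t
                c = np.array([np.cos(ang), np.sin(ang)])
                line = TangentLine2D(c, c)
                e_line = expected_sq_mahalanobis_line(tau(line, mu, cov))
                m = max(mahalanobis(c, mu, P), 1e-6)
                num += e_line / m**3
                den += 1.0 / m**3
            slow = num / den if normalize else num / t
            assert np.isclose(fast, slow, rtol=1e-10)

    def test_envelope_convergence_in_t(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            cov = random_spd(rng, 2)
            mu = rng.standard_normal(2)
            vals = [
                envelope_expected_sq_mahalanobis(np.zeros(2), 1.0, mu, cov, t=t) for t in (100, 1000, 10000)
            ]
            assert abs(vals[2] - vals[1]) < abs(vals[1] - vals[0]) + 1e-12


def _cloud_on_cylinder(truth, n=24, sigma=1e-4):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack(
        [truth.radius * np.cos(ang), truth.radius * np.sin(ang), np.linspace(-0.1, 0.1, n)]
    )
    cov = sigma**2 * np.eye(3)
    return FuzzyPointCloud([GaussianPoint(p, cov) for p in pts], geometry_used=truth)


class TestTotalObjective:
    def test_normalization_at_init_is_one(self, truth):
        fc = _cloud_on_cylinder(truth)
        ob = total_objective(truth, fc, truth, t=200)
        assert np.isclose(ob.normalized, 1.0, atol=1e-12)
        assert np.all(ob.per_point_values >= 0)

    def test_truth_beats_inflated_radius(self, truth):
        fc = _cloud_on_cylinder(truth)
        at_truth = total_objective(truth, fc, truth, t=500).normalized
        inflated = total_objective(truth.replace(radius=truth.radius * 1.2), fc, truth, t=500).normalized
        assert at_truth < inflated

    def test_duplication_invariance(self, truth):
        fc = _cloud_on_cylinder(truth)
        doubled = FuzzyPointCloud(points=list(fc.points) * 2, geometry_used=truth)
        cand = truth.replace(radius=truth.radius * 1.05)
        a = total_objective(cand, fc, truth, t=200).normalized
        b = total_objective(cand, doubled, truth, t=200).normalized
        assert np.isclose(a, b, rtol=1e-12)

    def test_rigid_motion_invariance(self, truth):
        # covariances must be wide relative to the tangent spacing so the
        # envelope sum resolves the per-line weight profile
        rng = np.random.default_rng(18)
        fc = _cloud_on_cylinder(truth, sigma=5e-3)
        cand = truth.replace(radius=truth.radius * 1.1)
        base = total_objective(cand, fc, truth, t=3000).normalized
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]
        shift = rng.standard_normal(3)
        fc_r = FuzzyPointCloud(
            [GaussianPoint(Q @ g.mean + shift, Q @ g.covariance @ Q.T, g.scanner_id) for g in fc.points]
        )
        truth_r = CylinderGeometry.from_axis(truth.radius, Q @ truth.axis, Q @ truth.center + shift, truth.length)
        cand_r = CylinderGeometry.from_axis(cand.radius, Q @ cand.axis, Q @ cand.center + shift, cand.length)
        moved = total_objective(cand_r, fc_r, truth_r, t=3000).normalized
        assert np.isclose(moved, base, atol=1e-8)
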
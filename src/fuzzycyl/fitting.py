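"""Cylinder fitting: Euclidean least squares, RANSAC, and fuzzy optimization.

Four methods share the same five-parameter cylinder description:

* ``ELS`` — Euclidean least squares: damped Gauss-Newton on the orthogonal
  point-to-surface residuals ``||perp(x - c)|| - r``.
* ``RELS`` — RANSAC consensus over small point subsets, refit by ELS on the
  inliers.
* ``EM`` — minimization of the expected-Mahalanobis envelope objective over
  a fuzzy point cloud, initialized by ELS.
* ``REM`` — the same, initialized by RANSAC + ELS.

The fuzzy methods run an outer loop: the current geometry estimate defines
the incidence angles and hence the covariances of the fuzzy cloud, the
objective is minimized, and the cloud is rebuilt from the new geometry until
the geometry stops changing (or a maximum number of updates is reached).

During optimization the axis is parameterized as a two-parameter
perturbation of a reference direction, ``v(a, b) = normalize(v_ref + a f1 +
b f2)``, which avoids the azimuth singularity of polar coordinates at the
pole (the test scenes have near-vertical axes).  The center is carried as
its two cross-section coordinates in the basis of the candidate axis, which
fixes the unidentifiable position along the axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize

from .errors import FitFailureError
from .fuzzy import FuzzyPointCloud, make_fuzzy_cloud
from .geometry import CylinderGeometry, axis_angles, cross_section_basis
from .lidar import ScannerSpec
from .objective import DEFAULT_TANGENT_LINES, cloud_mean_envelope

__all__ = ["FitConfig", "FitResult", "els_fit", "ransac_els_fit", "em_optimize", "fuzzy_fit_loop"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitConfig:
    """Settings shared by the fitting routines.

    Defaults follow the reference study setup: envelopes of 1000 tangent
    lines, at most 10 fuzzy-cloud distribution updates, and RANSAC capped at
    100 candidate subsets.
    """

    tangent_lines: int = DEFAULT_TANGENT_LINES
    max_updates: int = 10
    geometry_tol: float = 1e-3
    normalize_weights: bool = True
    ransac_max_subsets: int = 100
    ransac_subset_size: int = 9
    ransac_threshold_scale: float = 2.0
    gn_max_iter: int = 100
    seed: int | None = None


@dataclass
class FitResult:
    """Outcome of one cylinder fit."""

    geometry: CylinderGeometry
    objective_value: float
    method: str
    outer_iterations: int = 0
    converged: bool = True
    trace: list[CylinderGeometry] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "geometry": self.geometry.to_dict(),
            "objective_value": float(self.objective_value),
            "method": self.method,
            "outer_iterations": int(self.outer_iterations),
            "converged": bool(self.converged),
        }


# ---------------------------------------------------------------------------
# parameterization helpers


def _pack(cyl: CylinderGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Reference frame and parameter vector (a, b, cq1, cq2, r) at a geometry."""
    v0 = cyl.axis
    B = cross_section_basis(v0)
    cq = B @ cyl.center
    p = np.array([0.0, 0.0, cq[0], cq[1], cyl.radius])
    return p, v0, B[0], B[1]


def _unpack(p: np.ndarray, v0: np.ndarray, f1: np.ndarray, f2: np.ndarray, length: float) -> CylinderGeometry:
    a, b, cq1, cq2, r = p
    v = v0 + a * f1 + b * f2
    v = v / np.linalg.norm(v)
    B = cross_section_basis(v)
    center = cq1 * B[0] + cq2 * B[1]
    azimuth, elevation = axis_angles(v)
    return CylinderGeometry(radius=abs(float(r)), azimuth=azimuth, elevation=elevation, center=center, length=length)


def _axis_distances(points: np.ndarray, p: np.ndarray, v0, f1, f2) -> np.ndarray:
    a, b, cq1, cq2, _ = p
    v = v0 + a * f1 + b * f2
    v = v / np.linalg.norm(v)
    B = cross_section_basis(v)
    center = cq1 * B[0] + cq2 * B[1]
    d = points - center
    axial = d @ v
    perp = d - axial[:, None] * v
    return np.linalg.norm(perp, axis=1)


def _point_span(points: np.ndarray, v: np.ndarray) -> float:
    proj = points @ v
    return float(proj.max() - proj.min())


def _initial_geometry(points: np.ndarray) -> CylinderGeometry:
    """Algebraic initialization: PCA axis + Kasa circle fit in the plane.

    The axis is taken as the largest-eigenvalue eigenvector of the point
    covariance, which is reliable when the scanned patch is longer along the
    cylinder than around it (true for the scenes here; a known limitation
    for stubby cylinders).  The circle center and radius then follow from
    the linear Kasa fit of the projected points.
    """
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    w, U = np.linalg.eigh(centered.T @ centered)
    v = U[:, np.argmax(w)]
    if v[2] < 0:
        v = -v
    B = cross_section_basis(v)
    q = pts @ B.T
    # Kasa: minimize ||[2x 2y 1] [a b c]^T - (x^2 + y^2)||
    A = np.column_stack([2.0 * q[:, 0], 2.0 * q[:, 1], np.ones(len(q))])
    rhs = (q**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    cx, cy, c = sol
    r2 = c + cx**2 + cy**2
    r = float(np.sqrt(max(r2, 1e-12)))
    center = cx * B[0] + cy * B[1]
    azimuth, elevation = axis_angles(v)
    return CylinderGeometry(
        radius=r, azimuth=azimuth, elevation=elevation, center=center, length=max(_point_span(pts, v), 1e-6)
    )


# ---------------------------------------------------------------------------
# Euclidean least squares


def els_fit(points: np.ndarray, init: CylinderGeometry | None = None, config: FitConfig | None = None) -> FitResult:
    """Euclidean least-squares cylinder fit by damped Gauss-Newton.

    Minimizes ``sum_i (||perp(x_i - c)|| - r)^2`` over axis direction,
    in-plane center and radius, via Levenberg-Marquardt (Gauss-Newton with
    multiplicative damping) starting from an algebraic PCA + Kasa estimate
    unless ``init`` is given.
    """
    config = config or FitConfig()
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) < 6:
        raise FitFailureError(f"need at least 6 points, got {len(points)}")
    if init is None:
        init = _initial_geometry(points)
    p0, v0, f1, f2 = _pack(init)

    def residuals(p):
        return _axis_distances(points, p, v0, f1, f2) - p[4]

    try:
        res = least_squares(
            residuals,
            p0,
            method="lm",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-12,
            max_nfev=config.gn_max_iter * 6,
        )
    except Exception as exc:  # pragma: no cover - rank-deficient pathologies
        raise FitFailureError(f"Gauss-Newton failed: {exc}") from exc
    if not np.all(np.isfinite(res.x)):
        raise FitFailureError("Gauss-Newton produced non-finite parameters")
    geom = _unpack(res.x, v0, f1, f2, length=_point_span(points, init.axis))
    rms = float(np.sqrt(np.mean(res.fun**2)))
    # Gauss-Newton parameter covariance for standard errors
    try:
        J = res.jac
        dof = max(len(points) - 5, 1)
        s2 = float(res.fun @ res.fun) / dof
        pcov = s2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        pcov = None
    return FitResult(
        geometry=geom,
        objective_value=rms,
        method="ELS",
        outer_iterations=0,
        converged=bool(res.success),
        trace=[geom],
        diagnostics={
            "residual_rms": rms,
            "param_cov": pcov,
            "param_names": ["axis_a", "axis_b", "center_q1", "center_q2", "radius"],
            "n_points": len(points),
        },
    )


def _residuals_to(points: np.ndarray, geom: CylinderGeometry) -> np.ndarray:
    d = points - geom.center
    v = geom.axis
    perp = d - (d @ v)[:, None] * v
    return np.linalg.norm(perp, axis=1) - geom.radius


def ransac_els_fit(
    points: np.ndarray,
    config: FitConfig | None = None,
    rng: np.random.Generator | None = None,
    init: CylinderGeometry | None = None,
) -> FitResult:
    """RANSAC + ELS: consensus over minimal subsets, ELS refit on inliers.

    Minimal subsets of ``ransac_subset_size`` points (default 9) are drawn,
    each fitted by ELS; the inlier threshold is ``ransac_threshold_scale``
    times the median absolute residual of the initial full-data ELS fit.
    At most ``ransac_max_subsets`` (default 100) subsets are evaluated;
    consensus is the inlier count, ties broken by inlier residual RMS.
    """
    config = config or FitConfig()
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) < config.ransac_subset_size:
        raise FitFailureError(
            f"need at least {config.ransac_subset_size} points for RANSAC, got {len(points)}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    full = els_fit(points, init=init, config=config)
    thr = config.ransac_threshold_scale * float(np.median(np.abs(_residuals_to(points, full.geometry))))
    thr = max(thr, 1e-12)
    best = None  # (count, -rms, inlier_mask)
    for _ in range(config.ransac_max_subsets):
        idx = rng.choice(len(points), size=config.ransac_subset_size, replace=False)
        try:
            cand = els_fit(points[idx], config=config)
        except FitFailureError:
            continue
        resid = _residuals_to(points, cand.geometry)
        inliers = np.abs(resid) <= thr
        count = int(inliers.sum())
        if count < config.ransac_subset_size:
            continue
        rms = float(np.sqrt(np.mean(resid[inliers] ** 2)))
        key = (count, -rms)
        if best is None or key > best[0]:
            best = (key, inliers)
    if best is None:
        raise FitFailureError("no RANSAC subset produced a valid consensus fit")
    refit = els_fit(points[best[1]], config=config)
    refit.method = "RELS"
    refit.diagnostics["n_inliers"] = int(best[1].sum())
    refit.diagnostics["inlier_threshold"] = thr
    return refit


# ---------------------------------------------------------------------------
# expected-Mahalanobis optimization


def em_optimize(
    fc: FuzzyPointCloud,
    init: CylinderGeometry,
    t: int | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """Minimize the normalized envelope objective over cylinder parameters.

    A bound-constrained quasi-Newton method (L-BFGS-B, positive-definite
    Hessian approximation, radius bounded below) descends from ``init``; the
    best iterate seen is returned, so the normalized objective of the result
    never exceeds 1 (the value at ``init``).
    """
    config = config or FitConfig()
    if t is None:
        t = config.tangent_lines
    means3, covs3 = fc.means, fc.covariances
    p0, v0, f1, f2 = _pack(init)
    length = init.length

    normalizer = cloud_mean_envelope(init, means3, covs3, t, config.normalize_weights)
    if not np.isfinite(normalizer) or normalizer <= 0:
        raise FitFailureError("objective at the initial geometry is not finite and positive")

    best = {"p": p0.copy(), "f": 1.0}

    def fun(p):
        geom = _unpack(p, v0, f1, f2, length)
        val = cloud_mean_envelope(geom, means3, covs3, t, config.normalize_weights) / normalizer
        if np.isfinite(val) and val < best["f"]:
            best["f"] = float(val)
            best["p"] = p.copy()
        return val if np.isfinite(val) else 1e12

    bounds = [(-0.5, 0.5), (-0.5, 0.5), (None, None), (None, None), (1e-4, None)]
    res = minimize(
        fun,
        p0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"ftol": 1e-8, "gtol": 1e-6, "maxiter": 200},
    )
    geom = _unpack(best["p"], v0, f1, f2, length)
    ok = bool(res.success) or best["f"] <= 1.0
    result = FitResult(
        geometry=geom,
        objective_value=float(best["f"]),
        method="EM",
        outer_iterations=0,
        converged=ok,
        trace=[geom],
        diagnostics={"optimizer_message": str(res.message), "n_evaluations": int(res.nfev)},
    )
    if not ok:
        raise FitFailureError(f"optimizer failed: {res.message}", best_result=result)
    return result


def _geometry_change(old: CylinderGeometry, new: CylinderGeometry) -> float:
    """Max relative change over radius, in-plane center (scaled by r) and axis angle."""
    dr = abs(new.radius - old.radius) / old.radius
    cos_angle = float(np.clip(abs(old.axis @ new.axis), -1.0, 1.0))
    dangle = float(np.arccos(cos_angle))
    dc = new.center - old.center
    v = new.axis
    dc_perp = dc - (dc @ v) * v
    dcenter = float(np.linalg.norm(dc_perp)) / old.radius
    return max(dr, dangle, dcenter)


def fuzzy_fit_loop(
    points: np.ndarray,
    scanner_ids: np.ndarray,
    scanners: list[ScannerSpec],
    config: FitConfig | None = None,
    method: str = "em",
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Full fuzzy fitting pipeline with iterative covariance updates.

    1. Initial estimate by ELS (``method='em'``) or RANSAC + ELS
       (``method='rem'``) on the discrete points.
    2. Build the fuzzy point cloud from the current geometry estimate.
    3. Minimize the envelope objective.
    4. If the geometry changed more than ``geometry_tol`` and fewer than
       ``max_updates`` distribution updates have run, return to step 2.

    Non-convergence within ``max_updates`` returns the last iterate with
    ``converged=False`` (convergence of the update cycle is not guaranteed).
    """
    config = config or FitConfig()
    method = method.lower()
    if method not in ("em", "rem"):
        raise ValueError(f"method must be 'em' or 'rem', got {method!r}")
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    scanner_ids = np.asarray(scanner_ids, dtype=int).reshape(-1)
    if method == "rem":
        init_fit = ransac_els_fit(points, config=config, rng=rng)
    else:
        init_fit = els_fit(points, config=config)
    geom = init_fit.geometry
    trace = [geom]
    converged = False
    objective_value = np.nan
    iterations = 0
    for iterations in range(1, config.max_updates + 1):
        fc = make_fuzzy_cloud(points, scanner_ids, scanners, geom)
        try:
            step = em_optimize(fc, geom, t=config.tangent_lines, config=config)
        except FitFailureError as exc:
            if exc.best_result is None:
                raise
            step = exc.best_result
        change = _geometry_change(geom, step.geometry)
        geom = step.geometry
        objective_value = step.objective_value
        trace.append(geom)
        logger.info("fuzzy update %d: objective %.6f, geometry change %.3e", iterations, objective_value, change)
        if change < config.geometry_tol:
            converged = True
            break
    return FitResult(
        geometry=geom,
        objective_value=float(objective_value),
        method="EM" if method == "em" else "REM",
        outer_iterations=iterations,
        converged=converged,
        trace=trace,
        diagnostics={"init_method": init_fit.method, "n_points": len(points)},
    )
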
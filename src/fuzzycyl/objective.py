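"""Expected-Mahalanobis-distance objective for circle/cylinder fitting.

For a bivariate Gaussian and a line, the expected squared Mahalanobis
distance has the closed form ``tau**2 + 1`` where ``tau`` is the Mahalanobis
distance from the mean to the line: after whitening, the squared Euclidean
distance to a line at offset ``tau`` is a noncentral chi-square with one
degree of freedom and noncentrality ``tau**2``.

The cross-section circle is approximated by an envelope of ``t`` tangent
lines; each line's expected squared distance is down-weighted by the inverse
cubed Mahalanobis distance of its tangent point to the distribution, so that
far-away tangent lines contribute little.  The default aggregation is the
weighted mean

    E[M^2(C | mu, Sigma)] = sum_i (tau_i**2 + 1) / M(c_i)**3  /  sum_i 1 / M(c_i)**3

which is bounded below by 1 and attains it when the nearest tangent line
passes through the mean.  The unnormalized variant that divides by ``t``
instead of the weight sum is available via ``normalize_weights=False``; it
is not suitable for optimization because its infimum is 0 at geometries
arbitrarily far from the data (each term behaves like ``1/M`` there), which
lets a minimizer run away — see the methods note.

The full objective is the mean of these per-point expectations over the
fuzzy point cloud, normalized by the same quantity evaluated at the initial
geometry estimate, making values comparable across cloud sizes and noise
levels (the value at the initial geometry is exactly 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateLineError, EmptyCloudError, InvalidPrecisionError
from .fuzzy import FuzzyPointCloud
from .geometry import CylinderGeometry, TangentLine2D, project_to_cross_section, tangent_points

__all__ = [
    "ObjectiveBreakdown",
    "mahalanobis",
    "tau",
    "expected_sq_mahalanobis_line",
    "envelope_expected_sq_mahalanobis",
    "total_objective",
    "DENOMINATOR_GUARD",
    "DEFAULT_TANGENT_LINES",
]

#: Guard on the Mahalanobis distance in the envelope denominator; only binds
#: in the measure-zero event that a mean coincides with a tangent point.
DENOMINATOR_GUARD = 1e-6

#: Envelope size used throughout unless overridden.
DEFAULT_TANGENT_LINES = 1000


@dataclass(frozen=True)
class ObjectiveBreakdown:
    """Objective value with its per-point decomposition.

    ``normalized = mean / normalizer`` where ``normalizer`` is the mean
    expected squared distance under the initial geometry; at the initial
    geometry itself the normalized value is exactly 1.
    """

    per_point_values: np.ndarray
    mean: float
    normalizer: float
    normalized: float


def mahalanobis(x: np.ndarray, y: np.ndarray, precision: np.ndarray) -> float:
    """Mahalanobis distance ``sqrt((x-y)^T P (x-y))`` for precision matrix P.

    Reduces to the (unitless) Euclidean distance when ``P`` is the identity.
    """
    precision = np.asarray(precision, dtype=float)
    if not np.allclose(precision, precision.T, atol=1e-10 * max(1.0, float(np.abs(precision).max()))):
        raise InvalidPrecisionError("precision matrix is not symmetric")
    if np.linalg.eigvalsh(0.5 * (precision + precision.T)).min() <= 0:
        raise InvalidPrecisionError("precision matrix is not positive-definite")
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    return float(np.sqrt(d @ precision @ d))


def tau(tangent: TangentLine2D, mean: np.ndarray, cov: np.ndarray, circle_center=(0.0, 0.0)) -> float:
    """Mahalanobis distance from a Gaussian mean to a tangent line.

    In the frame centered at the circle and aligned with the Gaussian's
    principal axes this is ``|cx(cx-mux)+cy(cy-muy)| / sqrt(sx^2 cx^2 + sy^2 cy^2)``;
    the frame-invariant form ``|<c, c-mu>| / sqrt(c^T Sigma c)`` (all
    vectors relative to the circle center) is evaluated here, which agrees
    with the principal-frame expression for any orientation.
    """
    c = np.asarray(tangent.tangent_point, dtype=float) - np.asarray(circle_center, dtype=float)
    if np.linalg.norm(c) < 1e-15:
        raise DegenerateLineError("tangent point coincides with the circle center")
    mu = np.asarray(mean, dtype=float) - np.asarray(circle_center, dtype=float)
    cov = np.asarray(cov, dtype=float)
    return float(abs(c @ (c - mu)) / np.sqrt(c @ cov @ c))


def expected_sq_mahalanobis_line(tau_value: float) -> float:
    """Closed-form expected squared Mahalanobis distance to a line: ``tau**2 + 1``."""
    if tau_value < 0:
        raise ValueError("tau must be nonnegative")
    return tau_value**2 + 1.0


def _inv2x2(cov: np.ndarray) -> np.ndarray:
    """Batched inverse of (n, 2, 2) SPD matrices."""
    a, b = cov[:, 0, 0], cov[:, 0, 1]
    c, d = cov[:, 1, 0], cov[:, 1, 1]
    det = a * d - b * c
    inv = np.empty_like(cov)
    inv[:, 0, 0] = d
    inv[:, 0, 1] = -b
    inv[:, 1, 0] = -c
    inv[:, 1, 1] = a
    return inv / det[:, None, None]


def envelope_values(
    mu_centered: np.ndarray,
    cov2: np.ndarray,
    radius: float,
    t: int,
    normalize_weights: bool = True,
    eps: float = DENOMINATOR_GUARD,
) -> np.ndarray:
    """Vectorized per-point envelope expectation.

    Parameters
    ----------
    mu_centered : (n, 2) array
        Projected Gaussian means relative to the circle center.
    cov2 : (n, 2, 2) array
        Projected covariances.
    normalize_weights : bool
        If True (default), divide by the sum of the ``1/M**3`` weights (a
        weighted mean of per-line expectations, bounded below by 1).  If
        False, divide by ``t``; that variant is kept for reference but has
        a trivial infimum at far-away geometries.
    """
    C = tangent_points(radius, t)                                  # (t, 2)
    num = np.abs(radius**2 - mu_centered @ C.T)                    # (n, t) : |<c, c-mu>|
    den = np.sqrt(np.einsum("tj,njk,tk->nt", C, cov2, C))          # sqrt(c^T Sigma c)
    tau2 = (num / den) ** 2
    P = _inv2x2(cov2)
    d = C[None, :, :] - mu_centered[:, None, :]                    # (n, t, 2)
    q = np.einsum("ntj,njk,ntk->nt", d, P, d)
    M = np.sqrt(np.maximum(q, 0.0))
    w = 1.0 / np.maximum(M, eps) ** 3
    contrib = (tau2 + 1.0) * w
    if normalize_weights:
        return contrib.sum(axis=1) / w.sum(axis=1)
    return contrib.mean(axis=1)


def envelope_expected_sq_mahalanobis(
    circle_center: np.ndarray,
    radius: float,
    mean: np.ndarray,
    cov: np.ndarray,
    t: int = DEFAULT_TANGENT_LINES,
    normalize_weights: bool = True,
) -> float:
    """Expected squared Mahalanobis distance from one 2D Gaussian to a circle.

    The circle is approximated by its envelope of ``t`` tangent lines, each
    contributing its closed-form expectation weighted by the inverse cubed
    Mahalanobis distance of its tangent point.
    """
    if t < 3:
        from .errors import EnvelopeTooSmallError

        raise EnvelopeTooSmallError(f"envelope needs at least 3 tangent lines, got {t}")
    mu = np.asarray(mean, dtype=float).reshape(1, 2) - np.asarray(circle_center, dtype=float)
    cov2 = np.asarray(cov, dtype=float).reshape(1, 2, 2)
    return float(envelope_values(mu, cov2, radius, t, normalize_weights)[0])


def cloud_mean_envelope(
    cyl: CylinderGeometry,
    means3: np.ndarray,
    covs3: np.ndarray,
    t: int = DEFAULT_TANGENT_LINES,
    normalize_weights: bool = True,
) -> float:
    """Mean envelope expectation of a cloud under a candidate cylinder.

    Projects every Gaussian onto the candidate's cross-section plane and
    averages :func:`envelope_values`.  This is the un-normalized objective.
    """
    B = cyl.basis
    mu2 = means3 @ B.T - cyl.center2d
    cov2 = np.einsum("ij,njk,lk->nil", B, covs3, B)
    cov2 = 0.5 * (cov2 + np.swapaxes(cov2, 1, 2))
    return float(np.mean(envelope_values(mu2, cov2, cyl.radius, t, normalize_weights)))


def total_objective(
    cyl: CylinderGeometry,
    fc: FuzzyPointCloud,
    cyl0: CylinderGeometry,
    t: int = DEFAULT_TANGENT_LINES,
    normalize_weights: bool = True,
) -> ObjectiveBreakdown:
    """Normalized mean expected squared Mahalanobis distance of a cloud.

    The numerator evaluates the candidate geometry ``cyl``; the normalizer
    evaluates the initial estimate ``cyl0`` with the same envelope size, so
    that ``cyl == cyl0`` gives exactly 1.
    """
    if len(fc) == 0:
        raise EmptyCloudError("empty fuzzy point cloud")
    means3, covs3 = fc.means, fc.covariances

    def per_point(c: CylinderGeometry) -> np.ndarray:
        mu2, cov2 = project_to_cross_section(means3, c, covs3)
        return envelope_values(mu2 - c.center2d, cov2, c.radius, t, normalize_weights)

    vals = per_point(cyl)
    mean = float(vals.mean())
    normalizer = float(per_point(cyl0).mean())
    return ObjectiveBreakdown(
        per_point_values=vals,
        mean=mean,
        normalizer=normalizer,
        normalized=mean / normalizer,
    )
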
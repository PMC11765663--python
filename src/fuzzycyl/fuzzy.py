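"""Fuzzy point clouds: clouds of Gaussians instead of points.

A fuzzy point cloud replaces every measured 3D point by a trivariate normal
distribution whose covariance encodes that measurement's uncertainty.  The
covariances here follow the LiDAR beam model and therefore depend on an
estimate of the scanned geometry (through the incidence angle); the cloud
records which estimate generated it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateGeometryError,
    EmptyCloudError,
    IllConditionedError,
    InvalidCovarianceError,
)
from .geometry import CylinderGeometry
from .lidar import ScannerSpec, build_covariance

__all__ = [
    "GaussianPoint",
    "FuzzyPointCloud",
    "make_fuzzy_cloud",
    "sample_replicate",
    "whiten",
    "WhiteningTransform",
]

logger = logging.getLogger(__name__)


def _validated_spd(cov: np.ndarray, name="covariance") -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    sym = 0.5 * (cov + cov.T)
    if not np.allclose(cov, cov.T, atol=1e-10 * max(1.0, float(np.abs(cov).max()))):
        raise InvalidCovarianceError(f"{name} is not symmetric")
    if np.linalg.eigvalsh(sym).min() <= 0:
        raise InvalidCovarianceError(f"{name} is not positive-definite")
    return sym


@dataclass(frozen=True)
class GaussianPoint:
    """One fuzzy measurement: a trivariate normal N(mean, covariance).

    The precision matrix (inverse covariance) is cached at construction.
    """

    mean: np.ndarray
    covariance: np.ndarray
    scanner_id: int = 0
    precision: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float).reshape(3))
        cov = _validated_spd(self.covariance)
        object.__setattr__(self, "covariance", cov)
        if self.precision is None:
            object.__setattr__(self, "precision", np.linalg.inv(cov))


@dataclass
class FuzzyPointCloud:
    """A finite collection of Gaussian measurements with provenance.

    ``geometry_used`` is the cylinder estimate whose incidence angles
    generated the covariances.
    """

    points: list[GaussianPoint]
    geometry_used: CylinderGeometry | None = None

    def __post_init__(self):
        if len(self.points) == 0:
            raise EmptyCloudError("a fuzzy point cloud needs at least one point")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def means(self) -> np.ndarray:
        return np.array([p.mean for p in self.points])

    @property
    def covariances(self) -> np.ndarray:
        return np.array([p.covariance for p in self.points])

    @property
    def precisions(self) -> np.ndarray:
        return np.array([p.precision for p in self.points])

    @property
    def scanner_ids(self) -> np.ndarray:
        return np.array([p.scanner_id for p in self.points], dtype=int)

    def to_dataframe(self):
        """Documented column format: mean xyz, six covariance entries, scanner id."""
        import pandas as pd

        m, c = self.means, self.covariances
        return pd.DataFrame(
            {
                "x": m[:, 0], "y": m[:, 1], "z": m[:, 2],
                "cov_xx": c[:, 0, 0], "cov_xy": c[:, 0, 1], "cov_xz": c[:, 0, 2],
                "cov_yy": c[:, 1, 1], "cov_yz": c[:, 1, 2], "cov_zz": c[:, 2, 2],
                "scanner_id": self.scanner_ids,
            }
        )

    @classmethod
    def from_dataframe(cls, df, geometry_used=None) -> "FuzzyPointCloud":
        pts = []
        for row in df.itertuples(index=False):
            cov = np.array(
                [
                    [row.cov_xx, row.cov_xy, row.cov_xz],
                    [row.cov_xy, row.cov_yy, row.cov_yz],
                    [row.cov_xz, row.cov_yz, row.cov_zz],
                ]
            )
            pts.append(GaussianPoint(mean=(row.x, row.y, row.z), covariance=cov, scanner_id=int(row.scanner_id)))
        return cls(points=pts, geometry_used=geometry_used)


def make_fuzzy_cloud(
    points: np.ndarray,
    scanner_ids: np.ndarray,
    scanners: list[ScannerSpec],
    cyl_estimate: CylinderGeometry,
) -> FuzzyPointCloud:
    """Build a fuzzy cloud from measured points and a geometry estimate.

    Each point's covariance follows the LiDAR noise model evaluated with
    ``cyl_estimate`` (the incidence angle needs a surface).  Points whose
    covariance construction is degenerate (e.g. exactly on the estimated
    axis) are dropped with a warning rather than failing the whole cloud.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    scanner_ids = np.asarray(scanner_ids, dtype=int).reshape(-1)
    if len(points) != len(scanner_ids):
        raise ValueError("points and scanner_ids must have equal length")
    indexed: list[tuple[int, GaussianPoint]] = []
    dropped = 0
    for sid in np.unique(scanner_ids):
        mask = scanner_ids == sid
        idx = np.nonzero(mask)[0]
        try:
            covs = build_covariance(points[mask], scanners[sid], cyl_estimate)
        except DegenerateGeometryError:
            # batch failed: retry pointwise so only offending points drop
            covs = None
        if covs is None:
            for i in idx:
                try:
                    c = build_covariance(points[i], scanners[sid], cyl_estimate)
                except DegenerateGeometryError:
                    dropped += 1
                    continue
                indexed.append((int(i), GaussianPoint(points[i], c, int(sid))))
        else:
            indexed.extend((int(i), GaussianPoint(points[i], c, int(sid))) for i, c in zip(idx, covs))
    if dropped:
        logger.warning("dropped %d degenerate point(s) while building fuzzy cloud", dropped)
    indexed.sort(key=lambda pair: pair[0])  # keep the caller's point order
    return FuzzyPointCloud(points=[g for _, g in indexed], geometry_used=cyl_estimate)


def sample_replicate(fc: FuzzyPointCloud, seed) -> tuple[np.ndarray, np.ndarray]:
    """Draw one point per Gaussian; a replicate point cloud.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence` /
    :class:`numpy.random.Generator`; identical seeds give identical clouds.
    Scanner ids are preserved.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = fc.means
    L = np.linalg.cholesky(fc.covariances)
    z = rng.standard_normal((len(fc), 3))
    pts = means + np.einsum("nij,nj->ni", L, z)
    return pts, fc.scanner_ids.copy()


@dataclass(frozen=True)
class WhiteningTransform:
    """Affine map sending N(mean, cov) to the standard normal.

    ``T(x) = Lambda^{-1/2} U^T (x - mean)`` with ``cov = U Lambda U^T``.
    Euclidean distances after the map equal Mahalanobis distances before it.
    The eigendecomposition is made deterministic by sorting eigenvalues in
    descending order and fixing each eigenvector's sign so its first
    component of largest magnitude is positive.
    """

    mean: np.ndarray
    eigenvalues: np.ndarray       # descending
    eigenvectors: np.ndarray      # columns, matching eigenvalues

    @property
    def matrix(self) -> np.ndarray:
        """The linear part ``Lambda^{-1/2} U^T``."""
        return (self.eigenvectors / np.sqrt(self.eigenvalues)).T

    @property
    def inverse_matrix(self) -> np.ndarray:
        return self.eigenvectors * np.sqrt(self.eigenvalues)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x - self.mean) @ self.matrix.T

    def inverse(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        return y @ self.inverse_matrix.T + self.mean


def whiten(mean: np.ndarray, cov: np.ndarray) -> WhiteningTransform:
    """Whitening transform of a Gaussian (any dimension).

    Raises
    ------
    IllConditionedError
        If the covariance condition number exceeds 1e12.
    """
    mean = np.asarray(mean, dtype=float)
    cov = _validated_spd(np.asarray(cov, dtype=float))
    w, U = np.linalg.eigh(cov)
    order = np.argsort(-w, kind="stable")  # stable: ties keep eigh's order
    w, U = w[order], U[:, order]
    if w[-1] <= 0 or w[0] / w[-1] > 1e12:
        raise IllConditionedError(f"covariance condition number {w[0] / max(w[-1], 0.0):g} too large")
    # deterministic eigenvector signs: largest-magnitude component positive
    for j in range(U.shape[1]):
        k = int(np.argmax(np.abs(U[:, j])))
        if U[k, j] < 0:
            U[:, j] = -U[:, j]
    return WhiteningTransform(mean=mean, eigenvalues=w, eigenvectors=U)
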
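"""Cylinder parameterization and cross-section geometry.

A cylinder is described by its radius ``r``, the azimuth/elevation angles of
its axis direction, a point on the axis (the center), and a length that is
carried for bookkeeping but never constrains the fit.  For a fixed axis the
fitting problem lives in the cross-sectional plane ``Q`` perpendicular to the
axis: points and Gaussians are reduced to that plane, and the cross-section
circle is approximated by an envelope of tangent lines so that expected
distances have a closed form per line.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import EnvelopeTooSmallError, InvalidCovarianceError

__all__ = [
    "CylinderGeometry",
    "TangentLine2D",
    "axis_vector",
    "axis_angles",
    "cross_section_basis",
    "project_to_cross_section",
    "project_onto_axis",
    "tangent_envelope",
    "tangent_points",
]

#: |axis . z| above which the basis construction switches reference vectors.
BASIS_SWITCH_THRESHOLD = 0.9


def axis_vector(azimuth: float, elevation: float) -> np.ndarray:
    """Unit axis direction from azimuth ``theta`` and elevation ``phi``.

    ``v = (cos(phi) cos(theta), cos(phi) sin(theta), sin(phi))`` so that
    elevation ``pi/2`` gives the +z axis and elevation 0 lies in the xy-plane.
    """
    if not (np.isfinite(azimuth) and np.isfinite(elevation)):
        raise ValueError("azimuth and elevation must be finite")
    ce = np.cos(elevation)
    return np.array([ce * np.cos(azimuth), ce * np.sin(azimuth), np.sin(elevation)])


def axis_angles(v: np.ndarray) -> tuple[float, float]:
    """Inverse of :func:`axis_vector`: (azimuth, elevation) of a unit vector.

    At the poles (axis parallel to z) the azimuth is conventionally 0.
    """
    v = np.asarray(v, dtype=float)
    v = v / np.linalg.norm(v)
    elevation = float(np.arcsin(np.clip(v[2], -1.0, 1.0)))
    if abs(v[0]) < 1e-15 and abs(v[1]) < 1e-15:
        azimuth = 0.0
    else:
        azimuth = float(np.arctan2(v[1], v[0]))
    return azimuth, elevation


def cross_section_basis(axis: np.ndarray) -> np.ndarray:
    """Orthonormal basis ``(e1, e2)`` of the plane perpendicular to ``axis``.

    Returns a 2x3 matrix ``B`` with rows ``e1, e2`` such that ``(e1, e2, v)``
    is right-handed.  ``e1 = normalize(ref x v)`` with ``ref = (0,0,1)``
    unless ``|<v, z>| > 0.9`` in which case ``ref = (0,1,0)``; the switch
    keeps the construction well-conditioned near the pole, and the fallback
    reference is chosen so that a z-aligned axis yields the standard basis
    ``e1 = (1,0,0), e2 = (0,1,0)``.
    """
    v = np.asarray(axis, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("axis must be nonzero")
    v = v / n
    if abs(v[2]) > BASIS_SWITCH_THRESHOLD:
        ref = np.array([0.0, 1.0, 0.0])
    else:
        ref = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(ref, v)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v, e1)
    return np.vstack([e1, e2])


@dataclass(frozen=True)
class CylinderGeometry:
    """Cylinder parameterization (radius, axis angles, center, length).

    Parameters
    ----------
    radius : float
        Cross-section radius in meters, strictly positive.
    azimuth, elevation : float
        Axis direction angles in radians; see :func:`axis_vector`.
    center : (3,) array
        A point on the axis, in meters.  The position of the center along
        the axis is not identifiable from an infinite-cylinder fit and is
        therefore only a representative.
    length : float
        Carried for simulation (extent of the scanned surface along the
        axis) but never used as a fitting constraint.
    """

    radius: float
    azimuth: float
    elevation: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    length: float = 0.25

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))

    @property
    def axis(self) -> np.ndarray:
        """Unit axis direction vector."""
        return axis_vector(self.azimuth, self.elevation)

    @property
    def basis(self) -> np.ndarray:
        """2x3 cross-section basis matrix (rows ``e1``, ``e2``)."""
        return cross_section_basis(self.axis)

    @property
    def center2d(self) -> np.ndarray:
        """Projected center in cross-section coordinates."""
        return self.basis @ self.center

    @classmethod
    def from_axis(cls, radius: float, axis: np.ndarray, center=(0.0, 0.0, 0.0), length: float = 0.25):
        azimuth, elevation = axis_angles(axis)
        return cls(radius=radius, azimuth=azimuth, elevation=elevation, center=np.asarray(center, float), length=length)

    def replace(self, **kw) -> "CylinderGeometry":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "radius_m": float(self.radius),
            "azimuth_rad": float(self.azimuth),
            "elevation_rad": float(self.elevation),
            "center_m": [float(c) for c in self.center],
            "length_m": float(self.length),
            "axis": [float(c) for c in self.axis],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CylinderGeometry":
        return cls(
            radius=d["radius_m"],
            azimuth=d["azimuth_rad"],
            elevation=d["elevation_rad"],
            center=np.asarray(d["center_m"], float),
            length=d.get("length_m", 0.25),
        )


@dataclass(frozen=True)
class TangentLine2D:
    """A line tangent to the cross-section circle.

    ``tangent_point`` lies on the circle; ``unit_normal`` is the outward
    radial direction, perpendicular to the line.
    """

    tangent_point: np.ndarray
    unit_normal: np.ndarray

    def distance(self, x: np.ndarray) -> float:
        """Perpendicular (Euclidean) distance from ``x`` to the line."""
        x = np.asarray(x, float)
        return abs(float(self.unit_normal @ (x - self.tangent_point)))


def _check_spd(cov: np.ndarray, name: str = "covariance") -> None:
    cov = np.asarray(cov, float)
    if not np.allclose(cov, cov.T, atol=1e-10 * max(1.0, float(np.abs(cov).max()))):
        raise InvalidCovarianceError(f"{name} is not symmetric")
    w = np.linalg.eigvalsh(0.5 * (cov + cov.T))
    if w.min() <= 0:
        raise InvalidCovarianceError(f"{name} is not positive-definite (min eigenvalue {w.min():g})")


def project_to_cross_section(point_or_mean, cyl: CylinderGeometry, cov: np.ndarray | None = None):
    """Reduce a 3D point or Gaussian to the cross-section plane ``Q``.

    Coordinates are expressed in the orthonormal basis ``(e1, e2)`` of ``Q``
    (see :func:`cross_section_basis`).  A Gaussian is reduced by
    marginalization along the axis: the mean maps to ``B mu`` and the
    covariance to ``B Sigma B^T``, the distribution of the linear image under
    the basis matrix ``B``.  Since the cylinder surface is invariant along
    the axis, expectations of distances to it over the 3D Gaussian equal the
    expectation over this 2D marginal.

    Parameters
    ----------
    point_or_mean : (3,) or (n, 3) array
        Point(s) or Gaussian mean(s).
    cov : (3, 3) or (n, 3, 3) array, optional
        If given, the Gaussian covariance(s); the reduced ``(2, 2)``
        covariance(s) are returned alongside the projected mean(s).

    Returns
    -------
    (2,)/(n,2) array, or tuple of projected mean(s) and covariance(s).
    """
    B = cyl.basis
    x = np.asarray(point_or_mean, dtype=float)
    mean2 = x @ B.T
    if cov is None:
        return mean2
    cov = np.asarray(cov, dtype=float)
    if cov.ndim == 2:
        _check_spd(cov)
        cov2 = B @ cov @ B.T
    else:
        for c in cov:
            _check_spd(c)
        cov2 = np.einsum("ij,njk,lk->nil", B, cov, B)
    cov2 = 0.5 * (cov2 + np.swapaxes(cov2, -1, -2))
    return mean2, cov2


def project_onto_axis(point: np.ndarray, cyl: CylinderGeometry) -> np.ndarray:
    """Orthogonal projection ``p`` of a point onto the cylinder axis line."""
    v = cyl.axis
    x = np.asarray(point, dtype=float)
    d = x - cyl.center
    return cyl.center + (d @ v)[..., None] * v if x.ndim > 1 else cyl.center + float(d @ v) * v


def tangent_points(r: float, t: int) -> np.ndarray:
    """(t, 2) tangent points at angles ``2 pi k / t`` on a circle at the origin."""
    ang = 2.0 * np.pi * np.arange(t) / t
    return r * np.column_stack([np.cos(ang), np.sin(ang)])


def tangent_envelope(circle_center: np.ndarray, r: float, t: int) -> list[TangentLine2D]:
    """Envelope of ``t`` tangent lines approximating a circle.

    Tangent points are uniformly spaced in angle starting at angle 0 (the
    first cross-section basis vector), which gives deterministic, unbiased
    coverage.  Every line is at perpendicular distance exactly ``r`` from the
    circle center, hence never intersects the open disk.
    """
    if not r > 0:
        raise ValueError(f"circle radius must be positive, got {r}")
    if t < 3:
        raise EnvelopeTooSmallError(f"envelope needs at least 3 tangent lines, got {t}")
    c = np.asarray(circle_center, dtype=float).reshape(2)
    pts = tangent_points(r, t)
    normals = pts / r
    return [TangentLine2D(tangent_point=c + p, unit_normal=n) for p, n in zip(pts, normals)]
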
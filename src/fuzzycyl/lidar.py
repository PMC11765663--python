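"""LiDAR beam noise model and a deterministic scan simulator.

The measurement uncertainty of a terrestrial laser scanner point is modeled
as an anisotropic trivariate Gaussian.  Across the beam the standard
deviation is a quarter of the beam diameter (the footprint is conventionally
defined as four standard deviations of the Gaussian power profile); the beam
diameter grows linearly with range from the exit diameter ``d0`` at the
divergence half-angle ``lambda``.  Along the beam the uncertainty is the
base range uncertainty ``sigma0`` plus the radial uncertainty smeared out by
the incidence angle ``alpha`` between the beam and the surface normal:

    sigma_radial = d0/4 + (R/2) tan(lambda)
    sigma_prop   = sigma0 + sigma_radial * tan(alpha)

Grazing hits (``alpha -> 90 deg``) are clamped at ``ALPHA_MAX`` so that the
propagation uncertainty stays finite and the resulting precision matrix is
well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, EmptyScanError
from .geometry import CylinderGeometry, project_onto_axis

__all__ = [
    "ScannerSpec",
    "sigma_radial",
    "incidence_angle",
    "sigma_prop",
    "build_covariance",
    "simulate_scan",
    "ALPHA_MAX",
]

#: Incidence-angle clamp applied before tan(); keeps sigma_prop finite at
#: silhouette (near-tangent) rays.
ALPHA_MAX = np.deg2rad(89.5)

# Default beam constants approximating a Faro Focus-class scanner datasheet:
# 2.12 mm exit diameter, 0.3 mrad full divergence (0.15 mrad half-angle),
# 1 mm ranging uncertainty; 0.018 deg grid step is half the instrument's
# finest angular resolution.
DEFAULT_EXIT_DIAMETER = 2.12e-3
DEFAULT_DIVERGENCE_HALF_ANGLE = 0.15e-3
DEFAULT_BASE_RANGE_SIGMA = 1.0e-3
DEFAULT_ANGULAR_STEP = np.deg2rad(0.018)


@dataclass(frozen=True)
class ScannerSpec:
    """Position and beam/noise parameters of one terrestrial laser scanner."""

    position: np.ndarray
    exit_diameter: float = DEFAULT_EXIT_DIAMETER
    divergence_half_angle: float = DEFAULT_DIVERGENCE_HALF_ANGLE
    base_range_sigma: float = DEFAULT_BASE_RANGE_SIGMA
    angular_step: float = DEFAULT_ANGULAR_STEP

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float).reshape(3))
        if self.exit_diameter < 0:
            raise ValueError("exit_diameter must be >= 0")
        if self.divergence_half_angle < 0:
            raise ValueError("divergence_half_angle must be >= 0")
        if not self.base_range_sigma > 0:
            raise ValueError("base_range_sigma must be > 0")
        if not self.angular_step > 0:
            raise ValueError("angular_step must be > 0")

    def to_dict(self) -> dict:
        return {
            "position": [float(c) for c in self.position],
            "exit_diameter_m": float(self.exit_diameter),
            "divergence_half_angle_rad": float(self.divergence_half_angle),
            "base_range_sigma_m": float(self.base_range_sigma),
            "angular_step_deg": float(np.rad2deg(self.angular_step)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScannerSpec":
        return cls(
            position=np.asarray(d["position"], float),
            exit_diameter=d.get("exit_diameter_m", DEFAULT_EXIT_DIAMETER),
            divergence_half_angle=d.get("divergence_half_angle_rad", DEFAULT_DIVERGENCE_HALF_ANGLE),
            base_range_sigma=d.get("base_range_sigma_m", DEFAULT_BASE_RANGE_SIGMA),
            angular_step=np.deg2rad(d["angular_step_deg"]) if "angular_step_deg" in d else DEFAULT_ANGULAR_STEP,
        )


def _ranges(mu: np.ndarray, scanner: ScannerSpec) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    R = np.linalg.norm(mu - scanner.position, axis=-1)
    if np.any(R < 1e-12):
        raise DegenerateGeometryError("zero range: point coincides with the scanner position")
    return R


def sigma_radial(mu: np.ndarray, scanner: ScannerSpec):
    """Across-beam standard deviation: a quarter of the beam diameter at range."""
    R = _ranges(mu, scanner)
    out = scanner.exit_diameter / 4.0 + 0.5 * R * np.tan(scanner.divergence_half_angle)
    return float(out) if np.ndim(out) == 0 else out


def incidence_angle(mu: np.ndarray, scanner: ScannerSpec, cyl: CylinderGeometry):
    """Incidence angle ``alpha`` in [0, pi/2] between beam and surface normal.

    The surface normal at a cylinder point is the radial direction from its
    axis projection ``p`` to the point; ``alpha`` follows from the dot
    product of that direction with the beam direction.
    """
    mu = np.asarray(mu, dtype=float)
    R = _ranges(mu, scanner)
    p = project_onto_axis(mu, cyl)
    radial = mu - p
    rn = np.linalg.norm(radial, axis=-1)
    if np.any(rn < 1e-12):
        raise DegenerateGeometryError("point lies on the cylinder axis; surface normal undefined")
    beam = mu - scanner.position
    cos_a = np.abs(np.sum(radial * beam, axis=-1)) / (R * rn)
    out = np.arccos(np.clip(cos_a, 0.0, 1.0))
    return float(out) if np.ndim(out) == 0 else out


def sigma_prop(mu: np.ndarray, scanner: ScannerSpec, cyl: CylinderGeometry):
    """Along-beam standard deviation including the incidence-angle smear."""
    alpha = np.minimum(incidence_angle(mu, scanner, cyl), ALPHA_MAX)
    out = scanner.base_range_sigma + sigma_radial(mu, scanner) * np.tan(alpha)
    return float(out) if np.ndim(out) == 0 else out


def build_covariance(mu: np.ndarray, scanner: ScannerSpec, cyl: CylinderGeometry) -> np.ndarray:
    """Per-point 3x3 measurement covariance in the beam frame.

    The propagation direction (unit vector from scanner to point) carries
    ``sigma_prop**2``; the two directions perpendicular to the beam each
    carry ``sigma_radial**2``.  Eigenvalues are therefore
    ``{sigma_prop**2, sigma_radial**2, sigma_radial**2}``.

    Accepts a single point ``(3,)`` or a batch ``(n, 3)``.
    """
    mu = np.asarray(mu, dtype=float)
    single = mu.ndim == 1
    mus = mu[None, :] if single else mu
    R = _ranges(mus, scanner)
    u = (mus - scanner.position) / R[:, None]
    sr = np.atleast_1d(sigma_radial(mus, scanner))
    sp = np.atleast_1d(sigma_prop(mus, scanner, cyl))
    eye = np.eye(3)
    uu = u[:, :, None] * u[:, None, :]
    cov = sp[:, None, None] ** 2 * uu + sr[:, None, None] ** 2 * (eye - uu)
    return cov[0] if single else cov


def _scanner_frame(direction: np.ndarray) -> tuple[float, float]:
    """(azimuth, polar) spherical angles of a direction, world z up."""
    d = direction / np.linalg.norm(direction)
    az = float(np.arctan2(d[1], d[0]))
    pol = float(np.arccos(np.clip(d[2], -1.0, 1.0)))
    return az, pol


def _ray_directions(az: np.ndarray, pol: np.ndarray) -> np.ndarray:
    """Directions for an (azimuth x polar) grid, shape (len(az)*len(pol), 3)."""
    A, P = np.meshgrid(az, pol, indexing="ij")
    sp = np.sin(P)
    return np.column_stack([(sp * np.cos(A)).ravel(), (sp * np.sin(A)).ravel(), np.cos(P).ravel()])


def _intersect_cylinder(origin, directions, cyl: CylinderGeometry) -> np.ndarray:
    """First ray-cylinder intersections; rows of hit points (may be empty)."""
    v = cyl.axis
    w = origin - cyl.center
    d_perp = directions - np.outer(directions @ v, v)
    w_perp = w - (w @ v) * v
    a = np.einsum("ij,ij->i", d_perp, d_perp)
    b = 2.0 * d_perp @ w_perp
    c = w_perp @ w_perp - cyl.radius**2
    disc = b**2 - 4.0 * a * c
    ok = (disc >= 0) & (a > 1e-18)
    tt = np.full(len(directions), np.nan)
    tt[ok] = (-b[ok] - np.sqrt(disc[ok])) / (2.0 * a[ok])
    ok &= tt > 1e-9
    hits = origin + tt[ok, None] * directions[ok]
    axial = (hits - cyl.center) @ v
    hits = hits[np.abs(axial) <= cyl.length / 2.0]
    return hits


def simulate_scan(
    cyl: CylinderGeometry,
    scanners: list[ScannerSpec] | ScannerSpec,
    seed: int | None = None,
    grid_phase: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate noiseless TLS hit points on a cylinder.

    Each scanner casts rays on a regular spherical grid (azimuth x polar
    angle about its own position, world z up) with spacing
    ``scanner.angular_step``, centered on the direction to the cylinder
    center and wide enough to cover the cylinder's bounding sphere.  Only
    first intersections on the scanner-facing surface and within the length
    extent are kept, so self-occlusion of the back half is automatic.

    Hit points are exact intersections: measurement noise enters only when a
    fuzzy point cloud is built and sampled.  The ``seed`` argument is
    accepted for interface symmetry but unused — the scan is deterministic.

    ``grid_phase`` offsets every grid node by that fraction of a step
    (default 0: a node points exactly at the cylinder center).  A real
    instrument's grid is anchored to its own zero azimuth, so the phase
    relative to the target is arbitrary; error statistics are sensitive to
    it because it sets how close the outermost hitting rays come to the
    silhouette.

    Returns
    -------
    points : (n, 3) array
    scanner_ids : (n,) int array, index into ``scanners``
    """
    del seed  # deterministic: hit points carry no noise
    if isinstance(scanners, ScannerSpec):
        scanners = [scanners]
    all_pts, all_ids = [], []
    bound = np.hypot(cyl.radius, cyl.length / 2.0)
    for sid, sc in enumerate(scanners):
        to_center = cyl.center - sc.position
        dist = np.linalg.norm(to_center)
        if dist <= cyl.radius:
            raise DegenerateGeometryError("scanner position lies inside the cylinder")
        az0, pol0 = _scanner_frame(to_center)
        beta = np.arcsin(min(1.0, bound / dist))
        k = int(np.ceil(beta / sc.angular_step)) + 2
        offs = sc.angular_step * (np.arange(-k, k + 1) + grid_phase)
        dirs = _ray_directions(az0 + offs, pol0 + offs)
        hits = _intersect_cylinder(sc.position, dirs, cyl)
        if len(hits):
            all_pts.append(hits)
            all_ids.append(np.full(len(hits), sid, dtype=int))
    if not all_pts:
        raise EmptyScanError("no rays hit the cylinder")
    return np.vstack(all_pts), np.concatenate(all_ids)
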
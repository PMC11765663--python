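# Methods

## The model

A terrestrial laser scanner (TLS) measurement is not a point but a noisy
estimate of a surface location. `fuzzycyl` represents a scan as a *fuzzy
point cloud*: a finite set of trivariate normal distributions
N_i(mu_i, Sigma_i), one per measured point, where the covariance Sigma_i
encodes that measurement's location uncertainty — different in magnitude
and orientation for every point. Shape fitting then minimizes the mean
*expected* distance between these distributions and the candidate surface,
with the Mahalanobis distance M(x, y) = sqrt((x-y)^T P (x-y)) (P the
precision matrix) as the metric. Unlike the Euclidean distance it is
unitless, scale-invariant, and anisotropy-aware: a point is "far" from the
surface in proportion to how many standard deviations separate them, in the
direction that separates them.

### Cylinder parameterization

The cylinder has five free parameters: radius r, axis direction given by
azimuth/elevation, and the two coordinates of the axis point in the
cross-section plane Q perpendicular to the axis. The position of the
center *along* the axis, and the length, are not identifiable from an
infinite-cylinder fit and are carried only for bookkeeping. The plane
basis (e1, e2) is built as e1 = normalize(ref x v), e2 = v x e1 with
ref = (0, 0, 1), switching to ref = (0, 1, 0) when |<v, z>| > 0.9; the
switch keeps the construction well-conditioned near the vertical, and the
fallback is chosen so a z-aligned axis yields the standard basis. During
optimization the axis is parameterized as v(a, b) = normalize(v_ref + a e1
+ b e2) around a reference direction, avoiding the azimuth singularity of
polar angles at the pole (the study cylinder is vertical, i.e. exactly at
that singularity).

### Dimensionality reduction

Because the surface is invariant along the axis, each 3D Gaussian is
reduced to the cross-section plane by marginalization: mean B mu and
covariance B Sigma B^T, with B the 2x3 matrix of basis rows. The expected
distance of the 3D distribution to an axis-invariant surface equals the
expectation over this 2D marginal. (This reduction is the implementers'
construction; it is the natural linear-image reduction and is verified by
rotation-equivariance and basis-invariance tests.)

### Expected distance to the tangent-line envelope

For a single line L at Mahalanobis distance tau from the Gaussian mean, the
expected squared Mahalanobis distance has a closed form: after whitening
(the affine map T with T(x) = Lambda^{-1/2} U^T (x - mu), Sigma = U Lambda
U^T, which sends the Gaussian to the standard normal and Mahalanobis to
Euclidean distances), the squared distance to the line is a noncentral
chi-square with one degree of freedom and noncentrality tau^2, so

    E[M^2(L | mu, Sigma)] = tau^2 + 1,
    tau = |<c, c - mu>| / sqrt(c^T Sigma c),

with c the tangent point in coordinates relative to the circle center. The
tau formula is evaluated in frame-invariant form; in the Gaussian's
principal frame it reduces to the familiar componentwise expression.

The cross-section circle C is approximated by an envelope of t tangent
lines at uniformly spaced tangency angles. Approximating the circle by
tangent lines — rather than measuring distances to the curved circle
itself — avoids the curvature bias of convex shapes (a distribution
centered on a circle has more probability mass outside than inside, so
direct expected distances to the circle reward inflated radii). Each
line's expectation is weighted by w_i = 1 / M(c_i | mu, Sigma)^3, the
inverse *cubed* Mahalanobis distance of its tangent point, so that far-away
tangent lines (whose infinite extent would otherwise let them pass close to
the point) are suppressed; the cube makes the weight decay faster than
E[M^2] grows.

**Aggregation across the envelope.** Two aggregations were considered:

* dividing the weighted sum by the number of lines t (the form printed in
  the defining expression), and
* dividing by the sum of the weights (a weighted mean).

The first is not usable as an objective: because E[M^2(L)]/M ~ 1 for
far-away lines, each term behaves like 1/M there, and the whole sum tends
to 0 as the candidate geometry recedes from the data. Its infimum is
trivially attained at infinitely distant geometries, and a minimizer
descends toward it (observed as unbounded radius estimates). The weighted
mean is bounded below by 1, attains small values exactly when tangent
lines pass near the means, and is the reading consistent with the verbal
description "weighted by the distance of the point to the distribution".
The weighted mean is therefore the default (`normalize_weights=True`); the
literal form is retained behind the flag for study. A guard max(M, 1e-6)
in the denominator covers the measure-zero event that a mean coincides
with a tangent point.

The full objective is the mean of the per-point envelope expectations over
the cloud, divided by the same quantity at the initial geometry estimate:
the normalized objective is exactly 1 at the initial estimate and below 1
whenever the optimizer has improved on it, independent of cloud size or
noise scale.

### Envelope discretization

The envelope value converges as t grows (verified as a Cauchy-sequence
property over t = 100/1000/10000). For *noiseless* data lying exactly on
the cylinder, the finite envelope displaces the objective's minimum
slightly; the displacement shrinks with t (the test suite verifies
|dr|/r < 5e-3 at t = 1000 and < 1e-6 at t = 5000 on the 50 m noiseless
scan). For noisy data the effect is far below the statistical error. The
default t = 1000 follows the reference study; the Monte-Carlo tests and
the acceptance script use t = 200 (desk scale), where the discretization
effect is still negligible relative to replicate noise.

## LiDAR noise model

With range R = ||mu - s|| between the point and the scanner at s:

    sigma_radial = d0/4 + (R/2) tan(lambda)          across the beam
    alpha        = arccos(|<mu - p, mu - s>| / (R ||mu - p||))
    sigma_prop   = sigma0 + sigma_radial tan(alpha)  along the beam

where p is the point's projection onto the cylinder axis (so mu - p is the
surface normal direction), d0 the exit beam diameter, lambda the divergence
half-angle, and sigma0 the base range uncertainty. The across-beam
standard deviation is a quarter of the beam diameter, the conventional
4-sigma footprint definition for a Gaussian beam profile; the footprint
grows linearly with range (ranges are far beyond the Rayleigh length).
The incidence angle smears the footprint uncertainty along the beam;
alpha is clamped at 89.5 deg before the tangent so that silhouette-grazing
rays keep a finite variance. The covariance assigns sigma_prop^2 to the
beam direction and sigma_radial^2 to both perpendicular directions.

Because alpha depends on the surface, the covariances depend on the
geometry being estimated — a circular dependence. It is broken by
iteration: fit with the discrete points first (Euclidean least squares),
build the fuzzy cloud from that estimate, minimize the fuzzy objective,
rebuild the cloud from the new geometry, and repeat (at most 10 updates;
convergence when the maximum relative change over radius, in-plane center
scaled by r, and axis angle drops below 1e-3). Convergence of this outer
cycle is not guaranteed in general — a poor initial estimate yields a poor
initial cloud — and non-convergence is reported via the `converged` flag.

### Default instrument constants

| parameter | default | unit | rationale |
|---|---|---|---|
| exit beam diameter d0 | 2.12 | mm | datasheet-derived approximation (Faro Focus class) |
| divergence half-angle lambda | 0.15 | mrad | datasheet figure read as full angle 0.3 mrad |
| base range sigma0 | 1.0 | mm | datasheet ranging error +-1 mm |
| angular step | 0.018 | deg | half the instrument's finest resolution |

These are documented approximations of an instrument class, not published
simulation constants. See "Sensitivity" below.

## Scan simulator

Each scanner casts rays on a regular (azimuth x polar) grid about its own
position, step `angular_step`, centered on the direction to the cylinder
center and wide enough to cover the cylinder's bounding sphere. Hit points
are exact first ray-cylinder intersections restricted to the length extent;
the back half is self-occluded automatically. Hits are noiseless;
randomness enters only when replicate clouds are sampled from the fuzzy
cloud. A `grid_phase` parameter offsets the grid by a fraction of a step
for sensitivity studies (a real instrument's grid anchor relative to the
target is arbitrary).

What the simulator emulates: beam divergence, incidence-angle-dependent
anisotropic noise, multi-scanner scenes with per-scanner resolution and
range, self-occlusion. What it does not: angular (encoder) jitter,
registration error between scanners, surface roughness, occlusion by
external objects, footprint averaging over the beam cross-section, multiple
returns, atmospheric effects. Passing tests therefore demonstrate correct
behavior under idealized, known-noise conditions, not performance on real
forest scans.

## Fitting methods

* **ELS** — Euclidean least squares: damped Gauss-Newton
  (Levenberg-Marquardt) on residuals ||perp(x_i - c)|| - r over the five
  parameters. Initialization: axis from the dominant eigenvector of the
  point covariance (valid when the scanned patch is longer along the axis
  than around it — a documented limitation for stubby cylinders), then an
  algebraic Kasa circle fit in the projected plane.
* **RELS** — RANSAC: minimal subsets of 9 points, at most 100 subsets,
  inlier threshold twice the median absolute residual of the full-data ELS
  fit, consensus by inlier count with ties broken by inlier RMS, final ELS
  refit on the inliers.
* **EM** — the fuzzy objective minimized by a bound-constrained
  quasi-Newton method (L-BFGS-B; positive-definite Hessian approximation,
  r >= 1e-4 m, |axis perturbation| <= 0.5). The best iterate is returned,
  so the normalized objective never exceeds its value at the
  initialization. Initialized by ELS, inside the outer
  covariance-update loop above.
* **REM** — as EM but initialized by RANSAC + ELS.

## Monte-Carlo study

For each scenario (single scanner at 50 m; at 100 m; two scanners at 100 m
and 50 m placed 90 deg apart) the study simulates the base scan of the
true cylinder (r = 5 cm, l = 25 cm, vertical axis at the origin), builds
the true-geometry fuzzy cloud, samples replicate point clouds from it, fits
each replicate with the requested methods, and reports per-parameter
relative errors: center and radius errors as percent of the true radius,
axis-vector x/y component errors as raw unit-vector differences in percent.
The fitted axis sign is aligned with the truth, and the fitted center is
slid along the fitted axis into the truth's cross-section plane before
differencing (the axial position is not identifiable). Mean (nu) and
standard deviation (sigma) over replicates are tabulated, and dependent
pairwise Student's t-tests compare ELS vs EM and RELS vs REM per parameter.
The t-test compares absolute errors by default (the scientific question is
whether error magnitudes differ); signed errors via `absolute=False`.

Randomness: one master `SeedSequence`; each replicate gets a spawned child
(sampling and fitting streams spawned from it in turn), so any replicate is
reproducible in isolation and the report is independent of execution order.

Problem sizes: the package defaults to 50 replicates with 200 tangent lines
for routine runs (the CLI's `--full` switches to the reference-scale 200
replicates and 1000 tangent lines). The acceptance script runs the
Euclidean baseline at 200 replicates and the fuzzy loop at 50.

## Behavior under the default study conditions

Two empirical properties of the estimators, both recomputed by the shipped
artifacts, are worth stating explicitly:

* On a full ring with isotropic, homoscedastic noise the least-squares
  radius is inflated by approximately sigma^2/(2r) while the envelope
  method does not inflate — it overshoots into a negative bias of
  comparable, bounded magnitude (the curvature-bias test in the fitting
  test suite computes both).
* Under the default 50 m scan conditions — a one-sided arc whose flank
  points carry along-beam smear an order of magnitude larger than the
  head-on points — the envelope method's radius error is *positive and
  larger* than the least-squares error (a few percent vs a fraction of a
  percent; `scripts/acceptance.py` recomputes both). The advantage of the
  fuzzy objective is expected to grow with the overall noise level, and
  `scripts/sensitivity.py --with-em` shows the orderings under a larger
  divergence half-angle. At the default (low) noise level the baseline has
  little curvature bias left to remove, while the strongly heteroscedastic
  weighting of the envelope objective introduces a small inflation of its
  own.

## Sensitivity of the error statistics

The simulated error statistics are dominated by how close the outermost
hitting rays come to the cylinder silhouette, because sigma_prop grows like
tan(alpha) there. That proximity is set by the interaction of the angular
step, the grid phase, and the divergence half-angle — none of which are
published for the reference instrument beyond a datasheet citation. With
the defaults above, the mean ELS relative radius error is ~0.4% at 50 m,
~0.9% for the dual scene, and ~20% at 100 m (where the visible arc is so
short that circle fitting is ill-conditioned and errors are large for any
plausible noise level). Doubling the divergence half-angle to 0.3 mrad
raises the 50 m figure to ~4%, and 0.5 mrad to ~14%;
`scripts/sensitivity.py` reproduces this sweep. Comparisons with published
error tables should therefore be read through this sensitivity, and the
package deliberately keeps the documented datasheet-derived defaults rather
than calibrating them against any published table.

## Known limitations

* Circular cross-sections only; the envelope construction generalizes to
  other constant cross-sections but is not implemented.
* The PCA axis initialization fails for cylinders wider than they are long.
* No global optimization or multi-start: EM descends from the ELS (or
  RANSAC) initialization and inherits its basin.
* Only trivariate normal member distributions are supported.
* File formats: XYZ text and ASCII PLY (a minimal built-in codec); no LAS
  or binary PLY support.
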
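# fuzzycyl

Cylinder fitting for terrestrial laser scanning (TLS) point clouds that
treats every measured point as a 3D Gaussian — a *fuzzy point cloud* —
instead of an exact location.

## The problem

TLS instruments measure surfaces as dense point clouds, and cylinders are
the workhorse primitive for reconstructing tree stems, branches and pipes
from them. Ordinary least-squares fitting ignores that each point's
uncertainty differs in size *and* direction: the laser footprint grows with
range, and grazing (high-incidence) hits smear the uncertainty along the
beam. Near a cylinder's silhouette this smear is an order of magnitude
larger than at the center, and Euclidean fits systematically overestimate
the radius (curvature bias: noisy points around a convex surface land
outside more often than inside, in terms of distance-to-surface).

`fuzzycyl` fits the cylinder to the cloud of distributions instead. Each
point i becomes a trivariate normal N(mu_i, Sigma_i) with

    sigma_radial = d0/4 + (R/2) tan(lambda)       (across the beam)
    sigma_prop   = sigma0 + sigma_radial tan(alpha)  (along the beam)

where R is the range, d0 the exit beam diameter, lambda the divergence
half-angle, sigma0 the base range uncertainty, and alpha the incidence
angle. The fit minimizes the mean **expected squared Mahalanobis
distance** from the distributions to the cross-section circle,
approximated by an envelope of t tangent lines; for each line the
expectation is in closed form,

    E[M^2(L | mu, Sigma)] = tau^2 + 1,   tau = |<c, c-mu>| / sqrt(c^T Sigma c),

and the per-line values are combined with inverse-cubed-distance weights
so far-away tangent lines are suppressed. Because the covariances depend
on the (unknown) geometry through alpha, the fit iterates: least-squares
initialization, build the fuzzy cloud, minimize, rebuild, until the
geometry converges. Baselines (plain and RANSAC least squares) and a
deterministic TLS scan simulator for Monte-Carlo method comparison are
included.

## Worked example

Simulate a scan of the reference cylinder (radius 5 cm, length 25 cm,
vertical axis) from a scanner 50 m away, then fit it with the fuzzy
expected-Mahalanobis method:

```bash
$ fuzzycyl simulate scan50.xyz --scenario 50m
wrote 105 points from 1 scanner(s) to scan50.xyz

$ fuzzycyl fit scan50.xyz --method em --tangent-lines 500
                   Cylinder Fit Results
==========================================================
Method:                                                 EM
No. observations:                                      105
Converged:                                            True
Outer iterations:                                        1
Objective value:                                  0.999987
----------------------------------------------------------
parameter           estimate       std err          unit
----------------------------------------------------------
radius              0.050018                           m
azimuth             0.000000                         rad
elevation           1.570796                         rad
center_x            0.000000                           m
center_y           -0.000025                           m
center_z           -0.000000                           m
==========================================================
```

The scan is noiseless, so the fit recovers the true radius (0.05 m) to
18 um; the objective value is the envelope expectation normalized by its
value at the least-squares initialization (1 means the initialization was
already optimal), and the loop converged after a single covariance update.
Elevation pi/2 is the vertical axis.

The same workflow from Python, statsmodels-style:

```python
import numpy as np
from fuzzycyl import CylinderModel, scenario_scanners, simulate_scan, default_truth

scanners = scenario_scanners("50m")
points, ids = simulate_scan(default_truth(), scanners)
model = CylinderModel(points, ids, scanners=scanners)
results = model.fit(method="em")
print(results.summary())
print(results.params["radius"])     # 0.050018...
```

`fuzzycyl evaluate --scenario dual --replicates 50 --seed 0` runs the
Monte-Carlo comparison (ELS / RELS / EM / REM over replicate clouds sampled
from the true-geometry fuzzy cloud) and writes a JSON report with mean and
standard deviation of the relative parameter errors plus paired t-tests;
`--full` switches to the reference scale (200 replicates, 1000 tangent
lines).

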
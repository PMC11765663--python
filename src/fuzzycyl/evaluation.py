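"""Monte-Carlo comparison of the fitting methods.

Replicate point clouds are sampled from a fuzzy cloud built with the *true*
geometry, each replicate is fitted by the requested methods, and per-
parameter relative errors are aggregated into mean (``nu``) and standard
deviation (``sigma``) tables, with dependent pairwise Student's t-tests
between the Euclidean and expected-Mahalanobis variants.

Errors are reported in percent: center and radius errors are divided by the
true radius; axis-vector component errors are raw differences of the unit
vectors (no normalization).  Only the two cross-axis center components and
the x/y axis components are reported — the position along the axis and the
length are not identifiable from an infinite-cylinder fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitFailureError, FuzzyCylError
from .fitting import FitConfig, FitResult, els_fit, fuzzy_fit_loop, ransac_els_fit
from .fuzzy import make_fuzzy_cloud, sample_replicate
from .geometry import CylinderGeometry, cross_section_basis
from .lidar import ScannerSpec, simulate_scan

__all__ = [
    "SCENARIOS",
    "PARAMETERS",
    "ExperimentReport",
    "default_truth",
    "scenario_scanners",
    "relative_errors",
    "paired_t_test",
    "run_experiment",
]

logger = logging.getLogger(__name__)

#: Scanner positions (m) of the three study scenarios.
SCENARIOS = {
    "50m": [(0.0, 50.0, 0.0)],
    "100m": [(0.0, 100.0, 0.0)],
    "dual": [(0.0, 100.0, 0.0), (50.0, 0.0, 0.0)],
}

PARAMETERS = ["center_x", "center_y", "vector_x", "vector_y", "radius"]

METHOD_LABELS = {"els": "ELS", "rels": "RELS", "em": "EM", "rem": "REM"}


def default_truth() -> CylinderGeometry:
    """The study cylinder: radius 5 cm, length 25 cm, axis parallel to z, at the origin."""
    return CylinderGeometry(radius=0.05, azimuth=0.0, elevation=np.pi / 2.0, center=np.zeros(3), length=0.25)


def scenario_scanners(scenario: str, **scanner_kwargs) -> list[ScannerSpec]:
    """Scanner specifications for a named scenario (default beam constants)."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
    return [ScannerSpec(position=np.array(p), **scanner_kwargs) for p in SCENARIOS[scenario]]


def relative_errors(fit: FitResult | CylinderGeometry, truth: CylinderGeometry) -> np.ndarray:
    """Five relative parameter errors in percent.

    ``(100 (c_x - cx)/r, 100 (c_y - cy)/r, 100 (v_x - vx), 100 (v_y - vy),
    100 (r_hat - r)/r)``.  The fitted axis sign is aligned with the truth
    (maximizing the dot product) before differencing, and the fitted center
    is moved along the fitted axis into the truth's cross-section plane so
    that the unidentifiable axial position does not contaminate the error.
    Center components are expressed in the truth's cross-section basis
    (world x/y when the true axis is the z-axis).
    """
    geom = fit.geometry if isinstance(fit, FitResult) else fit
    v_true = truth.axis
    v_fit = geom.axis
    if float(v_fit @ v_true) < 0:
        v_fit = -v_fit
    denom = float(v_fit @ v_true)
    if abs(denom) < 1e-12:
        raise FitFailureError("fitted axis perpendicular to the true axis; errors undefined")
    # slide the fitted center along the fitted axis into the plane <x - c_true, v_true> = 0
    s = float((truth.center - geom.center) @ v_true) / denom
    c_eval = geom.center + s * v_fit
    B = cross_section_basis(v_true)
    dc = B @ (c_eval - truth.center)
    r = truth.radius
    return np.array(
        [
            100.0 * dc[0] / r,
            100.0 * dc[1] / r,
            100.0 * (v_fit[0] - v_true[0]),
            100.0 * (v_fit[1] - v_true[1]),
            100.0 * (geom.radius - r) / r,
        ]
    )


def paired_t_test(errors_a: np.ndarray, errors_b: np.ndarray, absolute: bool = True) -> float:
    """Two-sided dependent (paired) Student's t-test p-value.

    By default the test compares the *magnitudes* of the paired errors
    (whether one method's absolute error is systematically smaller); set
    ``absolute=False`` to test the signed errors.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired samples must be 1-D, equal length >= 2")
    if absolute:
        a, b = np.abs(a), np.abs(b)
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise FuzzyCylError("zero-variance differences: paired t-test p-value undefined")
    return float(stats.ttest_rel(a, b).pvalue)


@dataclass
class ExperimentReport:
    """Aggregated Monte-Carlo results for one scenario."""

    scenario: str
    truth: CylinderGeometry
    n_replicates: int
    methods: list[str]
    per_replicate: dict[str, np.ndarray]        # method -> (n_ok, 5) errors (%)
    nu: dict[str, np.ndarray]                   # method -> (5,) mean errors (%)
    sigma: dict[str, np.ndarray]                # method -> (5,) std of errors (%)
    p_values: dict[str, dict[str, float]]       # pair label -> parameter -> p
    n_failed: dict[str, int]
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def arr(a):
            return [[float(x) for x in row] for row in np.atleast_2d(a)]

        return {
            "schema_version": 1,
            "scenario": self.scenario,
            "truth": self.truth.to_dict(),
            "n_replicates": int(self.n_replicates),
            "methods": list(self.methods),
            "parameters": PARAMETERS,
            "per_replicate": {m: arr(v) for m, v in self.per_replicate.items()},
            "nu_percent": {m: [float(x) for x in v] for m, v in self.nu.items()},
            "sigma_percent": {m: [float(x) for x in v] for m, v in self.sigma.items()},
            "p_values": {k: {p: (None if np.isnan(v) else float(v)) for p, v in d.items()} for k, d in self.p_values.items()},
            "n_failed": {m: int(v) for m, v in self.n_failed.items()},
            "settings": self.settings,
        }

    def to_table(self) -> pd.DataFrame:
        """Wide table of nu/sigma per method, mirroring the study's layout."""
        cols = []
        for p in PARAMETERS:
            cols += [f"{p}_nu_percent", f"{p}_sigma_percent"]
        rows = {}
        for m in self.methods:
            label = METHOD_LABELS[m]
            vals = []
            for j in range(5):
                vals += [self.nu[m][j], self.sigma[m][j]]
            rows[label] = vals
        return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def _fit_one(method: str, pts, ids, scanners, config: FitConfig, rng: np.random.Generator) -> FitResult:
    if method == "els":
        return els_fit(pts, config=config)
    if method == "rels":
        return ransac_els_fit(pts, config=config, rng=rng)
    if method in ("em", "rem"):
        return fuzzy_fit_loop(pts, ids, scanners, config=config, method=method, rng=rng)
    raise ValueError(f"unknown method {method!r}")


def run_experiment(
    scenario: str = "50m",
    n_replicates: int = 50,
    seed: int = 0,
    methods: tuple[str, ...] = ("els", "rels", "em", "rem"),
    config: FitConfig | None = None,
    truth: CylinderGeometry | None = None,
    scanners: list[ScannerSpec] | None = None,
    covariance_scale: float = 1.0,
    absolute_t_test: bool = True,
) -> ExperimentReport:
    """Run the Monte-Carlo fitting comparison for one scenario.

    Simulates the base scan from the true geometry, builds the
    true-geometry fuzzy cloud, samples ``n_replicates`` point clouds from
    it, fits each with every requested method, and aggregates relative
    errors and paired t-tests.  All randomness descends from ``seed`` via
    spawned child streams (replicate k is reproducible in isolation and the
    report is independent of execution order).

    ``covariance_scale`` multiplies the sampling covariances (useful for
    noise-free consistency checks); the fitting itself always uses the
    unscaled noise model.
    """
    config = config or FitConfig()
    truth = truth or default_truth()
    if scanners is None:
        scanners = scenario_scanners(scenario)
    methods = tuple(m.lower() for m in methods)
    points, ids = simulate_scan(truth, scanners)
    fc_true = make_fuzzy_cloud(points, ids, scanners, truth)
    if covariance_scale != 1.0:
        from .fuzzy import FuzzyPointCloud, GaussianPoint

        fc_true = FuzzyPointCloud(
            points=[
                GaussianPoint(g.mean, covariance_scale * g.covariance, g.scanner_id) for g in fc_true.points
            ],
            geometry_used=truth,
        )

    master = np.random.SeedSequence(seed)
    children = master.spawn(n_replicates)
    errors: dict[str, list] = {m: [] for m in methods}
    failed = {m: 0 for m in methods}
    for k, child in enumerate(children):
        sample_ss, fit_ss = child.spawn(2)
        pts, rep_ids = sample_replicate(fc_true, np.random.default_rng(sample_ss))
        fit_streams = fit_ss.spawn(len(methods))
        for m, ss in zip(methods, fit_streams):
            try:
                fit = _fit_one(m, pts, rep_ids, scanners, config, np.random.default_rng(ss))
                err = relative_errors(fit, truth)
                errors[m].append((k, err))
                logger.info("replicate %d method %s: radius error %.3f%%", k, m, err[4])
            except (FitFailureError, FuzzyCylError) as exc:
                failed[m] += 1
                logger.info("replicate %d method %s failed: %s", k, m, exc)

    per_replicate = {m: np.array([e for _, e in errors[m]]).reshape(-1, 5) for m in methods}
    nu = {m: per_replicate[m].mean(axis=0) if len(per_replicate[m]) else np.full(5, np.nan) for m in methods}
    sig = {m: per_replicate[m].std(axis=0, ddof=1) if len(per_replicate[m]) > 1 else np.full(5, np.nan) for m in methods}

    p_values: dict[str, dict[str, float]] = {}
    for a, b in (("els", "em"), ("rels", "rem")):
        if a in methods and b in methods:
            ka = dict(errors[a])
            kb = dict(errors[b])
            common = sorted(set(ka) & set(kb))
            label = f"{METHOD_LABELS[a]}_vs_{METHOD_LABELS[b]}"
            p_values[label] = {}
            for j, pname in enumerate(PARAMETERS):
                try:
                    ea = np.array([ka[k][j] for k in common])
                    eb = np.array([kb[k][j] for k in common])
                    p_values[label][pname] = paired_t_test(ea, eb, absolute=absolute_t_test)
                except (FuzzyCylError, ValueError):
                    p_values[label][pname] = float("nan")

    return ExperimentReport(
        scenario=scenario,
        truth=truth,
        n_replicates=n_replicates,
        methods=list(methods),
        per_replicate=per_replicate,
        nu=nu,
        sigma=sig,
        p_values=p_values,
        n_failed=failed,
        settings={
            "seed": int(seed),
            "tangent_lines": int(config.tangent_lines),
            "max_updates": int(config.max_updates),
            "covariance_scale": float(covariance_scale),
            "absolute_t_test": bool(absolute_t_test),
            "scanners": [s.to_dict() for s in scanners],
            "n_scan_points": int(len(points)),
        },
    )
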
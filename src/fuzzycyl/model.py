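"""Model/Results interface for cylinder fitting.

:class:`CylinderModel` is constructed from point data (array or DataFrame)
plus scanner metadata; :meth:`CylinderModel.fit` dispatches to the chosen
method and returns a :class:`CylinderFitResults` carrying the parameter
estimates, standard errors where available, diagnostics, and a text
``summary()``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import relative_errors
from .fitting import FitConfig, FitResult, els_fit, fuzzy_fit_loop, ransac_els_fit
from .geometry import CylinderGeometry
from .lidar import ScannerSpec

__all__ = ["CylinderModel", "CylinderFitResults"]

_PARAM_INDEX = ["radius", "azimuth", "elevation", "center_x", "center_y", "center_z"]


class CylinderModel:
    """A cylinder to be fitted to a (possibly multi-scanner) point cloud.

    Parameters
    ----------
    points : (n, 3) array
        Measured 3D points, meters.
    scanner_ids : (n,) int array, optional
        Index of the scanner that produced each point (default all 0).
    scanners : list of ScannerSpec, optional
        Required for the fuzzy methods (``em``/``rem``), which need the beam
        model to build measurement covariances.
    """

    def __init__(self, points, scanner_ids=None, scanners: list[ScannerSpec] | None = None):
        self.points = np.asarray(points, dtype=float).reshape(-1, 3)
        if scanner_ids is None:
            scanner_ids = np.zeros(len(self.points), dtype=int)
        self.scanner_ids = np.asarray(scanner_ids, dtype=int).reshape(-1)
        if len(self.scanner_ids) != len(self.points):
            raise ValueError("scanner_ids length must match points")
        self.scanners = scanners

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, scanners=None) -> "CylinderModel":
        """Build from a DataFrame with columns ``x, y, z`` and optional ``scanner_id``."""
        pts = df[["x", "y", "z"]].to_numpy(dtype=float)
        ids = df["scanner_id"].to_numpy(dtype=int) if "scanner_id" in df.columns else None
        return cls(pts, ids, scanners=scanners)

    @property
    def nobs(self) -> int:
        return len(self.points)

    def fit(self, method: str = "em", config: FitConfig | None = None, seed: int | None = None, **kwargs) -> "CylinderFitResults":
        """Fit the cylinder.

        ``method`` is one of ``'els'``, ``'rels'``, ``'em'``, ``'rem'``.
        Keyword arguments override :class:`FitConfig` fields (e.g.
        ``tangent_lines=500``).
        """
        method = method.lower()
        if config is None:
            config = FitConfig(**kwargs) if kwargs else FitConfig()
        elif kwargs:
            raise ValueError("pass either config or keyword overrides, not both")
        if seed is not None:
            import dataclasses

            config = dataclasses.replace(config, seed=seed)
        rng = np.random.default_rng(config.seed)
        if method == "els":
            fr = els_fit(self.points, config=config)
        elif method == "rels":
            fr = ransac_els_fit(self.points, config=config, rng=rng)
        elif method in ("em", "rem"):
            if self.scanners is None:
                raise ValueError("fuzzy methods need scanner specifications (scanners=...)")
            fr = fuzzy_fit_loop(self.points, self.scanner_ids, self.scanners, config=config, method=method, rng=rng)
        else:
            raise ValueError(f"unknown method {method!r}")
        return CylinderFitResults(self, fr)


class CylinderFitResults:
    """Estimates, uncertainties and diagnostics of a cylinder fit."""

    def __init__(self, model: CylinderModel, fit_result: FitResult):
        self.model = model
        self.fit_result = fit_result

    # -- estimates ---------------------------------------------------------
    @property
    def geometry(self) -> CylinderGeometry:
        return self.fit_result.geometry

    @property
    def params(self) -> pd.Series:
        g = self.geometry
        return pd.Series(
            [g.radius, g.azimuth, g.elevation, *g.center],
            index=_PARAM_INDEX,
            name=self.fit_result.method,
        )

    @property
    def bse(self) -> pd.Series:
        """Standard errors (Gauss-Newton, ELS-based fits only; NaN otherwise).

        Derived from the residual variance and the Jacobian at the optimum;
        reported for the radius (the axis and center entries use the
        internal perturbation parameterization and are exposed through
        ``fit_result.diagnostics['param_cov']``).
        """
        out = pd.Series(np.nan, index=_PARAM_INDEX, name="bse")
        pcov = self.fit_result.diagnostics.get("param_cov")
        if pcov is not None:
            out["radius"] = float(np.sqrt(pcov[4, 4]))
        return out

    @property
    def method(self) -> str:
        return self.fit_result.method

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def errors_vs(self, truth: CylinderGeometry) -> pd.Series:
        """Relative parameter errors (%) against a known geometry."""
        from .evaluation import PARAMETERS

        return pd.Series(relative_errors(self.fit_result, truth), index=PARAMETERS)

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        g = self.geometry
        fr = self.fit_result
        bse = self.bse
        lines = [
            "Cylinder Fit Results".center(58),
            "=" * 58,
            f"{'Method:':<22}{fr.method:>36}",
            f"{'No. observations:':<22}{self.nobs:>36}",
            f"{'Converged:':<22}{str(fr.converged):>36}",
            f"{'Outer iterations:':<22}{fr.outer_iterations:>36}",
            f"{'Objective value:':<22}{fr.objective_value:>36.6g}",
            "-" * 58,
            f"{'parameter':<14}{'estimate':>14}{'std err':>14}{'unit':>14}",
            "-" * 58,
            f"{'radius':<14}{g.radius:>14.6f}{_fmt(bse['radius']):>14}{'m':>14}",
            f"{'azimuth':<14}{g.azimuth:>14.6f}{'':>14}{'rad':>14}",
            f"{'elevation':<14}{g.elevation:>14.6f}{'':>14}{'rad':>14}",
            f"{'center_x':<14}{g.center[0]:>14.6f}{'':>14}{'m':>14}",
            f"{'center_y':<14}{g.center[1]:>14.6f}{'':>14}{'m':>14}",
            f"{'center_z':<14}{g.center[2]:>14.6f}{'':>14}{'m':>14}",
            "=" * 58,
        ]
        return "\n".join(lines)

    def plot_cross_section(self, ax=None):
        """Scatter the points in the fitted cross-section with the fitted circle."""
        import matplotlib.pyplot as plt

        from .geometry import project_to_cross_section

        g = self.geometry
        q = project_to_cross_section(self.model.points, g)
        c = g.center2d
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(q[:, 0], q[:, 1], s=4, alpha=0.6, label="points")
        theta = np.linspace(0, 2 * np.pi, 256)
        ax.plot(c[0] + g.radius * np.cos(theta), c[1] + g.radius * np.sin(theta), "r-", label="fit")
        ax.set_aspect("equal")
        ax.set_xlabel("e1 (m)")
        ax.set_ylabel("e2 (m)")
        ax.legend()
        return ax

    def __repr__(self) -> str:
        g = self.geometry
        return f"<CylinderFitResults {self.method}: r={g.radius:.4f} m, n={self.nobs}>"


def _fmt(x: float) -> str:
    return "" if np.isnan(x) else f"{x:.2e}"
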
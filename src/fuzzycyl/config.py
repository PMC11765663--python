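"""Run configuration: scanners, truth geometry and method settings from YAML.

Units on disk are meters; angle keys with a ``_deg`` suffix are degrees and
are converted to radians on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .fitting import FitConfig
from .geometry import CylinderGeometry
from .lidar import ScannerSpec

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulation/fit/evaluation run."""

    scanners: list[ScannerSpec] = field(default_factory=list)
    truth: CylinderGeometry | None = None
    fit: FitConfig = field(default_factory=FitConfig)
    seed: int = 0
    output: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        scanners = [ScannerSpec.from_dict(s) for s in d.get("scanners", [])]
        truth = None
        if "truth" in d:
            tr = d["truth"]
            truth = CylinderGeometry(
                radius=tr["radius_m"],
                azimuth=np.deg2rad(tr.get("azimuth_deg", 0.0)),
                elevation=np.deg2rad(tr.get("elevation_deg", 90.0)),
                center=np.asarray(tr.get("center_m", [0.0, 0.0, 0.0]), float),
                length=tr.get("length_m", 0.25),
            )
        fit_kw = {
            k: d[k]
            for k in (
                "tangent_lines",
                "max_updates",
                "geometry_tol",
                "normalize_weights",
                "ransac_max_subsets",
                "ransac_subset_size",
                "ransac_threshold_scale",
            )
            if k in d
        }
        return cls(
            scanners=scanners,
            truth=truth,
            fit=FitConfig(**fit_kw),
            seed=int(d.get("seed", 0)),
            output=d.get("output"),
        )

    def to_dict(self) -> dict:
        out = {
            "scanners": [s.to_dict() for s in self.scanners],
            "seed": int(self.seed),
            "tangent_lines": self.fit.tangent_lines,
            "max_updates": self.fit.max_updates,
            "geometry_tol": self.fit.geometry_tol,
            "normalize_weights": self.fit.normalize_weights,
            "ransac_max_subsets": self.fit.ransac_max_subsets,
        }
        if self.truth is not None:
            out["truth"] = {
                "radius_m": float(self.truth.radius),
                "azimuth_deg": float(np.rad2deg(self.truth.azimuth)),
                "elevation_deg": float(np.rad2deg(self.truth.elevation)),
                "center_m": [float(c) for c in self.truth.center],
                "length_m": float(self.truth.length),
            }
        if self.output:
            out["output"] = self.output
        return out


def load_config(path) -> RunConfig:
    with open(Path(path)) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)
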
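"""Point cloud and report file I/O.

Point clouds are read and written as XYZ text (3 or 4 whitespace-separated
columns: x y z [scanner_id], meters) or ASCII PLY with ``float x/y/z``
properties and an optional integer ``scanner_id`` property.  Reports are
JSON with a schema version; experiment reports additionally render as a CSV
table of the nu/sigma error summary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import PointCloudParseError
from .evaluation import ExperimentReport
from .fitting import FitResult

__all__ = ["read_point_cloud", "write_point_cloud", "write_report", "read_report"]

_FMT = "%.12g"


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("xyz", "txt", "csv"):
        return "xyz"
    if suffix == "ply":
        return "ply"
    raise ValueError(f"cannot infer point cloud format from {path.name!r}; pass fmt=")


def read_point_cloud(path, fmt: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Read a point cloud; returns ``(points (n,3), scanner_ids (n,))``.

    Missing scanner ids default to 0.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "ply":
        return _read_ply(path)
    raise ValueError(f"unsupported format {fmt!r}")


def write_point_cloud(path, points: np.ndarray, scanner_ids: np.ndarray | None = None, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if scanner_ids is None:
        scanner_ids = np.zeros(len(points), dtype=int)
    scanner_ids = np.asarray(scanner_ids, dtype=int).reshape(-1)
    if fmt == "xyz":
        _write_xyz(path, points, scanner_ids)
    elif fmt == "ply":
        _write_ply(path, points, scanner_ids)
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def _read_xyz(path: Path) -> tuple[np.ndarray, np.ndarray]:
    pts, ids = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) not in (3, 4):
                raise PointCloudParseError(
                    f"{path.name}:{lineno}: expected 3 or 4 columns, got {len(parts)}", record=lineno
                )
            try:
                xyz = [float(v) for v in parts[:3]]
                sid = int(float(parts[3])) if len(parts) == 4 else 0
            except ValueError as exc:
                raise PointCloudParseError(f"{path.name}:{lineno}: {exc}", record=lineno) from exc
            pts.append(xyz)
            ids.append(sid)
    if not pts:
        raise PointCloudParseError(f"{path.name}: no points found")
    return np.array(pts), np.array(ids, dtype=int)


def _write_xyz(path: Path, points: np.ndarray, ids: np.ndarray) -> None:
    with open(path, "w") as fh:
        for (x, y, z), sid in zip(points, ids):
            fh.write(f"{_FMT % x} {_FMT % y} {_FMT % z} {sid}\n")


def _write_ply(path: Path, points: np.ndarray, ids: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(points)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write("property int scanner_id\nend_header\n")
        for (x, y, z), sid in zip(points, ids):
            fh.write(f"{_FMT % x} {_FMT % y} {_FMT % z} {sid}\n")


def _read_ply(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal ASCII PLY vertex reader (x, y, z, optional scanner_id)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise PointCloudParseError(f"{path.name}: not a PLY file", record=1)
    n_vertex = None
    props: list[str] = []
    header_end = None
    in_vertex = False
    for i, line in enumerate(lines[1:], start=2):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            if tok[1] != "ascii":
                raise PointCloudParseError(f"{path.name}: only ASCII PLY is supported", record=i)
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                n_vertex = int(tok[2])
        elif tok[0] == "property" and in_vertex:
            props.append(tok[-1])
        elif tok[0] == "end_header":
            header_end = i
            break
    if n_vertex is None or header_end is None:
        raise PointCloudParseError(f"{path.name}: malformed PLY header")
    for name in ("x", "y", "z"):
        if name not in props:
            raise PointCloudParseError(f"{path.name}: missing vertex property {name!r}")
    ix, iy, iz = props.index("x"), props.index("y"), props.index("z")
    isid = props.index("scanner_id") if "scanner_id" in props else None
    pts = np.empty((n_vertex, 3))
    ids = np.zeros(n_vertex, dtype=int)
    body = lines[header_end : header_end + n_vertex]
    if len(body) < n_vertex:
        raise PointCloudParseError(f"{path.name}: expected {n_vertex} vertex records, found {len(body)}")
    for k, line in enumerate(body):
        tok = line.split()
        try:
            pts[k] = [float(tok[ix]), float(tok[iy]), float(tok[iz])]
            if isid is not None:
                ids[k] = int(float(tok[isid]))
        except (ValueError, IndexError) as exc:
            raise PointCloudParseError(f"{path.name}: bad vertex record {k}: {exc}", record=k) from exc
    return pts, ids


def write_report(report: ExperimentReport | FitResult, path, csv_path=None) -> None:
    """Serialize a fit result or experiment report to JSON (and CSV summary).

    The payload contains no timestamps, so identical runs produce
    byte-identical files.
    """
    path = Path(path)
    payload = report.to_dict()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    if isinstance(report, ExperimentReport) and csv_path is not None:
        report.to_table().to_csv(Path(csv_path), index_label="method")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
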
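"""File formats: PLY surfaces, marker/contour/trajectory CSV, JSON reports.

Surfaces are exchanged as PLY (ASCII or binary little-endian), the format
body scanners commonly export; coordinates are millimetres unless the
header carries a ``comment units <m|cm|mm>`` line, in which case they are
converted on read.  Markers and trajectories are plain CSV, reports and
ground truth JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .datatypes import (
    EmptyInputError,
    MarkerSet,
    MaskRegion,
    ParseError,
    SourceLabel,
    SpinalTrajectory,
    SurfaceScan,
    ValidationError,
)

__all__ = [
    "read_surface",
    "write_surface",
    "apply_mask",
    "read_markers",
    "write_markers",
    "read_contours",
    "write_contours",
    "read_trajectory",
    "write_trajectory",
    "write_report",
    "read_report",
]

_UNIT_SCALE = {"mm": 1.0, "cm": 10.0, "m": 1000.0}
_ALLOWED_FORMATS = ("ascii", "binary_little_endian")


def _validate_ply_header(path: Path) -> float:
    """Check the PLY header, returning the unit scale factor to mm.

    Raises :class:`ParseError` naming the offending line for malformed or
    unsupported headers, and :class:`EmptyInputError` for zero vertices.
    """
    scale = 1.0
    with open(path, "rb") as fh:
        first = fh.readline().strip()
        if first != b"ply":
            raise ParseError(f"{path}: not a PLY file (first line {first!r})")
        vertex_count = None
        vertex_props: list[str] = []
        in_vertex = False
        for raw in fh:
            line = raw.decode("ascii", errors="replace").strip()
            if line.startswith("format"):
                parts = line.split()
                if len(parts) < 2 or parts[1] not in _ALLOWED_FORMATS:
                    raise ParseError(
                        f"{path}: unsupported PLY encoding in header line {line!r}; "
                        f"only {_ALLOWED_FORMATS} are accepted"
                    )
            elif line.startswith("comment units"):
                unit = line.split()[-1]
                if unit not in _UNIT_SCALE:
                    raise ParseError(f"{path}: unknown unit in header line {line!r}")
                scale = _UNIT_SCALE[unit]
            elif line.startswith("element"):
                parts = line.split()
                if len(parts) != 3:
                    raise ParseError(f"{path}: malformed header line {line!r}")
                in_vertex = parts[1] == "vertex"
                if in_vertex:
                    vertex_count = int(parts[2])
            elif line.startswith("property") and in_vertex:
                vertex_props.append(line.split()[-1])
            elif line == "end_header":
                break
        if vertex_count is None:
            raise ParseError(f"{path}: header lacks an 'element vertex' line")
        if vertex_count == 0:
            raise EmptyInputError(f"{path}: PLY declares zero vertices")
        for needed in ("x", "y", "z"):
            if needed not in vertex_props:
                raise ParseError(f"{path}: vertex element lacks property {needed!r}")
    return scale


def read_surface(path) -> SurfaceScan:
    """Read a PLY surface (ASCII or binary little-endian) into mm."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    scale = _validate_ply_header(path)
    loaded = trimesh.load(str(path), file_type="ply", process=False)
    vertices = np.asarray(loaded.vertices, dtype=float) * scale
    faces = np.asarray(loaded.faces, dtype=np.int64) if hasattr(loaded, "faces") else None
    if faces is not None and len(faces) == 0:
        faces = None
    if len(vertices) == 0:
        raise EmptyInputError(f"{path}: no vertices")
    return SurfaceScan(vertices=vertices, faces=faces, provenance=str(path))


def write_surface(scan: SurfaceScan, path, binary: bool = False) -> None:
    """Write a scan as PLY with double-precision coordinates (mm).

    Double rather than single precision vertex properties, so that write /
    read round trips preserve coordinates beyond 1e-6 mm at torso scale.
    """
    path = Path(path)
    nv = len(scan.vertices)
    nf = 0 if scan.faces is None else len(scan.faces)
    header = ["ply"]
    header.append("format binary_little_endian 1.0" if binary else "format ascii 1.0")
    header.append("comment units mm")
    header.append(f"element vertex {nv}")
    header += [f"property double {c}" for c in "xyz"]
    if nf:
        header.append(f"element face {nf}")
        header.append("property list uchar int vertex_indices")
    header.append("end_header")
    if binary:
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            fh.write(np.ascontiguousarray(scan.vertices, dtype="<f8").tobytes())
            if nf:
                counts = np.full((nf, 1), 3, dtype=np.uint8)
                idx = np.ascontiguousarray(scan.faces, dtype="<i4")
                rows = b"".join(
                    counts[i].tobytes() + idx[i].tobytes() for i in range(nf)
                )
                fh.write(rows)
    else:
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            for v in scan.vertices:
                fh.write(f"{v[0]:.10g} {v[1]:.10g} {v[2]:.10g}\n")
            if nf:
                for f in scan.faces:
                    fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def apply_mask(scan: SurfaceScan, mask: MaskRegion) -> SurfaceScan:
    """Remove the vertices inside the mask region (e.g. arms, waist band).

    Returns a new scan containing exactly the vertices outside the mask;
    faces referencing removed vertices are dropped.  Idempotent, and raises
    :class:`EmptyInputError` if nothing would remain.
    """
    inside = mask.contains(scan.vertices)
    keep = ~inside
    if not keep.any():
        raise EmptyInputError("mask removes every vertex of the scan")
    if not inside.any():
        return SurfaceScan(
            vertices=scan.vertices.copy(),
            faces=None if scan.faces is None else scan.faces.copy(),
            provenance=scan.provenance,
        )
    new_index = np.cumsum(keep) - 1
    faces = None
    if scan.faces is not None:
        ok = keep[scan.faces].all(axis=1)
        faces = new_index[scan.faces[ok]]
        if len(faces) == 0:
            faces = None
    return SurfaceScan(vertices=scan.vertices[keep], faces=faces, provenance=scan.provenance)


def _numeric_frame(path, columns) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing CSV columns {missing}")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based incl. header
            raise ParseError(f"{path}: non-numeric value in column {col!r} at line {row}")
        df[col] = converted
    return df


def read_markers(path) -> MarkerSet:
    """Read markers from CSV with columns level_mm, x_mm[, y_mm]."""
    df = _numeric_frame(path, ["level_mm", "x_mm"])
    y = df["y_mm"].to_numpy() if "y_mm" in df.columns else None
    return MarkerSet(levels=df["level_mm"].to_numpy(), x=df["x_mm"].to_numpy(), y=y)


def write_markers(markers: MarkerSet, path) -> None:
    data = {"level_mm": markers.levels, "x_mm": markers.x}
    if markers.y is not None:
        data["y_mm"] = markers.y
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6g")


def write_contours(contours, path) -> None:
    """Write a contour stack as CSV (level_mm, point_index, x_mm, y_mm)."""
    rows = []
    for c in contours:
        for i, (x, y) in enumerate(c.points):
            rows.append((c.level, i, x, y))
    pd.DataFrame(rows, columns=["level_mm", "point_index", "x_mm", "y_mm"]).to_csv(
        path, index=False, float_format="%.6g"
    )


def read_contours(path) -> list:
    from .datatypes import ContourLine

    df = _numeric_frame(path, ["level_mm", "point_index", "x_mm", "y_mm"])
    contours = []
    for level, grp in df.groupby("level_mm", sort=True):
        grp = grp.sort_values("point_index")
        contours.append(
            ContourLine(level=float(level), points=grp[["x_mm", "y_mm"]].to_numpy())
        )
    return contours


def write_trajectory(traj: SpinalTrajectory, path) -> None:
    pd.DataFrame(
        {
            "level_mm": traj.points[:, 2],
            "x_mm": traj.points[:, 0],
            "y_mm": traj.points[:, 1],
            "source": traj.source_label.value,
        }
    ).to_csv(path, index=False, float_format="%.6g")


def read_trajectory(path) -> SpinalTrajectory:
    raw = pd.read_csv(path)
    for needed in ("level_mm", "x_mm"):
        if needed not in raw.columns:
            raise ParseError(f"{path}: missing CSV column {needed!r}")
    label = SourceLabel.OTHER
    if "source" in raw.columns and len(raw):
        try:
            label = SourceLabel(str(raw["source"].iloc[0]))
        except ValueError:
            label = SourceLabel.OTHER
        raw = raw.drop(columns=["source"])
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 2
            raise ParseError(f"{path}: non-numeric value in column {col!r} at line {row}")
        raw[col] = converted
    y = raw["y_mm"].to_numpy() if "y_mm" in raw.columns else np.zeros(len(raw))
    pts = np.column_stack([raw["x_mm"].to_numpy(), y, raw["level_mm"].to_numpy()])
    return SpinalTrajectory(points=pts, source_label=label)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "value") and not isinstance(obj, (int, float, str, bool)):
        return obj.value  # enums
    return obj


def write_report(report: dict, path) -> None:
    """Serialize an analysis report (fit coefficients, included angles,
    per-slice sector areas and offsets, match results, severity class)."""
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
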
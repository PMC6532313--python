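"""Four-sector partition of a transverse contour and the lateral offset
correction of the dip position.

A partially rotated vertebral column makes the two dorsally convex rib-cage
arches asymmetric around the median without necessarily moving the posterior
dip.  The lateral position of the vertebral body is therefore estimated by
shifting the dip by an empirical offset derived from the imbalance of four
sector areas: the contour interior is split by two crosslines — the lateral
separation line through the dip, parallel to the mid-sagittal axis, and the
anterior-posterior separation line perpendicular to it at a distance ``d``
anterior of the dip — into two anterior sectors (A, B) and two posterior
sectors (C, D), with A and C on the patient's right.  Sector areas are the
convex-hull areas of each sector's points (Gauss's area formula), and

    x_off = ((A - B)/(A + B) + (C - D)/(C + D)) * R_omega,

where R_omega is the remaining width between the dip and the intersection of
the anterior-posterior separation line with the body contour on the side the
imbalance points to.  x_off > 0 means the vertebral body is rotated toward
the patient's right; a symmetric contour gives x_off = 0.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .datatypes import (
    ContourLine,
    DegenerateSectorError,
    DipEstimate,
    ReflectionAxis,
    SectorPartition,
    ValidationError,
    VertebralMarker,
)

__all__ = ["polygon_area", "partition_sectors", "compute_offset", "correct_marker"]


def shoelace_area(vertices: np.ndarray) -> float:
    """Absolute Gauss (shoelace) area of an ordered polygon."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return abs(0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def polygon_area(points) -> float:
    """Convex-hull area of a 2D point set by the shoelace formula.

    Parameters
    ----------
    points : (N, 2) array_like, N >= 3 and not all collinear.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or len(p) < 3:
        raise ValidationError("polygon_area needs at least 3 two-dimensional points")
    try:
        hull = ConvexHull(p)
    except QhullError as exc:
        raise ValidationError(f"degenerate point set for area computation: {exc}") from exc
    return shoelace_area(p[hull.vertices])


def _line_crossings(pts: np.ndarray, coord: int, value: float) -> np.ndarray:
    """Intersection points of a closed polyline with the line {coord == value}."""
    a = pts
    b = np.roll(pts, -1, axis=0)
    fa = a[:, coord] - value
    fb = b[:, coord] - value
    cross = (fa * fb) < 0
    out = []
    for i in np.nonzero(cross)[0]:
        t = fa[i] / (fa[i] - fb[i])
        out.append(a[i] + t * (b[i] - a[i]))
    on = np.isclose(fa, 0.0, atol=1e-12)
    if on.any():
        out.extend(a[on])
    return np.asarray(out).reshape(-1, 2)


def partition_sectors(
    contour: ContourLine,
    dip,
    axis: ReflectionAxis | None = None,
    d: float = 50.0,
) -> SectorPartition:
    """Split a contour into the four sectors around the dip and measure areas.

    The partition is computed in the axis-aligned frame: the contour is
    rotated so the reflection axis points anterior (+y) with the dip at the
    origin.  Points exactly on a separation line break ties toward the
    +x / anterior sector.

    Raises
    ------
    DegenerateSectorError
        if any sector holds fewer than 3 points (the slice should be flagged
        rather than silently dropped).
    """
    if axis is None:
        axis = ReflectionAxis()
    dip = np.asarray(dip, dtype=float)
    if d <= 0:
        raise ValidationError("separation distance d must be positive")
    t = np.deg2rad(axis.angle_deg)
    # rotate by +t so the axis direction (sin t, cos t) maps onto (0, 1)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    local = (contour.points - dip) @ rot.T

    y_extent = local[:, 1].max()
    if d >= y_extent:
        raise ValidationError(
            f"separation distance d={d} exceeds the anterior extent "
            f"({y_extent:.1f} mm) of the contour at the dip"
        )

    centre = np.array([0.0, d])
    x, y = local[:, 0], local[:, 1]
    right = x >= 0.0  # tie toward +x
    anterior = y >= d  # tie toward anterior
    quadrants = {
        "A": local[right & anterior],
        "B": local[~right & anterior],
        "C": local[right & ~anterior],
        "D": local[~right & ~anterior],
    }

    lat_cross = _line_crossings(local, 0, 0.0)  # on the lateral separation line
    ap_cross = _line_crossings(local, 1, d)  # on the anterior-posterior line

    def augment(name: str) -> np.ndarray:
        pts = [quadrants[name], centre[None, :]]
        if len(lat_cross):
            sel = lat_cross[:, 1] >= d if name in ("A", "B") else lat_cross[:, 1] < d
            pts.append(lat_cross[sel])
        if len(ap_cross):
            sel = ap_cross[:, 0] >= 0 if name in ("A", "C") else ap_cross[:, 0] < 0
            pts.append(ap_cross[sel])
        return np.vstack([p for p in pts if len(p)])

    areas = {}
    for name in "ABCD":
        pts = augment(name)
        if len(quadrants[name]) < 3:
            raise DegenerateSectorError(
                f"sector {name} has only {len(quadrants[name])} contour points"
            )
        areas[name] = polygon_area(pts)

    A, B, C, D = areas["A"], areas["B"], areas["C"], areas["D"]
    imbalance = (A - B) / (A + B) + (C - D) / (C + D) if (A + B) > 0 and (C + D) > 0 else 0.0

    # remaining width on the side the imbalance points to (ties: +x side)
    if len(ap_cross) == 0:
        raise DegenerateSectorError("anterior-posterior separation line misses the contour")
    side_right = imbalance >= 0
    sel = ap_cross[:, 0] >= 0 if side_right else ap_cross[:, 0] < 0
    if not sel.any():
        sel = ~sel  # fall back to the other side rather than failing
    R_omega = float(np.max(np.abs(ap_cross[sel, 0])))
    if R_omega <= 0:
        raise DegenerateSectorError("zero remaining width R_omega")

    return SectorPartition(d=d, dip=dip, A=A, B=B, C=C, D=D, R_omega=R_omega)


def compute_offset(partition: SectorPartition, grouping: str = "sum") -> float:
    """Lateral offset x_off (mm) of the vertebral body from the dip.

    ``grouping`` selects how R_omega enters the published formula, whose
    typography is ambiguous: ``"sum"`` (default) scales the sum of both
    normalized imbalances, ``"second-term"`` scales only the posterior one.
    """
    A, B, C, D = partition.A, partition.B, partition.C, partition.D
    if (A + B) <= 0 or (C + D) <= 0:
        raise DegenerateSectorError("sector area sums must be positive")
    ant = (A - B) / (A + B)
    post = (C - D) / (C + D)
    if grouping == "sum":
        return (ant + post) * partition.R_omega
    if grouping == "second-term":
        return ant + post * partition.R_omega
    raise ValidationError(f"unknown grouping {grouping!r}")


def correct_marker(dip: DipEstimate, x_off: float, level: float) -> VertebralMarker:
    """Shift the dip laterally by ``x_off`` to estimate the vertebral-body
    position at ``level``; both the raw dip and the corrected point are kept."""
    return VertebralMarker(level=float(level), dip_position=dip.position, x_off=float(x_off))
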
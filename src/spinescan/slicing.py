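"""Transverse slicing of a torso scan into closed 2D contour lines.

Slices are taken at user-chosen levels along the vertical torso axis; ten
to fifteen regularly spaced levels over the lumbar and thoracic section are
usually enough to capture the spine trajectory.  When the scan carries
triangles, the contour is the exact mesh/plane intersection; for raw point
clouds, the vertices inside a thin slab are projected onto the plane and
ordered into a polygon.
"""

from __future__ import annotations

import numpy as np
import shapely
import trimesh

from .datatypes import (
    ContourLine,
    EmptySliceError,
    FragmentedContourError,
    SlicePlan,
    SurfaceScan,
    ValidationError,
)

__all__ = ["plan_levels", "extract_slice", "order_contour", "resample_contour", "slice_scan"]

DEFAULT_THICKNESS = 2.0  # slab half-width (mm) for point-cloud slicing
DEFAULT_MAX_GAP = 15.0  # mm; larger gaps indicate a fragmented slice


def plan_levels(z_min: float, z_max: float, count: int, thickness: float = DEFAULT_THICKNESS) -> SlicePlan:
    """Equally spaced slice levels inclusive of both ends."""
    if count < 2:
        raise ValidationError("a slice plan needs at least 2 levels")
    if not z_min < z_max:
        raise ValidationError("z_min must be below z_max")
    return SlicePlan(levels=np.linspace(z_min, z_max, count), thickness=thickness)


def extract_slice(scan: SurfaceScan, level: float, thickness: float = DEFAULT_THICKNESS) -> np.ndarray:
    """2D point set of one transverse cut at ``level``.

    With faces present the points are mesh-edge/plane intersections exactly
    at z = level; otherwise all vertices with |z - level| <= thickness are
    projected onto the plane.
    """
    lo, hi = scan.z_range
    if not (lo - thickness <= level <= hi + thickness):
        raise EmptySliceError(f"slice level {level} mm outside scan z-range [{lo:.1f}, {hi:.1f}]")
    if scan.faces is not None:
        mesh = trimesh.Trimesh(vertices=scan.vertices, faces=scan.faces, process=False)
        section = mesh.section(plane_origin=[0.0, 0.0, level], plane_normal=[0.0, 0.0, 1.0])
        if section is None or len(section.vertices) == 0:
            raise EmptySliceError(f"no mesh intersection at level {level} mm")
        return np.asarray(section.vertices)[:, :2]
    mask = np.abs(scan.vertices[:, 2] - level) <= thickness
    pts = scan.vertices[mask][:, :2]
    if len(pts) < 8:
        raise EmptySliceError(f"only {len(pts)} points in slab at level {level} mm")
    return pts


def _angular_order(points: np.ndarray) -> np.ndarray:
    c = points.mean(axis=0)
    ang = np.arctan2(points[:, 1] - c[1], points[:, 0] - c[0])
    return points[np.argsort(ang, kind="stable")]


def _nearest_neighbour_chain(points: np.ndarray) -> np.ndarray:
    """Greedy nearest-neighbour ordering, used to repair slices for which a
    plain angular sort is invalid (non-star-shaped contours)."""
    from scipy.spatial import cKDTree

    n = len(points)
    tree = cKDTree(points)
    visited = np.zeros(n, dtype=bool)
    order = [int(np.argmin(points[:, 1]))]  # start posterior
    visited[order[0]] = True
    for _ in range(n - 1):
        cur = points[order[-1]]
        k = 2
        while True:
            dist, idx = tree.query(cur, k=min(k, n))
            idx = np.atleast_1d(idx)
            free = [i for i in idx if not visited[i]]
            if free:
                order.append(int(free[0]))
                visited[free[0]] = True
                break
            if k >= n:
                break
            k = min(2 * k, n)
    return points[order]


def _is_simple(points: np.ndarray) -> bool:
    return shapely.Polygon(points).is_simple


def order_contour(points: np.ndarray, max_gap: float = DEFAULT_MAX_GAP) -> ContourLine:
    """Order an unstructured transverse point set into a closed CCW polygon.

    An angular sort around the centroid is tried first and repaired with a
    greedy nearest-neighbour chain if the result self-intersects.  A gap
    between consecutive ordered points larger than ``max_gap`` indicates a
    fragmented slice (e.g. arms inside the slab) and raises.
    """
    pts = np.asarray(points, dtype=float)
    pts = np.unique(pts, axis=0)
    if len(pts) < 8:
        raise ValidationError("contour ordering needs at least 8 distinct points")
    span = pts.max(axis=0) - pts.min(axis=0)
    if min(span) < 1e-9:
        raise ValidationError("contour points are collinear")

    ordered = _angular_order(pts)
    if not _is_simple(ordered):
        ordered = _nearest_neighbour_chain(pts)

    gaps = np.linalg.norm(np.roll(ordered, -1, axis=0) - ordered, axis=1)
    if gaps.max() > max_gap:
        raise FragmentedContourError(
            f"largest gap {gaps.max():.1f} mm exceeds max-gap {max_gap} mm; "
            "slice appears fragmented"
        )

    contour = ContourLine(level=0.0, points=ordered)
    if contour.signed_area() < 0:  # enforce counter-clockwise orientation
        contour.points = contour.points[::-1].copy()
    return contour


def resample_contour(contour: ContourLine, n: int) -> ContourLine:
    """Resample a closed contour to ``n`` points equally spaced in arc length."""
    if n < 16:
        raise ValidationError("resampling needs n >= 16")
    pts = contour.points
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValidationError("cannot resample a zero-perimeter contour")
    targets = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    return ContourLine(level=contour.level, points=np.column_stack([x, y]))


def smooth_contour(contour: ContourLine, window: int) -> ContourLine:
    """Circular moving-average smoothing of a closed contour.

    Suppresses scanner/vertex noise before feature detection; the window is
    in points (odd), small relative to the dip width so anatomical features
    survive.
    """
    if window <= 1:
        return contour
    if window % 2 == 0:
        window += 1
    k = np.ones(window) / window
    pts = contour.points
    pad = window // 2
    ext = np.vstack([pts[-pad:], pts, pts[:pad]])
    sm = np.column_stack(
        [np.convolve(ext[:, 0], k, mode="valid"), np.convolve(ext[:, 1], k, mode="valid")]
    )
    return ContourLine(level=contour.level, points=sm)


def slice_scan(
    scan: SurfaceScan,
    plan: SlicePlan,
    n_resample: int = 512,
    max_gap: float = DEFAULT_MAX_GAP,
) -> list[ContourLine]:
    """Extract, order and resample one contour per planned level."""
    contours = []
    for level in plan.levels:
        pts = extract_slice(scan, float(level), plan.thickness)
        contour = order_contour(pts, max_gap=max_gap)
        contour = resample_contour(contour, n_resample)
        contour.level = float(level)
        contours.append(contour)
    return contours
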
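"""Vertebral-column trajectory assembly, polynomial fitting of its coronal
projection, included angles at inflexion points, lateral deviation, and
repeat-measurement spread.

The coronal projection x(z) is fitted with a 1D polynomial of user-chosen
degree n = 1..7: n = 2, 3, 4 describe single (C-type), double (S-type) and
triple curved spines.  Curvature is summarized by the included angles
between the curve normals at adjacent evaluation knots, the knots being the
curve endpoints plus any real inflexion levels inside the data range.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.polynomial import polynomial as P

from .datatypes import (
    DeviationSummary,
    MarkerSet,
    PolynomialFit,
    SourceLabel,
    SpinalTrajectory,
    ValidationError,
    VertebralMarker,
)
from .clinical import classify_deviation

__all__ = [
    "assemble",
    "fit_polynomial",
    "included_angles",
    "lateral_deviation",
    "trajectory_spread",
]


def assemble(
    markers: Sequence[VertebralMarker] | MarkerSet,
    source_label: SourceLabel = SourceLabel.OTHER,
    use_corrected: bool = True,
) -> SpinalTrajectory:
    """Build a z-sorted 3D trajectory from per-level markers.

    For :class:`VertebralMarker` inputs, ``use_corrected`` selects the
    offset-corrected lateral positions (default) or the raw dip positions,
    so both the dip-derived and the corrected trajectory remain available.
    """
    if isinstance(markers, MarkerSet):
        y = markers.y if markers.y is not None else np.zeros_like(markers.x)
        pts = np.column_stack([markers.x, y, markers.levels])
        label = markers.source_label if source_label is SourceLabel.OTHER else source_label
        return SpinalTrajectory(points=pts, source_label=label)
    rows = []
    for m in markers:
        xy = m.corrected_position if use_corrected else m.dip_position
        rows.append([xy[0], xy[1], m.level])
    if len(rows) < 2:
        raise ValidationError("need at least 2 markers to assemble a trajectory")
    pts = np.asarray(rows, dtype=float)
    order = np.argsort(pts[:, 2], kind="stable")
    pts = pts[order]
    if np.any(np.diff(pts[:, 2]) <= 0):
        raise ValidationError("duplicate marker levels")
    return SpinalTrajectory(points=pts, source_label=source_label)


def fit_polynomial(traj: SpinalTrajectory, degree: int) -> PolynomialFit:
    """Least-squares polynomial fit x(z) to the coronal projection.

    Degree must be in 1..7 and the trajectory must have more points than
    the degree.  Inflexion levels (real roots of x'' inside the data range)
    and the included angles are filled in.
    """
    if not 1 <= degree <= 7:
        raise ValidationError("polynomial degree must be in 1..7")
    if len(traj) <= degree:
        raise ValidationError(
            f"degree-{degree} fit needs at least {degree + 1} points, got {len(traj)}"
        )
    z = traj.z
    x = traj.points[:, 0]
    # fit in a scaled domain for conditioning, then convert to plain powers of z
    series = np.polynomial.Polynomial.fit(z, x, degree)
    coeffs = series.convert().coef
    coeffs = np.pad(coeffs, (0, degree + 1 - len(coeffs)))
    resid = x - P.polyval(z, coeffs)
    fit = PolynomialFit(
        degree=degree,
        coefficients=coeffs,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        z_min=float(z.min()),
        z_max=float(z.max()),
    )
    fit.inflexion_levels = _inflexion_levels(fit)
    fit.included_angles = included_angles(fit)
    return fit


def _inflexion_levels(fit: PolynomialFit) -> np.ndarray:
    """Real roots of the second derivative strictly inside the data range."""
    c2 = P.polyder(fit.coefficients, 2)
    c2 = np.trim_zeros(c2, "b")
    if len(c2) <= 1:
        return np.empty(0)
    roots = P.polyroots(c2)
    real = roots[np.abs(roots.imag) < 1e-9].real
    eps = 1e-9 * max(1.0, abs(fit.z_max - fit.z_min))
    inside = real[(real > fit.z_min + eps) & (real < fit.z_max - eps)]
    return np.sort(np.unique(np.round(inside, 12)))


def included_angles(fit: PolynomialFit) -> np.ndarray:
    """Angles (degrees) between curve normals at adjacent evaluation knots.

    Knots are the lower endpoint, the inflexion levels inside the data
    range, and the upper endpoint; the angle between the normals equals the
    angle between the tangents, |atan m1 - atan m2|.  A straight line gives
    a single angle of 0.
    """
    knots = np.concatenate([[fit.z_min], _inflexion_levels(fit), [fit.z_max]])
    slopes = fit.derivative(knots)
    theta = np.arctan(slopes)
    return np.abs(np.degrees(np.diff(theta)))


def _chord_distance(xz: np.ndarray) -> float:
    """Max perpendicular distance of sampled coronal points from the chord
    joining the first and last point."""
    a, b = xz[0], xz[-1]
    chord = b - a
    norm = np.linalg.norm(chord)
    if norm == 0:
        raise ValidationError("degenerate trajectory: coincident endpoints")
    v = xz - a
    cross = np.abs(v[:, 0] * chord[1] - v[:, 1] * chord[0]) / norm
    return float(cross.max())


def lateral_deviation(obj: SpinalTrajectory | PolynomialFit, n_samples: int = 512) -> DeviationSummary:
    """Maximum lateral deviation (mm) of the coronal curve from its endpoint
    chord, with the mild/moderate/strong severity class."""
    if isinstance(obj, PolynomialFit):
        z = np.linspace(obj.z_min, obj.z_max, n_samples)
        xz = np.column_stack([obj(z), z])
    else:
        xz = obj.coronal
    dev = _chord_distance(xz)
    return DeviationSummary(max_lateral_deviation=dev, severity=classify_deviation(dev))


def trajectory_spread(
    trajectories: Iterable[SpinalTrajectory], n_levels: int = 50
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-level lateral standard deviation across repeat trajectories.

    Each trajectory's x(z) is linearly interpolated onto a common grid over
    the overlapping z-range.  Returns (grid levels, per-level SD, max SD).
    """
    trajs = list(trajectories)
    if len(trajs) < 2:
        raise ValidationError("spread needs at least 2 trajectories")
    lo = max(t.z.min() for t in trajs)
    hi = min(t.z.max() for t in trajs)
    if lo >= hi:
        raise ValidationError("trajectories have no overlapping z-range")
    grid = np.linspace(lo, hi, n_levels)
    X = np.vstack([np.interp(grid, t.z, t.points[:, 0]) for t in trajs])
    sd = X.std(axis=0, ddof=1)
    return grid, sd, float(sd.max())
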
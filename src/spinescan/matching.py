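"""Constrained rigid matching of two coronal spine trajectories.

Two trajectories (e.g. one derived from contour dips and one from
vertebral-body centres) are compared by an in-plane rigid transform: an
unconstrained translation plus a rotation about the moving curve's centre
point, limited to -45 deg < alpha < +45 deg so that an upside-down match is
impossible.  Correspondence is point-to-point at equal normalized level,
and the optimality value is the mean squared residual distance after the
optimal alignment — lower means better agreement.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .datatypes import MatchResult, PolynomialFit, SpinalTrajectory, ValidationError

__all__ = ["sample_coronal", "match_curves", "optimality_table"]

ALPHA_BOUND_DEG = 45.0
_BOUND_EPS = 1e-6


def sample_coronal(curve: SpinalTrajectory | PolynomialFit, n_samples: int) -> np.ndarray:
    """Sample a coronal curve at ``n_samples`` points uniform in normalized
    level, returning (x, z) pairs."""
    if n_samples < 10:
        raise ValidationError("need at least 10 sample points")
    s = np.linspace(0.0, 1.0, n_samples)
    if isinstance(curve, PolynomialFit):
        z = curve.z_min + s * (curve.z_max - curve.z_min)
        return np.column_stack([curve(z), z])
    z = curve.z.min() + s * (curve.z.max() - curve.z.min())
    return np.column_stack([np.interp(z, curve.z, curve.points[:, 0]), z])


def _transform(points: np.ndarray, centre: np.ndarray, t: np.ndarray, alpha_rad: float) -> np.ndarray:
    c, s = np.cos(alpha_rad), np.sin(alpha_rad)
    rot = np.array([[c, -s], [s, c]])
    return centre + (points - centre) @ rot.T + t


def match_curves(
    moving: SpinalTrajectory | PolynomialFit,
    fixed: SpinalTrajectory | PolynomialFit,
    n_samples: int = 50,
) -> MatchResult:
    """Rigidly match ``moving`` onto ``fixed`` and score the agreement.

    The optimizer is a bounded least-squares fit over (tx, ty, alpha),
    multi-started at alpha in {-30, 0, +30} degrees; the rotation is applied
    about the moving curve's centre point (the sample at normalized level
    0.5).  Returns the transform, the per-point residual distances and the
    optimality value (mean squared residual, mm^2).
    """
    mov = sample_coronal(moving, n_samples)
    fix = sample_coronal(fixed, n_samples)
    centre = mov[len(mov) // 2].copy()

    def residuals(params: np.ndarray) -> np.ndarray:
        t, alpha = params[:2], params[2]
        return (_transform(mov, centre, t, alpha) - fix).ravel()

    bound = np.deg2rad(ALPHA_BOUND_DEG) - _BOUND_EPS
    lower = [-np.inf, -np.inf, -bound]
    upper = [np.inf, np.inf, bound]

    best = None
    any_converged = False
    for alpha0 in np.deg2rad([-30.0, 0.0, 30.0]):
        t0 = fix.mean(axis=0) - mov.mean(axis=0)
        res = least_squares(
            residuals,
            x0=[t0[0], t0[1], alpha0],
            bounds=(lower, upper),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        any_converged = any_converged or res.success
        if best is None or res.cost < best.cost:
            best = res

    t_opt, alpha_opt = best.x[:2], best.x[2]
    dists = np.linalg.norm(_transform(mov, centre, t_opt, alpha_opt) - fix, axis=1)
    return MatchResult(
        translation=(float(t_opt[0]), float(t_opt[1])),
        rotation_alpha=float(np.degrees(alpha_opt)),
        optimality=float(np.mean(dists**2)),
        residuals=dists,
        converged=bool(any_converged),
    )


def optimality_table(
    matches: Sequence[MatchResult], groups: Sequence[str]
) -> dict[str, dict[str, float]]:
    """Mean optimality per severity group, on linear and log10 scale.

    Groups with no members are omitted; zero means get ``-inf`` on the log
    scale.
    """
    if len(matches) != len(groups):
        raise ValidationError("matches and group labels must align")
    table: dict[str, dict[str, float]] = {}
    for label in dict.fromkeys(groups):  # preserve first-seen order
        vals = np.array([m.optimality for m, g in zip(matches, groups) if g == label])
        if len(vals) == 0:
            continue
        mean = float(vals.mean())
        table[label] = {
            "mean_optimality": mean,
            "log10_mean_optimality": float(np.log10(mean)) if mean > 0 else float("-inf"),
            "n": int(len(vals)),
        }
    return table
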
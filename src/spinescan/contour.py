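"""Analysis of a single transverse contour line.

The analysis starts from the characteristic dip along the median of the
back, assumed to coincide with the tip of the spinous process.  The natural
left/right symmetry of the torso around the mid-sagittal plane is then
exploited: a near-sagittal reflection axis is fitted so that the healthy
half of the contour, mirrored across the axis, best overlays the
pathological half where the latter is not distorted.  The area enclosed
between the reflected healthy half and the pathological half quantifies the
asymmetry of the slice.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.signal import find_peaks
from scipy.spatial import cKDTree

from .datatypes import (
    ContourLine,
    DipConfidence,
    DipEstimate,
    ReflectionAxis,
    Side,
    SymmetryResult,
    ValidationError,
)
from .sectors import polygon_area

__all__ = [
    "detect_dip",
    "fit_reflection_axis",
    "reflect_points",
    "reflect_side",
    "split_halves",
    "asymmetry_area",
    "resample_polyline",
]

POSTERIOR_AZIMUTH = -np.pi / 2  # -y direction: the median of the back

DEFAULT_SEARCH_WINDOW = 0.4  # fraction of arc length searched for the dip
DEFAULT_DEPTH_THRESHOLD = 1.0  # mm; shallower indentations are "none"
DEFAULT_TRIM_QUANTILE = 0.70  # fraction of best point matches kept in axis fit


def _smooth_circular(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    if window % 2 == 0:
        window += 1
    kernel = np.ones(window) / window
    padded = np.concatenate([values[-(window // 2):], values, values[: window // 2]])
    return np.convolve(padded, kernel, mode="valid")


def detect_dip(
    contour: ContourLine,
    search_window: float = DEFAULT_SEARCH_WINDOW,
    depth_threshold: float = DEFAULT_DEPTH_THRESHOLD,
    smooth_window: int = 1,
) -> DipEstimate:
    """Locate the posterior dip (spinous-process tip) on a closed contour.

    The contour is scanned over the posterior window (``search_window`` of
    the total arc length, centred on the -y azimuth from the centroid) for
    the deepest local indentation of the posterior extent, i.e. a local
    maximum of y along the arc.  The dip centre is refined as the centroid
    of the baseline-subtracted indentation, and its depth is measured
    against a local polynomial baseline fitted to the profile with the
    indentation excluded — the depth relative to the undisturbed posterior
    arch.  Confidence is ``none`` when no indentation reaches
    ``depth_threshold`` (mm), ``clear`` when the depth exceeds twice the
    threshold, otherwise ``weak``.

    ``smooth_window`` (odd, in points) applies a circular moving average to
    the profile before peak finding; useful on noisy scans.
    """
    if not contour.closed:
        raise ValidationError("dip detection requires a closed contour")
    if not 0.05 <= search_window <= 1.0:
        raise ValidationError("search window must be a fraction in [0.05, 1]")
    pts = contour.points
    n = len(pts)
    c = pts.mean(axis=0)
    rel = pts - c
    phi = np.arctan2(rel[:, 1], rel[:, 0])

    # contiguous circular window of indices centred on the posterior azimuth
    centre_idx = int(np.argmin(np.abs(np.angle(np.exp(1j * (phi - POSTERIOR_AZIMUTH))))))
    half = max(3, int(round(search_window * n / 2)))
    window_idx = (np.arange(centre_idx - half, centre_idx + half + 1)) % n

    # the dip is an indentation toward anterior: a local maximum of y along
    # the posterior arc (a local minimum of the posterior extent -y)
    y_win = _smooth_circular(pts[:, 1], smooth_window)[window_idx]
    signal = y_win
    m = len(window_idx)

    def local_extent(peak: int) -> tuple[int, int, float]:
        """Adjacent valleys of a peak and the raw indentation depth."""
        lb = peak
        while lb > 0 and signal[lb - 1] <= signal[lb]:
            lb -= 1
        rb = peak
        while rb < m - 1 and signal[rb + 1] <= signal[rb]:
            rb += 1
        return lb, rb, float(signal[peak] - max(signal[lb], signal[rb]))

    peaks, _ = find_peaks(signal)
    peaks = peaks[(peaks > 1) & (peaks < m - 2)]  # window edges are not local
    if len(peaks) == 0:
        pole = pts[centre_idx]
        return DipEstimate(position=pole, depth=0.0, confidence=DipConfidence.NONE)
    raw = [local_extent(p) for p in peaks]
    order = int(np.argmax([r[2] for r in raw]))
    best = int(peaks[order])
    left_base, right_base, raw_depth = raw[order]

    # sub-sample peak location: parabola through the peak triple
    frac = 0.0
    y0, y1, y2 = signal[best - 1], signal[best], signal[best + 1]
    denom = y0 - 2 * y1 + y2
    if abs(denom) > 1e-15:
        frac = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
    centre_f = best + frac

    # baseline of the undisturbed posterior arch: polynomial fit over a
    # local neighbourhood with the indentation itself excluded (the arch is
    # flat-bottomed, so a quartic is used when enough support points exist)
    depth = raw_depth
    halfw = max(right_base - best, best - left_base, 2)
    lo = max(0, best - 3 * halfw)
    hi = min(m, best + 3 * halfw + 1)
    idx = np.arange(lo, hi, dtype=float)
    inside = (idx > left_base) & (idx < right_base)
    n_support = int((~inside).sum())
    if n_support >= 6:
        deg = 4 if n_support >= 12 else 2
        coef = np.polynomial.polynomial.polyfit(idx[~inside], signal[lo:hi][~inside], deg)
        # refine the dip centre as the centroid of the top half of the
        # baseline-subtracted indentation (noise-robust versus the 3-point
        # parabola, yet insensitive to skew of the indentation tails), then
        # re-evaluate the depth there
        core = np.arange(left_base, right_base + 1)
        excess = signal[core] - np.polynomial.polynomial.polyval(core.astype(float), coef)
        weights = np.clip(excess - 0.5 * excess.max(), 0.0, None)
        if weights.sum() > 0:
            centre_f = float(np.sum(core * weights) / weights.sum())
        baseline = float(np.polynomial.polynomial.polyval(centre_f, coef))
        y_at = float(np.interp(centre_f, np.arange(m), signal))
        fitted_depth = y_at - baseline
        if fitted_depth > 0:
            depth = fitted_depth

    base = int(np.floor(centre_f))
    frac = centre_f - base
    i0 = int(window_idx[min(base, m - 1)])
    i1 = int(window_idx[min(base + 1, m - 1)])
    position = pts[i0] + frac * (pts[i1] - pts[i0])  # stays on the polyline

    if depth < depth_threshold:
        confidence = DipConfidence.NONE
    elif depth >= 2.0 * depth_threshold:
        confidence = DipConfidence.CLEAR
    else:
        confidence = DipConfidence.WEAK
    return DipEstimate(position=position, depth=depth, confidence=confidence)


def reflect_points(points: np.ndarray, axis: ReflectionAxis) -> np.ndarray:
    """Mirror points across the axis line (an involution)."""
    p0 = axis.point
    nvec = axis.normal
    v = np.asarray(points, dtype=float) - p0
    return p0 + v - 2.0 * np.outer(v @ nvec, nvec)


def axis_signed_distance(points: np.ndarray, axis: ReflectionAxis) -> np.ndarray:
    """Signed lateral distance of points from the axis (positive toward +x)."""
    return (np.asarray(points, dtype=float) - axis.point) @ axis.normal


def _largest_true_run(mask: np.ndarray) -> np.ndarray:
    """Indices of the longest circular run of True values."""
    n = len(mask)
    if mask.all():
        return np.arange(n)
    # rotate so position 0 is False, then find plain runs
    start = int(np.argmin(mask))
    rolled = np.roll(mask, -start)
    best_len, best_s, cur_s = 0, 0, None
    for i, v in enumerate(np.append(rolled, False)):
        if v and cur_s is None:
            cur_s = i
        elif not v and cur_s is not None:
            if i - cur_s > best_len:
                best_len, best_s = i - cur_s, cur_s
            cur_s = None
    return (np.arange(best_s, best_s + best_len) + start) % n


def split_halves(contour: ContourLine, axis: ReflectionAxis) -> tuple[np.ndarray, np.ndarray]:
    """Split an ordered closed contour into its right (+x side) and left
    halves relative to the axis, each an ordered open polyline running from
    posterior to anterior along the axis direction."""
    u = axis_signed_distance(contour.points, axis)
    right_idx = _largest_true_run(u >= 0)
    left_idx = _largest_true_run(u < 0)
    halves = []
    for idx in (right_idx, left_idx):
        half = contour.points[idx]
        if len(half) < 2:
            raise ValidationError("axis does not split the contour into two halves")
        v = (half - axis.point) @ axis.direction
        if v[0] > v[-1]:  # orient posterior -> anterior
            half = half[::-1]
        halves.append(half)
    return halves[0], halves[1]


def reflect_side(contour: ContourLine, axis: ReflectionAxis, side: Side) -> np.ndarray:
    """Mirror image of the chosen contour half across the axis line."""
    right, left = split_halves(contour, axis)
    half = right if side is Side.RIGHT else left
    return reflect_points(half, axis)


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample an open polyline to n points equally spaced in arc length."""
    p = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValidationError("cannot resample a degenerate polyline")
    t = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(t, s, p[:, 0]), np.interp(t, s, p[:, 1])])


def asymmetry_area(pathological_half: np.ndarray, reflected_half: np.ndarray) -> float:
    """Non-negative area (mm^2) enclosed between two matched polylines.

    Both polylines must carry the same number of points, parameterized over
    matching arc-length fractions; the area is the sum of absolute
    quadrilateral strip areas, zero iff the curves coincide.
    """
    a = np.asarray(pathological_half, dtype=float)
    b = np.asarray(reflected_half, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValidationError("half polylines must have matching shapes")
    total = 0.0
    for i in range(len(a) - 1):
        quad = np.array([a[i], a[i + 1], b[i + 1], b[i]])
        x, y = quad[:, 0], quad[:, 1]
        total += abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    return float(total)


def _auto_healthy_side(contour: ContourLine, init: ReflectionAxis) -> Side:
    """Heuristic: the healthy side is the one whose posterior quarter
    encloses the smaller (convex-hull) area — the rib hump enlarges the
    pathological side."""
    pts = contour.points
    c = pts.mean(axis=0)
    posterior = pts[pts[:, 1] < c[1]]
    u = axis_signed_distance(posterior, init)
    right, left = posterior[u >= 0], posterior[u < 0]
    if len(right) < 3 or len(left) < 3:
        return Side.LEFT
    return Side.RIGHT if polygon_area(right) < polygon_area(left) else Side.LEFT


def fit_reflection_axis(
    contour: ContourLine,
    healthy_side: Side | str = "auto",
    init: ReflectionAxis | None = None,
    trim_quantile: float = DEFAULT_TRIM_QUANTILE,
    n_area: int = 200,
    fix_angle: bool = False,
) -> SymmetryResult:
    """Fit the mid-sagittal reflection axis of a transverse contour.

    The axis (angle from anterior, lateral offset) minimizes the trimmed
    mean squared nearest-point distance between the healthy half mirrored
    across the axis and the pathological half: only the best-matching
    ``trim_quantile`` fraction of point distances enters the objective, so
    the fit keys on the portion of the pathological side that is not (or
    only little) distorted.  Multi-start Nelder-Mead over a +-10 deg x
    +-15 mm grid around ``init``; solutions with |angle| >= 45 deg are
    rejected in favour of the next-best start.

    Returns the optimal axis, the healthy side actually used, and the
    mismatch area between the reflected healthy half and the pathological
    half.

    With ``fix_angle`` the axis stays parallel to ``init`` (a vertical
    crosshair when init has angle 0) and only the lateral offset is
    optimized.
    """
    if not 0.1 <= trim_quantile <= 1.0:
        raise ValidationError("trim quantile must lie in [0.1, 1]")
    if init is None:
        from .contour import detect_dip as _dd  # local alias for clarity

        dip = _dd(contour)
        init = ReflectionAxis(angle_deg=0.0, offset=float(dip.position[0]), y_ref=float(dip.position[1]))
    if isinstance(healthy_side, str) and healthy_side == "auto":
        healthy_side = _auto_healthy_side(contour, init)
    else:
        healthy_side = Side(healthy_side)

    # split once with the initial axis and keep membership fixed during the
    # optimization; the trimmed objective absorbs boundary effects
    right, left = split_halves(contour, init)
    healthy = right if healthy_side is Side.RIGHT else left
    patho = left if healthy_side is Side.RIGHT else right
    tree = cKDTree(patho)
    keep = max(4, int(np.floor(trim_quantile * len(healthy))))

    def objective(params: np.ndarray) -> float:
        angle, offset = params
        if abs(angle) >= 45.0:
            return 1e12
        axis = ReflectionAxis(angle_deg=float(angle), offset=float(offset), y_ref=init.y_ref)
        mirrored = reflect_points(healthy, axis)
        d, _ = tree.query(mirrored)
        d2 = np.sort(d**2)[:keep]
        return float(d2.mean())

    x0 = np.array([init.angle_deg, init.offset])
    f0 = objective(x0)
    best_x, best_f = x0, f0
    angle_starts = (0.0,) if fix_angle else (-10.0, 0.0, 10.0)
    for da in angle_starts:
        for doff in (-15.0, 0.0, 15.0):
            start = x0 + [da, doff]
            if fix_angle:
                res = minimize(
                    lambda o: objective(np.array([x0[0], o[0]])),
                    [start[1]],
                    method="Nelder-Mead",
                    options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 200},
                )
                cand_x, cand_f = np.array([x0[0], res.x[0]]), float(res.fun)
            else:
                res = minimize(
                    objective,
                    start,
                    method="Nelder-Mead",
                    options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 400},
                )
                cand_x, cand_f = res.x, float(res.fun)
            if abs(cand_x[0]) >= 45.0:
                continue
            if cand_f < best_f:
                best_f, best_x = cand_f, cand_x

    converged = best_f < f0 or np.isclose(best_f, f0)
    axis = ReflectionAxis(angle_deg=float(best_x[0]), offset=float(best_x[1]), y_ref=init.y_ref)

    mirrored = reflect_points(healthy, axis)
    m = resample_polyline(mirrored, n_area)
    p = resample_polyline(patho, n_area)
    # align parameter direction: both run posterior -> anterior already, but
    # guard against a flipped mirror by endpoint proximity
    if np.linalg.norm(m[0] - p[0]) + np.linalg.norm(m[-1] - p[-1]) > np.linalg.norm(
        m[0] - p[-1]
    ) + np.linalg.norm(m[-1] - p[0]):
        m = m[::-1]
    area = asymmetry_area(p, m)
    return SymmetryResult(
        axis=axis,
        healthy_side=healthy_side,
        mismatch_area=area,
        objective=best_f,
        converged=bool(converged),
    )
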
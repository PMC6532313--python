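"""End-to-end orchestration: scan -> contours -> dips -> offsets ->
trajectory -> fit -> severity (-> match against a reference trajectory).

Every automated decision (healthy-side choice, rejected slices) is logged
into the report so that a run is auditable, and the whole pipeline is
deterministic for a fixed configuration.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .datatypes import (
    ContourLine,
    DipConfidence,
    SourceLabel,
    SpinalTrajectory,
    SpinescanError,
    SurfaceScan,
    ValidationError,
)
from .contour import detect_dip, fit_reflection_axis
from .matching import match_curves
from .sectors import compute_offset, correct_marker, partition_sectors
from .slicing import plan_levels, slice_scan
from .trajectory import fit_polynomial, lateral_deviation

log = logging.getLogger("spinescan")

__all__ = ["AnalysisParams", "SliceResult", "PipelineResult", "analyze_contours", "run_pipeline"]


@dataclass
class AnalysisParams:
    """Tunable parameters of the contour-analysis pipeline (all mm / deg)."""

    d: float = 50.0  # anterior-posterior separation distance
    grouping: str = "sum"  # offset-formula grouping variant
    trim_quantile: float = 0.70
    healthy_side: str = "auto"  # left | right | auto
    degree: int = 2  # polynomial degree of the coronal fit
    dip_threshold: float = 1.0  # mm, minimal indentation depth
    search_window: float = 0.40  # posterior arc fraction searched for the dip
    n_resample: int = 512  # contour resampling density
    smooth_window: int = 7  # points; circular smoothing for dip detection
    contour_smooth: int = 9  # points; contour-level smoothing before analysis
    thickness: float = 2.0  # slab half-width for point-cloud slicing
    max_gap: float = 15.0  # fragmented-contour gap threshold
    # axis_mode: "vertical" fits only the lateral offset of a vertical
    # crosshair (the default interactive workflow); "free" also fits the
    # angle; "fixed" keeps the vertical axis through the dip untouched
    axis_mode: str = "vertical"
    use_corrected: bool = True  # trajectory from corrected (vs raw dip) markers


@dataclass
class SliceResult:
    level: float
    ok: bool
    reason: str = ""
    dip: dict = field(default_factory=dict)
    axis: dict = field(default_factory=dict)
    sectors: dict = field(default_factory=dict)
    x_off: float = float("nan")
    corrected: tuple[float, float] | None = None
    mismatch_area: float = float("nan")


def analyze_slice(contour: ContourLine, params: AnalysisParams) -> SliceResult:
    """Run the full single-slice analysis: dip, reflection axis, sector
    partition, offset correction."""
    result = SliceResult(level=contour.level, ok=False)
    if params.contour_smooth > 1:
        from .slicing import smooth_contour

        contour = smooth_contour(contour, params.contour_smooth)
    dip = detect_dip(
        contour,
        search_window=params.search_window,
        depth_threshold=params.dip_threshold,
        smooth_window=params.smooth_window,
    )
    result.dip = {
        "x": float(dip.position[0]),
        "y": float(dip.position[1]),
        "depth": dip.depth,
        "confidence": dip.confidence.value,
    }
    if dip.confidence is DipConfidence.NONE:
        result.reason = "no dip above depth threshold"
        return result

    from .datatypes import ReflectionAxis

    init = ReflectionAxis(angle_deg=0.0, offset=float(dip.position[0]), y_ref=float(dip.position[1]))
    if params.axis_mode in ("vertical", "free"):
        sym = fit_reflection_axis(
            contour,
            healthy_side=params.healthy_side,
            init=init,
            trim_quantile=params.trim_quantile,
            fix_angle=params.axis_mode == "vertical",
        )
        axis = sym.axis
        result.axis = {
            "angle_deg": axis.angle_deg,
            "offset_mm": axis.offset,
            "healthy_side": sym.healthy_side.value,
            "mode": params.axis_mode,
            "converged": sym.converged,
        }
        result.mismatch_area = sym.mismatch_area
    elif params.axis_mode == "fixed":
        axis = init
        result.axis = {"angle_deg": 0.0, "offset_mm": init.offset, "healthy_side": "fixed",
                       "mode": "fixed"}
    else:
        raise ValidationError(f"unknown axis_mode {params.axis_mode!r}")

    partition = partition_sectors(contour, dip.position, axis, d=params.d)
    result.sectors = {
        "A": partition.A,
        "B": partition.B,
        "C": partition.C,
        "D": partition.D,
        "R_omega": partition.R_omega,
    }
    result.x_off = compute_offset(partition, grouping=params.grouping)
    marker = correct_marker(dip, result.x_off, contour.level)
    result.corrected = (float(marker.corrected_position[0]), float(marker.corrected_position[1]))
    result.ok = True
    return result


@dataclass
class PipelineResult:
    slices: list[SliceResult]
    trajectory: SpinalTrajectory | None
    dip_trajectory: SpinalTrajectory | None
    fit: object | None
    deviation: object | None
    match: object | None
    report: dict


def analyze_contours(
    contours: list[ContourLine],
    params: AnalysisParams,
    reference: SpinalTrajectory | None = None,
) -> PipelineResult:
    """Analyze an ordered contour stack and assemble the spine trajectory.

    Slices that fail (no dip, degenerate sectors) are flagged and skipped;
    the pipeline continues as long as at least two usable markers remain.
    When ``reference`` is given, the resulting trajectory is rigidly
    matched against it and the match appended to the report.
    """
    slice_results: list[SliceResult] = []
    markers = []
    for contour in contours:
        try:
            res = analyze_slice(contour, params)
        except SpinescanError as exc:
            res = SliceResult(level=contour.level, ok=False, reason=f"{type(exc).__name__}: {exc}")
            log.info("slice %.1f mm rejected: %s", contour.level, res.reason)
        if res.ok:
            markers.append(res)
        else:
            log.info("slice %.1f mm flagged: %s", contour.level, res.reason)
        slice_results.append(res)

    report: dict = {
        "schema_version": 1,
        "package_version": __version__,
        "params": asdict(params),
        "slices": [
            {
                "level_mm": s.level,
                "ok": s.ok,
                "reason": s.reason,
                "dip": s.dip,
                "axis": s.axis,
                "sectors": s.sectors,
                "x_off_mm": s.x_off,
                "corrected_xy_mm": s.corrected,
                "mismatch_area_mm2": s.mismatch_area,
            }
            for s in slice_results
        ],
        "n_slices_used": len(markers),
        "optimality_definition": "mean squared residual distance (mm^2) after optimal alignment",
        "axis_fit": "trimmed nearest-point least squares (automated)",
    }

    if len(markers) < 2:
        report["error"] = "fewer than 2 usable markers"
        return PipelineResult(slice_results, None, None, None, None, None, report)

    def traj_from(key: str, label: SourceLabel) -> SpinalTrajectory:
        pts = []
        for s in markers:
            if key == "corrected":
                x, y = s.corrected
            else:
                x, y = s.dip["x"], s.dip["y"]
            pts.append([x, y, s.level])
        return SpinalTrajectory(points=np.asarray(pts), source_label=label)

    dip_traj = traj_from("dip", SourceLabel.SP2)
    corr_traj = traj_from("corrected", SourceLabel.CORRECTED)
    traj = corr_traj if params.use_corrected else dip_traj

    fit = fit_polynomial(traj, params.degree)
    deviation = lateral_deviation(fit)
    report["trajectory"] = {
        "source": traj.source_label.value,
        "points_xyz_mm": traj.points,
    }
    report["fit"] = {
        "degree": fit.degree,
        "coefficients": fit.coefficients,
        "residual_rms_mm": fit.residual_rms,
        "inflexion_levels_mm": fit.inflexion_levels,
        "included_angles_deg": fit.included_angles,
        "included_angle_knots": "endpoints + interior inflexion levels",
    }
    report["deviation"] = {
        "max_lateral_deviation_mm": deviation.max_lateral_deviation,
        "severity": deviation.severity.value,
    }

    match = None
    if reference is not None:
        match = match_curves(traj, reference)
        report["match"] = {
            "translation_mm": match.translation,
            "rotation_alpha_deg": match.rotation_alpha,
            "optimality_mm2": match.optimality,
            "converged": match.converged,
        }
    return PipelineResult(slice_results, traj, dip_traj, fit, deviation, match, report)


def run_pipeline(
    scan: SurfaceScan,
    n_levels: int = 15,
    z_min: float | None = None,
    z_max: float | None = None,
    params: AnalysisParams | None = None,
    reference: SpinalTrajectory | None = None,
    level_margin: float = 0.10,
) -> PipelineResult:
    """Slice a surface scan and run the full contour analysis on it.

    Levels default to ``n_levels`` regular intervals over the central
    ``1 - 2 * level_margin`` of the scan's z-range (avoiding the slice
    degeneracies at the torso ends).
    """
    params = params or AnalysisParams()
    lo, hi = scan.z_range
    span = hi - lo
    z_min = lo + level_margin * span if z_min is None else z_min
    z_max = hi - level_margin * span if z_max is None else z_max
    plan = plan_levels(z_min, z_max, n_levels, thickness=params.thickness)
    contours = slice_scan(scan, plan, n_resample=params.n_resample, max_gap=params.max_gap)
    result = analyze_contours(contours, params, reference=reference)
    result.report["slice_plan"] = {
        "levels_mm": plan.levels,
        "thickness_mm": plan.thickness,
        "n_resample": params.n_resample,
    }
    return result
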
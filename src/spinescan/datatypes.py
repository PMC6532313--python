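"""Core domain types shared across the analysis pipeline.

Coordinate convention is RAS, millimetres throughout:

* ``x`` — toward the patient's right,
* ``y`` — anterior,
* ``z`` — superior (the vertical torso axis).

Transverse slices therefore live in the ``(x, y)`` plane and the coronal
projection of the spine is ``x`` as a function of ``z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np


class SpinescanError(Exception):
    """Base class for all package errors."""


class ValidationError(SpinescanError):
    """An input violated a documented invariant."""


class ParseError(SpinescanError):
    """A file could not be parsed; the message names the offending content."""


class EmptyInputError(SpinescanError):
    """An operation received or produced an empty result."""


class EmptySliceError(SpinescanError):
    """A slicing slab did not intersect the scan."""


class FragmentedContourError(SpinescanError):
    """Slice points form disjoint clusters (e.g. arms inside the slab)."""


class DegenerateSectorError(SpinescanError):
    """A sector of the four-way contour partition has fewer than 3 points."""


def _as_points(points, dim: int, name: str) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != dim:
        raise ValidationError(f"{name} must be an (N, {dim}) array, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite coordinates")
    return arr


@dataclass
class SurfaceScan:
    """A torso surface as vertices (and optionally triangles) in mm, RAS."""

    vertices: np.ndarray
    faces: np.ndarray | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.vertices = _as_points(self.vertices, 3, "vertices")
        if len(self.vertices) < 4:
            raise ValidationError("a surface scan needs at least 4 vertices")
        if self.faces is not None:
            self.faces = np.asarray(self.faces, dtype=np.int64)
            if self.faces.size == 0:
                self.faces = None
            elif self.faces.ndim != 2 or self.faces.shape[1] != 3:
                raise ValidationError("faces must be an (M, 3) triangle index array")
            elif self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValidationError("face indices out of vertex range")

    @property
    def z_range(self) -> tuple[float, float]:
        z = self.vertices[:, 2]
        return float(z.min()), float(z.max())

    def __len__(self) -> int:
        return len(self.vertices)


class SourceLabel(str, Enum):
    """Provenance of a marker set / trajectory.

    SP1: markers placed on a 2D coronal projection image;
    SP2: dip positions from the contour-line analysis;
    SP3: true vertebral-body centres (reference);
    scanner: surface-scan pipeline output; corrected: dip + lateral offset.
    """

    SP1 = "SP1"
    SP2 = "SP2"
    SP3 = "SP3"
    SCANNER = "scanner"
    CORRECTED = "corrected"
    OTHER = "other"


@dataclass
class MarkerSet:
    """Per-level markers: lateral position x (mm), optional y, at level z (mm)."""

    levels: np.ndarray
    x: np.ndarray
    y: np.ndarray | None = None
    source_label: SourceLabel = SourceLabel.OTHER

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.levels.shape != self.x.shape or self.levels.ndim != 1:
            raise ValidationError("levels and x must be 1-D arrays of equal length")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if self.y.shape != self.levels.shape:
                raise ValidationError("y must match levels in length")
        order = np.argsort(self.levels, kind="stable")
        self.levels = self.levels[order]
        self.x = self.x[order]
        if self.y is not None:
            self.y = self.y[order]
        if len(self.levels) >= 2 and np.any(np.diff(self.levels) <= 0):
            raise ValidationError("marker levels must be strictly increasing (duplicate z)")

    def __len__(self) -> int:
        return len(self.levels)


@dataclass
class MaskRegion:
    """Axis-aligned 3D box marking vertices to *exclude* from a scan."""

    lower: tuple[float, float, float]
    upper: tuple[float, float, float]

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.shape != (3,) or hi.shape != (3,):
            raise ValidationError("mask bounds must be 3-vectors")
        if np.any(lo >= hi):
            raise ValidationError("mask requires min < max per axis")
        self.lower = tuple(lo)
        self.upper = tuple(hi)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        lo = np.asarray(self.lower)
        hi = np.asarray(self.upper)
        return np.all((p >= lo) & (p <= hi), axis=1)


@dataclass
class SlicePlan:
    """Transverse slice levels (mm) with a slab half-width per level."""

    levels: np.ndarray
    thickness: float = 2.0

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.ndim != 1 or len(self.levels) < 2:
            raise ValidationError("a slice plan needs at least 2 levels")
        if np.any(np.diff(self.levels) <= 0):
            raise ValidationError("slice levels must be strictly increasing")
        if self.thickness <= 0:
            raise ValidationError("slab half-width must be positive")


@dataclass
class ContourLine:
    """Closed, ordered transverse contour at one level.

    Points are (x, y) in mm, ordered counter-clockwise when viewed from
    superior (+z).
    """

    level: float
    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        self.points = _as_points(self.points, 2, "contour points")
        if len(self.points) < 8:
            raise ValidationError("a contour needs at least 8 points")
        # drop consecutive duplicates (incl. an explicit closing point)
        d = np.linalg.norm(np.diff(self.points, axis=0, append=self.points[:1]), axis=1)
        keep = d > 1e-12
        if not keep.all():
            self.points = self.points[keep]
        if len(self.points) < 8:
            raise ValidationError("contour degenerate after removing duplicate points")

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def segment_lengths(self) -> np.ndarray:
        nxt = np.roll(self.points, -1, axis=0) if self.closed else self.points[1:]
        cur = self.points if self.closed else self.points[:-1]
        return np.linalg.norm(nxt - cur, axis=1)

    @property
    def perimeter(self) -> float:
        return float(self.segment_lengths().sum())

    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def area(self) -> float:
        return abs(self.signed_area())


class DipConfidence(str, Enum):
    CLEAR = "clear"
    WEAK = "weak"
    NONE = "none"


@dataclass
class DipEstimate:
    """Location of the posterior dip attributed to the spinous-process tip."""

    position: np.ndarray
    depth: float
    confidence: DipConfidence

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.depth < 0:
            raise ValidationError("dip depth must be non-negative")


@dataclass
class ReflectionAxis:
    """Near-sagittal reflection axis in a transverse slice.

    ``angle_deg`` is measured from the +y (anterior) direction, positive
    rotating toward +x; ``offset`` is the signed lateral position of the axis
    at the reference level ``y_ref`` (the dip's y by convention).
    """

    angle_deg: float = 0.0
    offset: float = 0.0
    y_ref: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.angle_deg) >= 45.0:
            raise ValidationError("reflection axis must stay near-sagittal (|angle| < 45 deg)")

    @property
    def direction(self) -> np.ndarray:
        """Unit vector along the axis (toward anterior)."""
        t = np.deg2rad(self.angle_deg)
        return np.array([np.sin(t), np.cos(t)])

    @property
    def normal(self) -> np.ndarray:
        """Unit vector perpendicular to the axis, toward the patient's right."""
        t = np.deg2rad(self.angle_deg)
        return np.array([np.cos(t), -np.sin(t)])

    @property
    def point(self) -> np.ndarray:
        return np.array([self.offset, self.y_ref])


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass
class SymmetryResult:
    axis: ReflectionAxis
    healthy_side: Side
    mismatch_area: float
    objective: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if self.mismatch_area < 0:
            raise ValidationError("mismatch area must be non-negative")


@dataclass
class SectorPartition:
    """Four-sector split of a contour: A, B anterior / C, D posterior;
    A and C on the +x side of the lateral separation line."""

    d: float
    dip: np.ndarray
    A: float
    B: float
    C: float
    D: float
    R_omega: float

    def __post_init__(self) -> None:
        self.dip = np.asarray(self.dip, dtype=float)
        for name in "ABCD":
            if getattr(self, name) < 0:
                raise ValidationError(f"sector area {name} must be non-negative")
        if self.R_omega <= 0:
            raise ValidationError("R_omega must be positive")
        if self.d <= 0:
            raise ValidationError("separation distance d must be positive")


@dataclass
class VertebralMarker:
    """Per-level dip with its lateral offset correction."""

    level: float
    dip_position: np.ndarray
    x_off: float
    corrected_position: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dip_position = np.asarray(self.dip_position, dtype=float)
        if self.corrected_position is None:
            self.corrected_position = self.dip_position + np.array([self.x_off, 0.0])
        else:
            self.corrected_position = np.asarray(self.corrected_position, dtype=float)


@dataclass
class SpinalTrajectory:
    """Ordered 3D marker sequence (x_i, y_i, z_i), z strictly increasing."""

    points: np.ndarray
    source_label: SourceLabel = SourceLabel.OTHER

    def __post_init__(self) -> None:
        self.points = _as_points(self.points, 3, "trajectory points")
        if len(self.points) < 2:
            raise ValidationError("a trajectory needs at least 2 points")
        if np.any(np.diff(self.points[:, 2]) <= 0):
            raise ValidationError("trajectory levels must be strictly increasing")

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]

    @property
    def coronal(self) -> np.ndarray:
        """Coronal projection as (x, z) pairs."""
        return self.points[:, [0, 2]]

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class PolynomialFit:
    """Least-squares polynomial x(z) of the coronal spine projection."""

    degree: int
    coefficients: np.ndarray  # ascending powers of z
    residual_rms: float
    z_min: float
    z_max: float
    inflexion_levels: np.ndarray = field(default_factory=lambda: np.empty(0))
    included_angles: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.inflexion_levels = np.asarray(self.inflexion_levels, dtype=float)
        self.included_angles = np.asarray(self.included_angles, dtype=float)

    def __call__(self, z) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(z, dtype=float), self.coefficients)

    def derivative(self, z, order: int = 1) -> np.ndarray:
        c = np.polynomial.polynomial.polyder(self.coefficients, order)
        return np.polynomial.polynomial.polyval(np.asarray(z, dtype=float), c)


class DeviationClass(str, Enum):
    MILD = "mild"
    MODERATE = "moderate"
    STRONG = "strong"


class CobbClass(str, Enum):
    NO_SCOLIOSIS = "no scoliosis"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


@dataclass
class DeviationSummary:
    max_lateral_deviation: float
    severity: DeviationClass


@dataclass
class MatchResult:
    """Rigid in-plane match of one coronal trajectory onto another."""

    translation: tuple[float, float]
    rotation_alpha: float  # degrees, |alpha| < 45
    optimality: float  # mean squared residual distance, mm^2
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.optimality < 0:
            raise ValidationError("optimality must be non-negative")


@dataclass
class RotationEstimate:
    """Vertebral-body rotation relative to the spinous process.

    P is the vertebral-body position, R the dip on the contour, Q the foot
    of the posterior perpendicular from P at distance PS; alpha is the angle
    QPR (degrees), QR the lateral shift of the dip.
    """

    P: np.ndarray
    R: np.ndarray
    Q: np.ndarray
    PS: float
    QR: float
    alpha: float


@dataclass
class DeltaProfile:
    """Vertebral-body-to-skin distances and their normalized deviations."""

    delta: np.ndarray
    delta_bar: float
    delta_norm: np.ndarray
    levels_norm: np.ndarray


@dataclass
class SeverityClass:
    deviation_class: DeviationClass | None = None
    cobb_class: CobbClass | None = None
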
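"""Clinical summary metrics: vertebral rotation from the dip shift,
normalized vertebral-body-to-skin distance profile, and severity bands.

Severity conventions:

* lateral deviation of the coronal spine curve — mild <= 10 mm,
  moderate 10-20 mm, strong >= 20 mm;
* Cobb angle — scoliosis onset at 10 deg, mild 10-20 deg, moderate
  20-40 deg, severe > 40 deg (band edges assigned to the lower band).
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    CobbClass,
    DeltaProfile,
    DeviationClass,
    RotationEstimate,
    SeverityClass,
    ValidationError,
)

__all__ = [
    "vertebral_rotation",
    "delta_profile",
    "classify_deviation",
    "classify_cobb",
    "classify",
]


def vertebral_rotation(P, R, PS: float) -> RotationEstimate:
    """Estimate the vertebral-body rotation relative to its spinous process.

    Given the vertebral-body position ``P``, the dip position ``R`` on the
    contour and the posterior distance ``PS`` from the body to the contour,
    ``Q`` is the foot of the posterior perpendicular from ``P`` (so the
    triangle QPR has its right angle at Q) and the rotation angle is

        alpha = atan(QR / PS)   [degrees],

    signed by the lateral direction of the dip shift QR (positive toward
    the patient's right).
    """
    P = np.asarray(P, dtype=float)
    R = np.asarray(R, dtype=float)
    if PS <= 0:
        raise ValidationError("PS (vertebral body to contour distance) must be positive")
    Q = P + np.array([0.0, -PS])
    QR = float(R[0] - Q[0])
    alpha = float(np.degrees(np.arctan2(QR, PS)))
    return RotationEstimate(P=P, R=R, Q=Q, PS=float(PS), QR=QR, alpha=alpha)


def delta_profile(delta_i, levels, iliac: float, prominens: float) -> DeltaProfile:
    """Normalized vertebral-body-to-skin distances along the spine.

    Each distance is expressed relative to the subject's mean,
    ``(delta_i - mean) / mean``, removing body-size effects; levels are
    mapped affinely so the iliac crest is 0 and the vertebra prominens is 1.
    """
    delta = np.asarray(delta_i, dtype=float)
    z = np.asarray(levels, dtype=float)
    if delta.ndim != 1 or delta.shape != z.shape:
        raise ValidationError("delta and levels must be 1-D arrays of equal length")
    if len(delta) < 2:
        raise ValidationError("at least 2 levels are required")
    if np.any(delta <= 0):
        raise ValidationError("all distances must be positive")
    if not iliac < prominens:
        raise ValidationError("iliac level must lie below the vertebra prominens")
    delta_bar = float(delta.mean())
    delta_norm = (delta - delta_bar) / delta_bar
    levels_norm = (z - iliac) / (prominens - iliac)
    return DeltaProfile(
        delta=delta, delta_bar=delta_bar, delta_norm=delta_norm, levels_norm=levels_norm
    )


def classify_deviation(deviation_mm: float) -> DeviationClass:
    """Severity band of a lateral spine deviation in mm (<=10 / 10-20 / >=20)."""
    if deviation_mm < 0:
        raise ValidationError("deviation must be non-negative")
    if deviation_mm <= 10.0:
        return DeviationClass.MILD
    if deviation_mm >= 20.0:
        return DeviationClass.STRONG
    return DeviationClass.MODERATE


def classify_cobb(cobb_deg: float) -> CobbClass:
    """Cobb-angle severity band (onset 10 deg; 10-20 / 20-40 / >40)."""
    if cobb_deg < 0:
        raise ValidationError("Cobb angle must be non-negative")
    if cobb_deg < 10.0:
        return CobbClass.NO_SCOLIOSIS
    if cobb_deg <= 20.0:
        return CobbClass.MILD
    if cobb_deg <= 40.0:
        return CobbClass.MODERATE
    return CobbClass.SEVERE


def classify(deviation_mm: float | None = None, cobb_deg: float | None = None) -> SeverityClass:
    """Severity classification from a lateral deviation and/or a Cobb angle."""
    if deviation_mm is None and cobb_deg is None:
        raise ValidationError("provide a deviation in mm and/or a Cobb angle in degrees")
    return SeverityClass(
        deviation_class=None if deviation_mm is None else classify_deviation(deviation_mm),
        cobb_class=None if cobb_deg is None else classify_cobb(cobb_deg),
    )
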
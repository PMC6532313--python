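"""Parametric synthetic torsos with a known embedded spine.

The generator builds a torso as a stack of superellipse cross-sections
carrying three anatomical features:

* a Gaussian posterior dip at the spinous-process azimuth, following the
  (known) coronal spine polynomial;
* a unilateral posterior rib-hump bump whose side and amplitude follow a
  per-level vertebral rotation profile, with a contralateral anterior
  flattening of equal amplitude — vertebral rotation thus changes the
  contour asymmetry without moving the dip much;
* a lateral shift of the vertebral body away from the dip by
  ``QR = d_skin * tan(rotation)``, the trigonometric link between rotation
  and dip shift.

Every output is deterministic for a fixed seed, and the ground truth
(spine trajectory, dip positions, rotations, body-to-skin distances,
cross-section areas) is returned alongside so that each pipeline stage can
be tested against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import ContourLine, SpinalTrajectory, SourceLabel, SurfaceScan, ValidationError

__all__ = ["TorsoSpec", "GroundTruth", "generate_contour", "generate_torso", "preset"]

POSTERIOR = -np.pi / 2


@dataclass
class TorsoSpec:
    """Parameters of a synthetic torso.

    ``spine_coeffs`` are ascending polynomial coefficients of the coronal
    spine x (mm) in the normalized height zeta = z / height.  The rotation
    profile is ``rot_max`` scaled by the normalized spine deflection (a
    sin(pi*zeta) bow when the spine is straight), so rotation peaks at the
    curve apex.
    """

    height: float = 450.0
    n_levels: int = 15
    a0: float = 150.0  # lateral half-width, mm
    b0: float = 110.0  # anterior-posterior half-width, mm
    exponent: float = 2.5  # superellipse roundness
    spine_coeffs: tuple[float, ...] = (0.0,)
    rot_max: float = 0.0  # peak vertebral rotation, degrees
    d_skin: float = 50.0  # vertebral body to back-skin distance, mm
    k_hump: float = 26.0  # rib-hump gain, mm per unit sin(rotation); chosen
    # so the contour asymmetry is self-consistent with the dip shift that
    # the same rotation produces through QR = d_skin * tan(rotation)
    hump_sigma: float = np.pi / 8  # azimuthal hump width, rad
    dip_depth: float = 6.0  # mm
    dip_width: float = 18.0  # mm along the contour
    noise_sigma: float = 0.5  # mm, Gaussian vertex noise
    seed: int = 0
    n_theta: int = 128  # mesh ring resolution
    n_rings: int = 64
    level_margin: float = 0.10  # analysis levels span [margin, 1-margin]*height

    def __post_init__(self) -> None:
        if min(self.a0, self.b0) <= self.dip_depth:
            raise ValidationError("cross-section half-widths must exceed the dip depth")
        if abs(self.rot_max) > 30.0:
            raise ValidationError("|rotation| must stay within 30 degrees")

    # -- ground-truth curves ------------------------------------------------
    def spine_x(self, z) -> np.ndarray:
        zeta = np.asarray(z, dtype=float) / self.height
        return np.polynomial.polynomial.polyval(zeta, np.asarray(self.spine_coeffs, dtype=float))

    def rotation_deg(self, z) -> np.ndarray:
        zeta = np.asarray(z, dtype=float) / self.height
        x = self.spine_x(z)
        zz = np.linspace(0, self.height, 201)
        ref = np.max(np.abs(self.spine_x(zz)))
        if ref < 1e-9:
            shape = np.sin(np.pi * zeta)
        else:
            shape = x / ref
        return self.rot_max * shape

    def width_factor(self, z) -> np.ndarray:
        """Smooth waist narrowing along the torso."""
        zeta = np.asarray(z, dtype=float) / self.height
        return 1.0 - 0.10 * np.exp(-(((zeta - 0.45) / 0.22) ** 2))

    def analysis_levels(self) -> np.ndarray:
        return np.linspace(
            self.level_margin * self.height, (1 - self.level_margin) * self.height, self.n_levels
        )


@dataclass
class GroundTruth:
    """Per-level ground truth of a synthetic torso."""

    levels: np.ndarray
    spine: np.ndarray  # (n, 3): vertebral-body centres (x, y, z)
    dip: np.ndarray  # (n, 2): dip positions (x, y)
    rotation_deg: np.ndarray
    delta: np.ndarray  # vertebral body to back-skin distance, mm
    area: np.ndarray  # cross-section area, mm^2

    def spine_trajectory(self) -> SpinalTrajectory:
        return SpinalTrajectory(points=self.spine, source_label=SourceLabel.SP3)

    def dip_trajectory(self) -> SpinalTrajectory:
        pts = np.column_stack([self.dip, self.levels])
        return SpinalTrajectory(points=pts, source_label=SourceLabel.SP2)

    def to_dict(self) -> dict:
        return {
            "levels_mm": self.levels.tolist(),
            "spine_xyz_mm": self.spine.tolist(),
            "dip_xy_mm": self.dip.tolist(),
            "rotation_deg": self.rotation_deg.tolist(),
            "delta_mm": self.delta.tolist(),
            "area_mm2": self.area.tolist(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GroundTruth":
        return cls(
            levels=np.asarray(data["levels_mm"], dtype=float),
            spine=np.asarray(data["spine_xyz_mm"], dtype=float),
            dip=np.asarray(data["dip_xy_mm"], dtype=float),
            rotation_deg=np.asarray(data["rotation_deg"], dtype=float),
            delta=np.asarray(data["delta_mm"], dtype=float),
            area=np.asarray(data["area_mm2"], dtype=float),
        )


def _wrap(angle: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * angle))


def _gaussian(theta: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * (_wrap(theta - mu) / sigma) ** 2)


def _radius(spec: TorsoSpec, level: float, theta: np.ndarray) -> np.ndarray:
    w = float(spec.width_factor(level))
    a, b = spec.a0 * w, spec.b0 * w
    p = spec.exponent
    r_se = (np.abs(np.cos(theta) / a) ** p + np.abs(np.sin(theta) / b) ** p) ** (-1.0 / p)
    sigma_dip = spec.dip_width / b
    r = r_se - spec.dip_depth * _gaussian(theta, POSTERIOR, sigma_dip)
    rot = float(spec.rotation_deg(level))
    if rot != 0.0:
        amp = spec.k_hump * np.sin(np.deg2rad(abs(rot)))
        side = np.sign(rot)
        theta_hump = POSTERIOR + side * np.pi / 4  # posterior, hump side
        theta_flat = theta_hump + np.pi  # anterior, contralateral
        r = r + amp * _gaussian(theta, theta_hump, spec.hump_sigma)
        r = r - amp * _gaussian(theta, theta_flat, spec.hump_sigma)
    return r


def _level_truth(spec: TorsoSpec, level: float, contour: ContourLine) -> dict:
    rot = float(spec.rotation_deg(level))
    x_vert = float(spec.spine_x(level))
    qr = spec.d_skin * np.tan(np.deg2rad(rot))
    x_dip = x_vert - qr
    w = float(spec.width_factor(level))
    y_dip = -(spec.b0 * w - spec.dip_depth)
    y_vert = y_dip + spec.d_skin
    # body-to-skin distance measured numerically along -y at the body's x
    pts = contour.points
    posterior = pts[pts[:, 1] < 0]
    order = np.argsort(posterior[:, 0])
    y_back = float(np.interp(x_vert, posterior[order, 0], posterior[order, 1]))
    return {
        "rotation": rot,
        "spine": (x_vert, y_vert),
        "dip": (x_dip, y_dip),
        "delta": y_vert - y_back,
        "area": contour.area,
    }


def generate_contour(spec: TorsoSpec, level: float, n_points: int = 512) -> tuple[ContourLine, dict]:
    """One analytic cross-section contour at ``level`` plus its ground truth.

    The contour is noise-free (noise is a mesh-level property); it is
    exactly mirror-symmetric about x = 0 when the rotation profile and the
    spine polynomial both vanish.
    """
    if not 0.0 <= level <= spec.height:
        raise ValidationError("level outside the torso height")
    theta = np.arange(n_points) * (2 * np.pi / n_points)
    r = _radius(spec, level, theta)
    rot = float(spec.rotation_deg(level))
    x_vert = float(spec.spine_x(level))
    centre_x = x_vert - spec.d_skin * np.tan(np.deg2rad(rot))  # dip follows the process
    pts = np.column_stack([centre_x + r * np.cos(theta), r * np.sin(theta)])
    contour = ContourLine(level=float(level), points=pts)
    return contour, _level_truth(spec, level, contour)


def generate_torso(spec: TorsoSpec) -> tuple[SurfaceScan, GroundTruth]:
    """Closed triangle mesh of the torso plus per-level ground truth.

    Cross-section rings are stacked along z, triangulated side-by-side and
    capped with fans; Gaussian vertex noise of ``noise_sigma`` mm is added
    with the spec's seed (bit-identical output for identical spec + seed).
    """
    nt, nr = spec.n_theta, spec.n_rings
    theta = np.arange(nt) * (2 * np.pi / nt)
    z_rings = np.linspace(0.0, spec.height, nr)
    verts = []
    for z in z_rings:
        r = _radius(spec, float(z), theta)
        rot = float(spec.rotation_deg(z))
        cx = float(spec.spine_x(z)) - spec.d_skin * np.tan(np.deg2rad(rot))
        ring = np.column_stack(
            [cx + r * np.cos(theta), r * np.sin(theta), np.full(nt, z)]
        )
        verts.append(ring)
    vertices = np.vstack(verts)

    faces = []
    for j in range(nr - 1):
        base, nxt = j * nt, (j + 1) * nt
        for i in range(nt):
            i2 = (i + 1) % nt
            faces.append([base + i, base + i2, nxt + i])
            faces.append([base + i2, nxt + i2, nxt + i])
    # caps
    bottom_c = len(vertices)
    top_c = bottom_c + 1
    centres = np.array(
        [
            [vertices[:nt, 0].mean(), vertices[:nt, 1].mean(), 0.0],
            [vertices[-nt:, 0].mean(), vertices[-nt:, 1].mean(), spec.height],
        ]
    )
    vertices = np.vstack([vertices, centres])
    for i in range(nt):
        i2 = (i + 1) % nt
        faces.append([i2, i, bottom_c])
        faces.append([(nr - 1) * nt + i, (nr - 1) * nt + i2, top_c])
    faces = np.asarray(faces, dtype=np.int64)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        vertices = vertices + rng.normal(0.0, spec.noise_sigma, size=vertices.shape)

    scan = SurfaceScan(vertices=vertices, faces=faces, provenance=f"synthetic seed={spec.seed}")

    levels = spec.analysis_levels()
    truth_rows = [generate_contour(spec, float(z))[1] for z in levels]
    truth = GroundTruth(
        levels=levels,
        spine=np.array([[t["spine"][0], t["spine"][1], z] for t, z in zip(truth_rows, levels)]),
        dip=np.array([t["dip"] for t in truth_rows]),
        rotation_deg=np.array([t["rotation"] for t in truth_rows]),
        delta=np.array([t["delta"] for t in truth_rows]),
        area=np.array([t["area"] for t in truth_rows]),
    )
    return scan, truth


def _c_curve(amplitude: float) -> tuple[float, ...]:
    """Parabolic C-curve with apex ``amplitude`` at mid-height, zero at ends."""
    return (0.0, 4.0 * amplitude, -4.0 * amplitude)


def _s_curve(amplitude: float) -> tuple[float, ...]:
    """Cubic S-curve with peak deflection ``amplitude``."""
    scale = amplitude / 0.09622504486493764  # max of zeta(1-zeta)(1-2zeta)
    return (0.0, scale, -3.0 * scale, 2.0 * scale)


PRESETS = {
    "straight": dict(spine_coeffs=(0.0,), rot_max=0.0),
    "c-mild": dict(spine_coeffs=_c_curve(12.0), rot_max=6.0),
    "c-moderate": dict(spine_coeffs=_c_curve(25.0), rot_max=12.0),
    "c-strong": dict(spine_coeffs=_c_curve(55.0), rot_max=22.0),
    "s-curve": dict(spine_coeffs=_s_curve(18.0), rot_max=10.0),
}


def preset(name: str, seed: int = 0, **overrides) -> TorsoSpec:
    """Named torso presets spanning the mild/moderate/strong regimes."""
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return TorsoSpec(seed=seed, **params)
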
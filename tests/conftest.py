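"""Shared fixtures: analytic shapes with known geometry and cached
synthetic torsos."""

from __future__ import annotations

import numpy as np
import pytest

from spinescan.datatypes import ContourLine, SurfaceScan
from spinescan.synthetic import TorsoSpec, generate_torso


def make_ellipse_notch(
    a: float = 150.0,
    b: float = 110.0,
    notch_depth: float = 6.0,
    notch_x: float = 0.0,
    sigma: float = 0.15,
    n: int = 1024,
    centre_x: float = 0.0,
) -> ContourLine:
    """Ellipse with a Gaussian notch toward anterior on the posterior side,
    whose apex sits exactly at x = ``notch_x``.  ``sigma`` is the notch
    width as a fraction of the lateral half-width ``a``."""
    theta = np.arange(n) * (2 * np.pi / n)
    r = 1.0 / np.sqrt((np.cos(theta) / a) ** 2 + (np.sin(theta) / b) ** 2)
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    if notch_depth > 0:
        posterior = y < 0
        g = np.exp(-0.5 * ((x - notch_x) / (sigma * a)) ** 2)
        y = y + notch_depth * g * posterior
    pts = np.column_stack([centre_x + x, y])
    return ContourLine(level=0.0, points=pts)


def make_cylinder_mesh(radius: float = 100.0, height: float = 200.0,
                       n_theta: int = 64, n_rings: int = 21) -> SurfaceScan:
    theta = np.arange(n_theta) * (2 * np.pi / n_theta)
    rings = [
        np.column_stack([radius * np.cos(theta), radius * np.sin(theta), np.full(n_theta, z)])
        for z in np.linspace(0, height, n_rings)
    ]
    verts = np.vstack(rings)
    faces = []
    for j in range(n_rings - 1):
        base, nxt = j * n_theta, (j + 1) * n_theta
        for i in range(n_theta):
            i2 = (i + 1) % n_theta
            faces.append([base + i, base + i2, nxt + i])
            faces.append([base + i2, nxt + i2, nxt + i])
    return SurfaceScan(vertices=verts, faces=np.asarray(faces))


@pytest.fixture(scope="session")
def ellipse_notch_centre() -> ContourLine:
    return make_ellipse_notch()


@pytest.fixture(scope="session")
def cylinder_mesh() -> SurfaceScan:
    return make_cylinder_mesh()


@pytest.fixture(scope="session")
def straight_torso_clean():
    """Noise-free straight-spine torso with ground truth."""
    return generate_torso(TorsoSpec(noise_sigma=0.0, seed=0))


@pytest.fixture(scope="session")
def c_curve_torso():
    """C-curve torso (amplitude 20 mm), 0.5 mm noise, fixed seed."""
    spec = TorsoSpec(noise_sigma=0.5, seed=42, spine_coeffs=(0.0, 80.0, -80.0))
    return generate_torso(spec)
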
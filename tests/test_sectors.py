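"""Sector partition, shoelace areas and the lateral offset correction."""

from __future__ import annotations

import numpy as np
import pytest

from spinescan.contour import detect_dip
from spinescan.datatypes import (
    ContourLine,
    DegenerateSectorError,
    DipEstimate,
    DipConfidence,
    ReflectionAxis,
    SectorPartition,
    ValidationError,
)
from spinescan.sectors import compute_offset, correct_marker, partition_sectors, polygon_area
from spinescan.synthetic import TorsoSpec, generate_contour

from conftest import make_ellipse_notch


def mc_area(points: np.ndarray, n_samples: int, rng: np.random.Generator) -> float:
    """Monte-Carlo rejection-sampling area of the convex hull of points."""
    from scipy.spatial import ConvexHull

    hull = ConvexHull(points)
    verts = points[hull.vertices]
    lo, hi = verts.min(axis=0), verts.max(axis=0)
    samples = rng.uniform(lo, hi, size=(n_samples, 2))
    # inside test: on the inner side of every hull edge (CCW order)
    edges = np.roll(verts, -1, axis=0) - verts
    rel = samples[:, None, :] - verts[None, :, :]
    cross = edges[None, :, 0] * rel[:, :, 1] - edges[None, :, 1] * rel[:, :, 0]
    inside = np.all(cross >= 0, axis=1) | np.all(cross <= 0, axis=1)
    box = np.prod(hi - lo)
    return float(inside.mean() * box)


class TestPolygonArea:
    def test_unit_square(self):
        assert polygon_area([(0, 0), (1, 0), (1, 1), (0, 1)]) == 1.0

    def test_triangle(self):
        assert polygon_area([(0, 0), (1, 0), (0, 1)]) == 0.5

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            polygon_area([(0, 0), (1, 1)])

    def test_random_25gon_against_monte_carlo(self):
        rng = np.random.default_rng(2024)
        pts = rng.normal(0, 40, size=(25, 2))
        exact = polygon_area(pts)
        approx = mc_area(pts, 1_000_000, rng)
        assert abs(exact - approx) / exact < 0.005


class TestPartitionSectors:
    def test_symmetric_contour_balanced(self, ellipse_notch_centre):
        part = partition_sectors(ellipse_notch_centre, dip=(0.0, -104.0), d=50.0)
        assert abs(part.A - part.B) / (part.A + part.B) < 0.005
        assert abs(part.C - part.D) / (part.C + part.D) < 0.005

    def test_rectangle_quarters(self):
        t = np.linspace(0, 1, 201)
        top = np.column_stack([200 * t - 100, np.full_like(t, 50.0)])
        bottom = np.column_stack([100 - 200 * t, np.full_like(t, -50.0)])
        right = np.column_stack([np.full(99, 100.0), np.linspace(-49.5, 49.5, 99)])
        left = np.column_stack([np.full(99, -100.0), np.linspace(49.5, -49.5, 99)])
        pts = np.vstack([bottom, left, top, right])
        contour = ContourLine(level=0.0, points=pts)
        part = partition_sectors(contour, dip=(0.0, -50.0), d=50.0)
        for area in (part.A, part.B, part.C, part.D):
            assert abs(area - 5000.0) < 25.0
        assert np.isclose(part.R_omega, 100.0, atol=1.0)

    def test_rotated_vertebra_sign(self):
        """Rotation to the right produces A > B (hump on the right)."""
        spec = TorsoSpec(noise_sigma=0.0, rot_max=15.0, spine_coeffs=(0.0, 80.0, -80.0))
        contour, _ = generate_contour(spec, 225.0)
        dip = detect_dip(contour)
        part = partition_sectors(contour, dip.position, d=50.0)
        assert part.A != part.B
        assert compute_offset(part) > 0

    def test_degenerate_sector_flagged(self):
        contour = make_ellipse_notch()
        with pytest.raises((DegenerateSectorError, ValidationError)):
            # dip far off the contour pushes the crosslines outside
            partition_sectors(contour, dip=(0.0, -104.0), d=500.0)


class TestComputeOffset:
    def test_symmetric_zero(self):
        part = SectorPartition(d=50, dip=(0, 0), A=100, B=100, C=80, D=80, R_omega=60)
        assert compute_offset(part) == 0.0

    def test_hand_evaluated_posterior_imbalance(self):
        part = SectorPartition(d=50, dip=(0, 0), A=100, B=100, C=60, D=40, R_omega=50)
        assert np.isclose(compute_offset(part), 10.0)

    def test_hand_evaluated_both_negative(self):
        part = SectorPartition(d=50, dip=(0, 0), A=40, B=60, C=40, D=60, R_omega=50)
        assert np.isclose(compute_offset(part), -20.0)

    def test_second_term_grouping(self):
        part = SectorPartition(d=50, dip=(0, 0), A=100, B=100, C=60, D=40, R_omega=50)
        assert np.isclose(compute_offset(part, grouping="second-term"), 10.0)
        part2 = SectorPartition(d=50, dip=(0, 0), A=150, B=50, C=80, D=80, R_omega=50)
        assert np.isclose(compute_offset(part2, grouping="second-term"), 0.5)

    def test_bounded_magnitude(self):
        part = SectorPartition(d=50, dip=(0, 0), A=1, B=1000, C=1, D=1000, R_omega=50)
        assert abs(compute_offset(part)) <= 2 * part.R_omega


class TestOffsetProperties:
    def test_antisymmetric_under_mirror(self):
        spec = TorsoSpec(noise_sigma=0.0, rot_max=12.0, spine_coeffs=(0.0, 80.0, -80.0))
        contour, _ = generate_contour(spec, 225.0)
        dip = detect_dip(contour)
        part = partition_sectors(contour, dip.position, d=50.0)
        x_off = compute_offset(part)

        mirrored = ContourLine(level=0.0, points=contour.points * [-1, 1])
        dip_m = detect_dip(mirrored)
        part_m = partition_sectors(mirrored, dip_m.position, d=50.0)
        x_off_m = compute_offset(part_m)
        assert abs(x_off + x_off_m) < 0.01 * part.R_omega

    def test_exact_zero_on_symmetric_analytic_contour(self, ellipse_notch_centre):
        dip = detect_dip(ellipse_notch_centre)
        part = partition_sectors(ellipse_notch_centre, dip.position, d=50.0)
        assert abs(compute_offset(part)) < 1e-9

    def test_monotone_in_rotation(self):
        offsets = []
        for rot in np.linspace(0, 25, 6):
            spec = TorsoSpec(noise_sigma=0.0, rot_max=float(rot), spine_coeffs=(0.0, 80.0, -80.0))
            contour, _ = generate_contour(spec, 225.0)
            dip = detect_dip(contour)
            part = partition_sectors(contour, dip.position, d=50.0)
            offsets.append(abs(compute_offset(part)))
        assert np.all(np.diff(offsets) >= 0)

    def test_shoelace_vs_monte_carlo_small_batch(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            pts = rng.normal(0, 30, size=(rng.integers(5, 30), 2))
            exact = polygon_area(pts)
            approx = mc_area(pts, 400_000, rng)
            assert abs(exact - approx) / exact < 0.005


class TestCorrectMarker:
    def _dip(self, x=3.0):
        return DipEstimate(position=(x, -90.0), depth=5.0, confidence=DipConfidence.CLEAR)

    def test_zero_offset_identity(self):
        m = correct_marker(self._dip(), 0.0, 100.0)
        assert np.allclose(m.corrected_position, m.dip_position)

    def test_additive(self):
        m = correct_marker(self._dip(3.0), 10.0, 100.0)
        assert np.isclose(m.corrected_position[0], 13.0)
        assert np.isclose(m.dip_position[0], 3.0)  # raw dip retained

    def test_corrected_closer_to_vertebral_truth(self):
        """For rotated-vertebra contours the corrected positions beat the
        raw dips in RMS distance to the true vertebral centres."""
        raw_err, corr_err = [], []
        spec = TorsoSpec(noise_sigma=0.0, rot_max=18.0, spine_coeffs=(0.0, 80.0, -80.0))
        for level in np.linspace(60, 390, 9):
            contour, truth = generate_contour(spec, float(level))
            dip = detect_dip(contour)
            part = partition_sectors(contour, dip.position, d=50.0)
            x_off = compute_offset(part)
            marker = correct_marker(dip, x_off, float(level))
            raw_err.append(dip.position[0] - truth["spine"][0])
            corr_err.append(marker.corrected_position[0] - truth["spine"][0])
        rms = lambda v: float(np.sqrt(np.mean(np.square(v))))
        assert rms(corr_err) < rms(raw_err)
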
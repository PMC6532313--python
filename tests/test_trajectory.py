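"""Trajectory assembly, polynomial fitting, included angles, deviation."""

from __future__ import annotations

import numpy as np
import pytest

from spinescan.datatypes import (
    DeviationClass,
    MarkerSet,
    SpinalTrajectory,
    ValidationError,
    VertebralMarker,
)
from spinescan.trajectory import (
    assemble,
    fit_polynomial,
    included_angles,
    lateral_deviation,
    trajectory_spread,
)


def traj_from_poly(coeffs, z=None, n=15, y=0.0):
    z = np.linspace(0, 400, n) if z is None else np.asarray(z)
    x = np.polynomial.polynomial.polyval(z, coeffs)
    return SpinalTrajectory(points=np.column_stack([x, np.full_like(z, y), z]))


class TestAssemble:
    def _markers(self, levels, xs):
        return [
            VertebralMarker(level=float(l), dip_position=(float(x), -90.0), x_off=0.0)
            for l, x in zip(levels, xs)
        ]

    def test_sorted_input_unchanged(self):
        t = assemble(self._markers([0, 100, 200], [1, 2, 3]))
        assert np.allclose(t.z, [0, 100, 200])

    def test_shuffled_input_sorted(self):
        t = assemble(self._markers([200, 0, 100], [3, 1, 2]))
        assert np.allclose(t.z, [0, 100, 200])
        assert np.allclose(t.points[:, 0], [1, 2, 3])

    def test_duplicate_levels_rejected(self):
        with pytest.raises(ValidationError):
            assemble(self._markers([0, 0, 100], [1, 2, 3]))

    def test_markerset_input(self):
        ms = MarkerSet(levels=[0.0, 100.0], x=[1.0, 2.0])
        t = assemble(ms)
        assert len(t) == 2

    def test_corrected_vs_raw_selectable(self):
        markers = [
            VertebralMarker(level=0.0, dip_position=(0.0, -90.0), x_off=5.0),
            VertebralMarker(level=100.0, dip_position=(1.0, -90.0), x_off=5.0),
        ]
        corr = assemble(markers, use_corrected=True)
        raw = assemble(markers, use_corrected=False)
        assert np.allclose(corr.points[:, 0] - raw.points[:, 0], 5.0)


class TestFitPolynomial:
    def test_exact_line(self):
        fit = fit_polynomial(traj_from_poly([2.0, 0.05]), 1)
        assert fit.residual_rms < 1e-9

    def test_exact_quadratic_coefficients(self):
        coeffs = [0.0, 0.4, -0.001]
        fit = fit_polynomial(traj_from_poly(coeffs), 2)
        assert np.allclose(fit.coefficients, coeffs, atol=1e-9)
        assert fit.residual_rms < 1e-9

    def test_degree_n_reproduces_lower_degree_data(self):
        coeffs = [1.0, 0.1, -2e-4]
        for deg in (2, 3, 5, 7):
            fit = fit_polynomial(traj_from_poly(coeffs, n=20), deg)
            assert fit.residual_rms < 1e-8

    def test_residual_non_increasing_in_degree(self):
        rng = np.random.default_rng(5)
        z = np.linspace(0, 400, 20)
        x = 0.3 * np.sin(z / 60.0) * 20 + rng.normal(0, 1, len(z))
        traj = SpinalTrajectory(points=np.column_stack([x, np.zeros_like(z), z]))
        rms = [fit_polynomial(traj, d).residual_rms for d in range(1, 8)]
        assert np.all(np.diff(rms) <= 1e-12)

    def test_noisy_c_curve_amplitude(self):
        """Amplitude of a noisy C-curve recovered within 3*sigma/sqrt(n)."""
        rng = np.random.default_rng(11)
        z = np.linspace(0, 400, 15)
        amp = 20.0
        x = 4 * amp * (z / 400) * (1 - z / 400) + rng.normal(0, 1.0, len(z))
        traj = SpinalTrajectory(points=np.column_stack([x, np.zeros_like(z), z]))
        fit = fit_polynomial(traj, 2)
        apex = fit(200.0)
        assert abs(apex - amp) < 3.0 * 1.0 / np.sqrt(15) * 3  # generous 3-sigma band

    def test_underdetermined_rejected(self):
        with pytest.raises(ValidationError):
            fit_polynomial(traj_from_poly([0.0, 1.0], n=3), 3)

    def test_degree_out_of_range(self):
        with pytest.raises(ValidationError):
            fit_polynomial(traj_from_poly([0.0, 1.0]), 8)


class TestIncludedAngles:
    def test_straight_line_zero(self):
        fit = fit_polynomial(traj_from_poly([5.0, 0.0]), 1)
        assert np.allclose(fit.included_angles, [0.0])

    def test_cubic_closed_form(self):
        # x(z) = a*(z-200)^3 has one inflexion at z=200
        a = 1e-6
        coeffs = np.polynomial.polynomial.polyfromroots([200.0, 200.0, 200.0]) * a
        fit = fit_polynomial(traj_from_poly(coeffs, n=25), 3)
        assert len(fit.inflexion_levels) == 1
        assert np.isclose(fit.inflexion_levels[0], 200.0, atol=1e-6)
        m = lambda z: fit.derivative(z)
        expected = [
            abs(np.degrees(np.arctan(m(0.0)) - np.arctan(m(200.0)))),
            abs(np.degrees(np.arctan(m(200.0)) - np.arctan(m(400.0)))),
        ]
        assert np.allclose(fit.included_angles, expected, atol=1e-9)

    def test_symmetric_s_curve_equal_angles(self):
        # odd cubic about the midpoint: the two included angles match
        coeffs = np.polynomial.polynomial.polyfromroots([0.0, 200.0, 400.0]) * 2e-6
        fit = fit_polynomial(traj_from_poly(coeffs, n=31), 3)
        assert len(fit.included_angles) == 2
        assert abs(fit.included_angles[0] - fit.included_angles[1]) < 1e-6

    def test_quadratic_has_endpoint_knots_only(self):
        fit = fit_polynomial(traj_from_poly([0.0, 0.4, -0.001]), 2)
        assert len(fit.inflexion_levels) == 0
        assert len(fit.included_angles) == 1
        assert fit.included_angles[0] > 0


class TestLateralDeviation:
    def test_straight_trajectory(self):
        summary = lateral_deviation(traj_from_poly([3.0, 0.02]))
        assert summary.max_lateral_deviation < 1e-9
        assert summary.severity is DeviationClass.MILD

    def test_parabolic_arc_apex_15mm(self):
        # apex 15 mm off the chord joining the endpoints
        coeffs = [0.0, 4 * 15.0 / 400, -4 * 15.0 / 400**2]
        fit = fit_polynomial(traj_from_poly(coeffs, n=21), 2)
        summary = lateral_deviation(fit)
        assert np.isclose(summary.max_lateral_deviation, 15.0, atol=0.01)
        assert summary.severity is DeviationClass.MODERATE

    def test_apex_40mm_is_strong(self):
        coeffs = [0.0, 4 * 40.0 / 400, -4 * 40.0 / 400**2]
        fit = fit_polynomial(traj_from_poly(coeffs, n=21), 2)
        summary = lateral_deviation(fit)
        assert np.isclose(summary.max_lateral_deviation, 40.0, atol=0.01)
        assert summary.severity is DeviationClass.STRONG

    def test_boundary_values(self):
        from spinescan.clinical import classify_deviation

        assert classify_deviation(10.0) is DeviationClass.MILD
        assert classify_deviation(20.0) is DeviationClass.STRONG
        assert classify_deviation(15.0) is DeviationClass.MODERATE

    def test_rigid_invariance(self):
        coeffs = [0.0, 4 * 25.0 / 400, -4 * 25.0 / 400**2]
        traj = traj_from_poly(coeffs, n=21)
        base = lateral_deviation(traj).max_lateral_deviation
        th = np.deg2rad(17.0)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        xz = traj.points[:, [0, 2]] @ rot.T + [40.0, 10.0]
        order = np.argsort(xz[:, 1])
        moved = SpinalTrajectory(
            points=np.column_stack([xz[order, 0], np.zeros(len(xz)), xz[order, 1]])
        )
        assert np.isclose(lateral_deviation(moved).max_lateral_deviation, base, atol=1e-6)


class TestTrajectorySpread:
    def test_identical_trajectories_zero(self):
        t = traj_from_poly([0.0, 0.05])
        _, sd, mx = trajectory_spread([t, t, t])
        assert np.allclose(sd, 0.0)
        assert mx < 1e-12

    def test_two_offset_lines(self):
        t1 = traj_from_poly([0.0, 0.05])
        t2 = traj_from_poly([4.0, 0.05])  # offset 2w with w = 2
        _, sd, mx = trajectory_spread([t1, t2])
        assert np.allclose(sd, 2.0 * np.sqrt(2.0))
        assert np.isclose(mx, 2.0 * np.sqrt(2.0))

    def test_jittered_repeats_match_sigma(self):
        rng = np.random.default_rng(21)
        sigma = 1.5
        trajs = []
        for _ in range(40):
            z = np.linspace(0, 400, 15)
            x = 0.05 * z + rng.normal(0, sigma, len(z))
            trajs.append(SpinalTrajectory(points=np.column_stack([x, np.zeros_like(z), z])))
        _, sd, mx = trajectory_spread(trajs)
        assert abs(np.median(sd) - sigma) < 0.4

    def test_non_overlapping_ranges_error(self):
        t1 = traj_from_poly([0.0, 0.05], z=np.linspace(0, 100, 5))
        t2 = traj_from_poly([0.0, 0.05], z=np.linspace(200, 300, 5))
        with pytest.raises(ValidationError):
            trajectory_spread([t1, t2])
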
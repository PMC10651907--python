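"""Rotation, interpolation and path-length primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from activegaze.errors import InvalidInputError
from activegaze.geometry import (
    Pose6DOF,
    angular_difference,
    angular_velocity_series,
    path_length,
    quat_angle_deg,
    quat_from_axis_angle,
    quat_multiply,
    quat_conjugate,
    random_unit_quaternion,
    slerp_pose,
    unit,
)


def _pose(t, pos, quat):
    return Pose6DOF(t=t, position=np.array(pos, float), orientation=quat)


IDENT = np.array([1.0, 0.0, 0.0, 0.0])


class TestSlerpPose:
    def setup_method(self):
        self.p0 = _pose(0.0, (0, 0, 0), IDENT)
        self.p1 = _pose(1.0, (1, 0, 0), quat_from_axis_angle((0, 0, 1), 90.0))

    def test_boundaries_are_exact(self):
        for u, ref in [(0.0, self.p0), (1.0, self.p1)]:
            out = slerp_pose(self.p0, self.p1, u)
            np.testing.assert_allclose(out.position, ref.position, atol=1e-12)
            assert angular_difference(out.orientation, ref.orientation) < 1e-9

    def test_midpoint_is_half_translation_half_rotation(self):
        mid = slerp_pose(self.p0, self.p1, 0.5)
        np.testing.assert_allclose(mid.position, [0.5, 0, 0], atol=1e-12)
        assert angular_difference(mid.orientation, IDENT) == pytest.approx(45.0, abs=1e-9)

    def test_rotation_angle_monotone_in_u(self):
        us = np.linspace(0, 1, 21)
        angles = [
            angular_difference(slerp_pose(self.p0, self.p1, u).orientation, IDENT)
            for u in us
        ]
        assert np.all(np.diff(angles) >= -1e-12)

    @pytest.mark.parametrize("u", [-0.1, 1.1, float("nan")])
    def test_bad_fraction_rejected(self, u):
        with pytest.raises(InvalidInputError):
            slerp_pose(self.p0, self.p1, u)

    def test_non_finite_position_rejected(self):
        with pytest.raises(InvalidInputError):
            _pose(0.0, (np.inf, 0, 0), IDENT)


class TestAngularDifference:
    def test_identity_is_zero(self):
        q = quat_from_axis_angle((0.3, 0.4, 0.5), 33.0)
        assert angular_difference(q, q) == pytest.approx(0.0, abs=1e-9)

    def test_quarter_turn(self):
        q = quat_from_axis_angle((0, 0, 1), 90.0)
        assert angular_difference(IDENT, q) == pytest.approx(90.0, abs=1e-9)

    def test_matches_rotation_matrix_trace_oracle(self, rng):
        """Geodesic angle equals the angle recovered from tr(R_rel)."""
        for _ in range(100):
            q1 = random_unit_quaternion(rng)
            q2 = random_unit_quaternion(rng)
            got = angular_difference(q1, q2)
            rel = quat_multiply(q1, quat_conjugate(q2))
            w, x, y, z = rel
            r = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ])
            expected = np.degrees(np.arccos(np.clip((np.trace(r) - 1) / 2, -1, 1)))
            assert got == pytest.approx(expected, abs=1e-6)

    def test_symmetric_and_triangle_inequality(self, rng):
        for _ in range(50):
            qa, qb, qc = (random_unit_quaternion(rng) for _ in range(3))
            ab = angular_difference(qa, qb)
            assert ab == pytest.approx(angular_difference(qb, qa), abs=1e-9)
            assert ab <= angular_difference(qa, qc) + angular_difference(qc, qb) + 1e-9

    def test_non_unit_rejected(self):
        with pytest.raises(InvalidInputError):
            angular_difference(IDENT, np.array([2.0, 0, 0, 0]))


class TestAngularVelocity:
    def test_constant_direction_gives_zeros(self):
        dirs = np.tile([1.0, 0, 0], (20, 1))
        ts = np.arange(20) * 0.02
        np.testing.assert_allclose(angular_velocity_series(dirs, ts), 0.0, atol=1e-9)

    def test_two_samples_one_degree_apart(self):
        d0 = np.array([1.0, 0, 0])
        d1 = unit([np.cos(np.radians(1.0)), np.sin(np.radians(1.0)), 0])
        v = angular_velocity_series(np.array([d0, d1]), [0.0, 0.02])
        np.testing.assert_allclose(v, [50.0, 50.0], atol=1e-9)

    def test_central_difference_matches_pair_average_on_great_circle(self, rng):
        """Along a great circle with uniform sampling, the central estimate
        equals the mean of the adjacent per-pair arccos velocities."""
        angles = np.cumsum(rng.uniform(0.2, 1.0, 30))
        dirs = np.column_stack(
            [np.cos(np.radians(angles)), np.sin(np.radians(angles)), np.zeros(30)]
        )
        ts = np.arange(30) * 0.02
        v = angular_velocity_series(dirs, ts)
        pair = np.degrees(
            np.arccos(np.clip(np.sum(dirs[:-1] * dirs[1:], axis=1), -1, 1))
        ) / np.diff(ts)
        expected = (pair[:-1] + pair[1:]) / 2.0
        np.testing.assert_allclose(v[1:-1], expected, atol=1e-9)

    def test_duplicate_timestamps_rejected(self):
        dirs = np.tile([1.0, 0, 0], (3, 1))
        with pytest.raises(InvalidInputError):
            angular_velocity_series(dirs, [0.0, 0.0, 0.02])


class TestPathLength:
    def test_single_point_is_zero(self):
        assert path_length(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_three_four_five(self):
        assert path_length(np.array([[0, 0, 0], [3, 4, 0]]), 0.0) == pytest.approx(5.0)

    def test_threshold_suppresses_stationary_noise(self):
        """A stationary head with 0.2 mm/axis noise accumulates < 5% of the
        naive sum when integrated with a 2 mm anchor step."""
        rng = np.random.default_rng(77)
        pts = rng.normal(0.0, 0.0002, (1000, 3))
        naive = path_length(pts, 0.0)
        anchored = path_length(pts, 0.002)
        assert anchored < 0.05 * naive

    def test_non_increasing_in_min_step(self):
        rng = np.random.default_rng(5)
        pts = np.cumsum(rng.normal(0, 0.01, (200, 3)), axis=0)
        lengths = [path_length(pts, s) for s in [0.0, 0.001, 0.005, 0.02, 0.1]]
        assert all(a >= b - 1e-12 for a, b in zip(lengths, lengths[1:]))

    def test_zero_step_equals_naive_sum(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(0, 1, (50, 3))
        expected = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
        assert path_length(pts, 0.0) == pytest.approx(expected, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            path_length(np.empty((0, 3)))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(0.0, 1.0), st.integers(0, 2**31 - 1))
def test_slerp_orientation_angle_proportional(u, seed):
    """Slerp between identity and a fixed rotation scales the angle by u."""
    r = np.random.default_rng(seed)
    axis = unit(r.normal(size=3))
    total = r.uniform(1.0, 179.0)
    p0 = Pose6DOF(0.0, np.zeros(3), IDENT)
    p1 = Pose6DOF(1.0, np.zeros(3), quat_from_axis_angle(axis, total))
    out = slerp_pose(p0, p1, u)
    assert quat_angle_deg(out.orientation) == pytest.approx(u * total, abs=1e-6)
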
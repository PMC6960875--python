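"""Quaternion algebra: printed-formula fidelity and rotation-oracle checks.

The independent oracle throughout is scipy's Rotation (quaternion -> 3x3
rotation matrix), which fixes the composition and handedness conventions
empirically.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from headgest import quaternion as hq
from tests.conftest import random_unit_quaternions


class TestNormalize:
    @pytest.mark.parametrize(
        "q, expected",
        [
            ([0, 0, 0, 2], [0, 0, 0, 1]),
            ([0.6, 0, 0.8, 0], [0.6, 0, 0.8, 0]),
            ([1, 1, 1, 1], [0.5, 0.5, 0.5, 0.5]),
        ],
    )
    def test_examples(self, q, expected):
        assert np.allclose(hq.normalize(q), expected, atol=1e-15)

    def test_zero_norm_rejected_with_index(self):
        with pytest.raises(ValueError, match="index 1"):
            hq.normalize(np.array([[0, 0, 0, 1.0], [0, 0, 0, 0.0]]))


class TestMultiply:
    def test_identity_both_sides(self, rng):
        q = random_unit_quaternions(rng, 10)
        identity = np.array([0.0, 0.0, 0.0, 1.0])
        assert np.allclose(hq.multiply(q, identity), q, atol=1e-15)
        assert np.allclose(hq.multiply(identity, q), q, atol=1e-15)

    def test_norm_multiplicative(self, rng):
        a = rng.normal(size=(1000, 4))
        b = rng.normal(size=(1000, 4))
        assert np.allclose(
            hq.qnorm(hq.multiply(a, b)), hq.qnorm(a) * hq.qnorm(b), atol=1e-9
        )

    def test_composition_order_is_apply_first_then_second(self):
        """Two 90-degree z-rotations compose to a 180-degree z-rotation, and
        the product's matrix factors as R(second) @ R(first)."""
        s = np.sin(np.pi / 4)
        qz90 = np.array([0, 0, s, np.cos(np.pi / 4)])
        prod = hq.multiply(qz90, qz90)
        expected = Rotation.from_euler("z", 180, degrees=True).as_matrix()
        assert np.allclose(Rotation.from_quat(prod).as_matrix(), expected, atol=1e-12)

    def test_matrix_factorization_on_random_pairs(self, rng):
        for _ in range(50):
            a, b = random_unit_quaternions(rng, 2)
            Rm = Rotation.from_quat(hq.multiply(a, b)).as_matrix()
            Rab = Rotation.from_quat(b).as_matrix() @ Rotation.from_quat(a).as_matrix()
            assert np.allclose(Rm, Rab, atol=1e-12)


class TestInverse:
    def test_identity_self_inverse(self):
        assert np.allclose(hq.inverse([0, 0, 0, 1]), [0, 0, 0, 1])

    def test_non_unit_scaling(self):
        assert np.allclose(hq.inverse([0, 0, 0, 2]), [0, 0, 0, 0.5])

    def test_defining_property(self, rng):
        for q in random_unit_quaternions(rng, 20):
            assert np.allclose(hq.multiply(q, hq.inverse(q)), [0, 0, 0, 1], atol=1e-12)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            hq.inverse([0.0, 0, 0, 0])


class TestAngle:
    def test_self_angle_zero(self, rng):
        for q in random_unit_quaternions(rng, 5):
            assert hq.angle(q, q) == pytest.approx(0.0, abs=1e-9)

    def test_quarter_turn(self):
        q90x = [np.sin(np.pi / 4), 0, 0, np.cos(np.pi / 4)]
        assert hq.angle([0, 0, 0, 1], q90x) == pytest.approx(np.pi / 2, abs=1e-12)

    def test_matches_rotation_matrix_geodesic(self, rng):
        for _ in range(200):
            q1, q2 = random_unit_quaternions(rng, 2)
            R1 = Rotation.from_quat(q1).as_matrix()
            R2 = Rotation.from_quat(q2).as_matrix()
            oracle = np.arccos(np.clip((np.trace(R1.T @ R2) - 1) / 2, -1, 1))
            assert hq.angle(q1, q2) == pytest.approx(oracle, abs=1e-9)

    def test_symmetry_and_sign_invariance(self, rng):
        for _ in range(100):
            q1, q2 = random_unit_quaternions(rng, 2)
            a = hq.angle(q1, q2)
            assert abs(a - hq.angle(q2, q1)) < 1e-12
            assert abs(a - hq.angle(-q1, q2)) < 1e-12
            assert abs(a - hq.angle(q1, -q2)) < 1e-12
            assert abs(a - hq.angle(-q1, -q2)) < 1e-12
            assert 0.0 <= a <= np.pi


class TestRotateToVector:
    def test_identity_points_forward(self):
        assert np.allclose(hq.rotate_to_vector([0, 0, 0, 1]), [0, 0, 1])

    def test_matches_rotation_matrix_oracle(self, rng):
        Q = random_unit_quaternions(rng, 1000)
        expected = Rotation.from_quat(Q).apply([0.0, 0.0, 1.0])
        assert np.allclose(hq.to_spatial(Q), expected, atol=1e-9)

    def test_output_unit_norm(self, rng):
        v = hq.to_spatial(random_unit_quaternions(rng, 100))
        assert np.allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-9)

    def test_rejects_non_unit(self):
        with pytest.raises(ValueError, match="normalize"):
            hq.rotate_to_vector([0, 0, 0, 2.0])


class TestMarkleyMean:
    def test_copies_recover_input(self, rng):
        q = random_unit_quaternions(rng, 1)[0]
        if q[3] < 0:
            q = -q
        m = hq.markley_mean(np.tile(q, (5, 1)))
        assert np.allclose(m, q, atol=1e-10)

    def test_two_quaternion_closed_form(self, rng):
        for _ in range(100):
            q1, q2 = random_unit_quaternions(rng, 2)
            if np.dot(q1, q2) < 0:
                q2 = -q2
            expected = hq.normalize(q1 + q2)
            if expected[3] < 0:
                expected = -expected
            assert np.allclose(hq.markley_mean(np.stack([q1, q2])), expected, atol=1e-10)

    def test_sign_invariance(self, rng):
        q = random_unit_quaternions(rng, 3)
        flipped = q * np.array([[1], [-1], [1]])
        assert np.allclose(hq.markley_mean(q), hq.markley_mean(flipped), atol=1e-12)

    def test_perturbed_copies_stay_close(self, rng):
        base = random_unit_quaternions(rng, 1)[0]
        perturbed = []
        for _ in range(50):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            half = np.radians(rng.uniform(0, 5)) / 2
            step = np.concatenate([np.sin(half) * axis, [np.cos(half)]])
            perturbed.append(hq.multiply(base, step))
        m = hq.markley_mean(np.stack(perturbed))
        assert hq.angle(m, base) <= np.radians(5)

    def test_weighted_mean_degenerates_to_heaviest(self, rng):
        q1, q2 = random_unit_quaternions(rng, 2)
        m = hq.markley_mean(np.stack([q1, q2]), weights=[1e9, 1e-9])
        assert min(np.abs(m - q1).max(), np.abs(m + q1).max()) < 1e-6

    def test_empty_and_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            hq.markley_mean(np.empty((0, 4)))
        with pytest.raises(ValueError):
            hq.markley_mean(np.eye(4), weights=[0, 0, 0, 0])


class TestRereference:
    def test_first_sample_identity(self, rng):
        Q = random_unit_quaternions(rng, 20)
        Qr = hq.rereference(Q)
        assert np.allclose(Qr[0], [0, 0, 0, 1], atol=1e-12)

    def test_constant_sequence_all_identity(self, rng):
        q = random_unit_quaternions(rng, 1)[0]
        Qr = hq.rereference(np.tile(q, (10, 1)))
        assert np.allclose(Qr, np.tile([0, 0, 0, 1.0], (10, 1)), atol=1e-12)

    def test_preserves_consecutive_angles(self, rng):
        Q = random_unit_quaternions(rng, 50)
        before = hq.consecutive_angles(Q)
        after = hq.consecutive_angles(hq.rereference(Q))
        assert np.allclose(before, after, atol=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hq.rereference(np.empty((0, 4)))
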
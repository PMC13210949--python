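"""Quaternion algebra against closed forms and the rotation-matrix oracle."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from sparsetrack import quat


def to_scipy(q):
    """w-first → scipy's x,y,z,w rotation."""
    q = np.atleast_2d(q)
    return Rotation.from_quat(q[:, [1, 2, 3, 0]])


def angle_between(q1, q2):
    return quat.geodesic_error_deg(q1, q2)


class TestHamiltonProduct:
    def test_identity_element(self, rng):
        q = quat.random_unit(rng)
        assert np.allclose(quat.hamilton_product(quat.IDENTITY, q), q)
        assert np.allclose(quat.hamilton_product(q, quat.IDENTITY), q)

    def test_ij_equals_k(self):
        i = np.array([0.0, 1.0, 0.0, 0.0])
        j = np.array([0.0, 0.0, 1.0, 0.0])
        assert np.allclose(quat.hamilton_product(i, j), [0, 0, 0, 1])

    def test_matches_rotation_matrix_oracle(self, rng):
        q1 = quat.random_unit(rng, 1000)
        q2 = quat.random_unit(rng, 1000)
        ours = quat.hamilton_product(q1, q2)
        oracle = (to_scipy(q1).as_matrix() @ to_scipy(q2).as_matrix())
        np.testing.assert_allclose(to_scipy(ours).as_matrix(), oracle, atol=1e-9)

    def test_norm_multiplicative(self, rng):
        q1 = quat.random_unit(rng, 100) * 2.0
        q2 = quat.random_unit(rng, 100) * 0.5
        out = quat.hamilton_product(q1, q2)
        np.testing.assert_allclose(np.linalg.norm(out, axis=-1), 1.0, atol=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            quat.hamilton_product(np.array([np.nan, 0, 0, 0]), quat.IDENTITY)


class TestInverse:
    def test_conjugate_form(self):
        q = np.array([0.5, 0.5, 0.5, 0.5])
        assert np.allclose(quat.quat_inverse(q), [0.5, -0.5, -0.5, -0.5])

    def test_identity(self):
        assert np.allclose(quat.quat_inverse(quat.IDENTITY), quat.IDENTITY)

    def test_self_consistency(self, rng):
        q = quat.random_unit(rng, 200)
        prod = quat.hamilton_product(q, quat.quat_inverse(q))
        np.testing.assert_allclose(prod, np.tile(quat.IDENTITY, (200, 1)), atol=1e-9)

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            quat.quat_inverse(np.zeros(4))


class TestCoordPermute:
    def test_upper(self):
        q = np.array([0.1, 0.2, 0.3, 0.4])
        assert np.allclose(quat.coord_permute(q, "upper"), [0.1, 0.3, -0.2, 0.4])

    def test_lower(self):
        q = np.array([0.1, 0.2, 0.3, 0.4])
        assert np.allclose(quat.coord_permute(q, "lower"), [0.1, 0.3, -0.2, -0.4])

    def test_identity_fixed(self):
        for cls in ("upper", "lower"):
            assert np.allclose(quat.coord_permute(quat.IDENTITY, cls), quat.IDENTITY)

    def test_norm_preserved_exactly(self, rng):
        q = quat.random_unit(rng, 50)
        out = quat.coord_permute(q, "upper")
        # a signed permutation preserves the component magnitudes exactly
        np.testing.assert_array_equal(
            np.sort(np.abs(q), axis=-1), np.sort(np.abs(out), axis=-1)
        )

    def test_unknown_class(self):
        with pytest.raises(ValueError):
            quat.coord_permute(quat.IDENTITY, "torso")


class TestBoresight:
    def test_identity_at_calibration_instant(self, rng):
        q0 = quat.random_unit(rng)
        offset = quat.quat_inverse(q0)
        out = quat.boresight_calibrate(q0, offset)
        assert angle_between(out, quat.IDENTITY) < 1e-6

    def test_identity_offset_passthrough(self, rng):
        q = quat.random_unit(rng)
        assert np.allclose(quat.boresight_calibrate(q, quat.IDENTITY), q)

    def test_matrix_oracle(self, rng):
        qg = quat.random_unit(rng, 1000)
        qo = quat.random_unit(rng, 1000)
        ours = quat.boresight_calibrate(qg, qo)
        oracle = to_scipy(qo).as_matrix() @ to_scipy(qg).as_matrix()
        np.testing.assert_allclose(to_scipy(ours).as_matrix(), oracle, atol=1e-9)


class TestSwingTwist:
    def test_pure_twist(self):
        q = quat.from_axis_angle([1, 0, 0], np.radians(40.0))
        st = quat.swing_twist_decompose(q, axis=(1, 0, 0))
        assert angle_between(st.twist, q) < 1e-7
        assert angle_between(st.swing, quat.IDENTITY) < 1e-7

    def test_pure_swing(self):
        q = quat.from_axis_angle([0, 1, 0], np.radians(40.0))
        st = quat.swing_twist_decompose(q, axis=(1, 0, 0))
        assert angle_between(st.twist, quat.IDENTITY) < 1e-7
        assert angle_between(st.swing, q) < 1e-7

    def test_recomposition_10k(self, rng):
        q = quat.random_unit(rng, 10_000)
        st = quat.swing_twist_decompose(q)
        recomposed = quat.hamilton_product(st.swing, st.twist)
        err = np.radians(quat.geodesic_error_deg(recomposed, q))
        assert err.max() < 1e-7

    def test_twist_parallel_to_axis(self, rng):
        q = quat.random_unit(rng, 1000)
        st = quat.swing_twist_decompose(q, axis=(1, 0, 0))
        # off-axis vector components of the twist vanish
        assert np.abs(st.twist[:, 2:]).max() < 1e-7

    def test_degenerate_pure_orthogonal_half_turn(self):
        q = quat.from_axis_angle([0, 1, 0], np.pi)  # w = 0, v ⟂ axis
        st = quat.swing_twist_decompose(q, axis=(1, 0, 0))
        assert np.allclose(st.twist, quat.IDENTITY)
        assert np.allclose(st.swing, q)

    def test_near_degenerate_recomposition(self, rng):
        angles = np.pi - 10.0 ** rng.uniform(-10, -6, 500)
        axes = np.stack([np.zeros(500), np.cos(t := rng.uniform(0, 2 * np.pi, 500)), np.sin(t)], axis=-1)
        q = quat.from_axis_angle(axes, angles)
        st = quat.swing_twist_decompose(q, axis=(1, 0, 0))
        recomposed = quat.hamilton_product(st.swing, st.twist)
        assert np.radians(quat.geodesic_error_deg(recomposed, q)).max() < 1e-7


class TestRelativeRotation:
    def test_equal_inputs(self, rng):
        q = quat.random_unit(rng)
        assert angle_between(quat.relative_rotation(q, q), quat.IDENTITY) < 1e-7

    def test_against_identity_distal(self):
        q = quat.from_axis_angle([0, 0, 1], np.pi / 2)
        assert np.allclose(quat.relative_rotation(q, quat.IDENTITY), q)

    def test_recomposes_proximal(self, rng):
        qp = quat.random_unit(rng, 500)
        qd = quat.random_unit(rng, 500)
        q_rel = quat.relative_rotation(qp, qd)
        back = quat.hamilton_product(q_rel, qd)
        assert quat.geodesic_error_deg(back, qp).max() < 1e-4


class TestGeodesicError:
    def test_zero_for_equal(self, rng):
        q = quat.random_unit(rng, 100)
        assert np.allclose(quat.geodesic_error_deg(q, q), 0.0, atol=1e-4)

    def test_zero_for_antipodal(self, rng):
        q = quat.random_unit(rng, 100)
        assert np.allclose(quat.geodesic_error_deg(q, -q), 0.0, atol=1e-5)

    def test_ninety_degrees(self):
        q = quat.from_axis_angle([1, 0, 0], np.pi / 2)
        assert abs(quat.geodesic_error_deg(q, quat.IDENTITY) - 90.0) < 1e-9

    def test_range(self, rng):
        e = quat.geodesic_error_deg(quat.random_unit(rng, 1000), quat.random_unit(rng, 1000))
        assert np.all((e >= 0) & (e <= 180.0))


class TestAvatarCalibration:
    def test_equal_tpose_is_identity_offset(self, rng):
        qt = quat.random_unit(rng)
        qr = quat.random_unit(rng)
        assert np.allclose(quat.avatar_calibration(qt, qt, qr), qr, atol=1e-12)

    def test_tpose_instant_maps_to_avatar(self, rng):
        qs = quat.random_unit(rng)
        qa = quat.random_unit(rng)
        out = quat.avatar_calibration(qs, qa, q_raw=qs)
        assert angle_between(out, qa) < 1e-4

    def test_matrix_oracle(self, rng):
        qs = quat.random_unit(rng, 1000)
        qa = quat.random_unit(rng, 1000)
        qr = quat.random_unit(rng, 1000)
        ours = quat.avatar_calibration(qs, qa, qr)
        oracle = (
            to_scipy(qr).as_matrix()
            @ to_scipy(qs).as_matrix().transpose(0, 2, 1)
            @ to_scipy(qa).as_matrix()
        )
        np.testing.assert_allclose(to_scipy(ours).as_matrix(), oracle, atol=1e-9)


class TestLogExp:
    def test_log_identity(self):
        assert np.allclose(quat.quat_log(quat.IDENTITY), 0.0)

    def test_exp_ninety_about_x(self):
        q = quat.quat_exp(np.array([np.pi / 2, 0, 0]))
        assert np.allclose(q, [np.cos(np.pi / 4), np.sin(np.pi / 4), 0, 0])

    def test_round_trip_1000(self, rng):
        q = quat.random_unit(rng, 1000)
        back = quat.quat_exp(quat.quat_log(q))
        assert np.radians(quat.geodesic_error_deg(back, q)).max() < 1e-7

    def test_near_identity_no_blowup(self):
        v = np.array([1e-12, 0, 0])
        q = quat.quat_exp(v)
        assert np.all(np.isfinite(q))
        assert np.allclose(quat.quat_log(q), v, atol=1e-15)


def test_norm_preservation_across_operations(rng):
    q1 = quat.random_unit(rng, 300)
    q2 = quat.random_unit(rng, 300)
    outs = [
        quat.hamilton_product(q1, q2),
        quat.quat_inverse(q1),
        quat.coord_permute(q1, "upper"),
        quat.boresight_calibrate(q1, q2),
        quat.relative_rotation(q1, q2),
        quat.swing_twist_decompose(q1).swing,
        quat.swing_twist_decompose(q1).twist,
        quat.quat_exp(quat.quat_log(q1)),
    ]
    for out in outs:
        np.testing.assert_allclose(np.linalg.norm(out, axis=-1), 1.0, atol=1e-9)


def test_canonicalize_nonnegative_w(rng):
    q = quat.random_unit(rng, 100)
    c = quat.canonicalize(q)
    assert np.all(c[:, 0] >= 0)
    assert np.allclose(quat.geodesic_error_deg(c, q), 0.0, atol=1e-4)


# -- hypothesis property tests ------------------------------------------------

from hypothesis import given
from hypothesis import strategies as st

finite4 = st.lists(
    st.floats(min_value=-1e3, max_value=1e3, allow_nan=False), min_size=4, max_size=4
).filter(lambda v: sum(x * x for x in v) > 1e-6)


@given(finite4)
def test_normalize_then_exp_log_round_trip(vec):
    q = quat.normalize(np.array(vec))
    back = quat.quat_exp(quat.quat_log(q))
    assert np.radians(quat.geodesic_error_deg(back, q)) < 1e-7


@given(finite4, finite4)
def test_product_norm_and_geodesic_symmetry(v1, v2):
    q1 = quat.normalize(np.array(v1))
    q2 = quat.normalize(np.array(v2))
    prod = quat.hamilton_product(q1, q2)
    assert abs(np.linalg.norm(prod) - 1.0) < 1e-9
    assert abs(quat.geodesic_error_deg(q1, q2) - quat.geodesic_error_deg(q2, q1)) < 1e-6
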
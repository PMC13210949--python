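"""Stream sanitization, normalization, windowing, targets and mixing."""

import numpy as np
import pytest

from sparsetrack import features as F
from sparsetrack import quat


def make_stream(T=60, seed=0):
    rng = np.random.default_rng(seed)
    return F.SensorStream(
        time=np.arange(T) / 60.0,
        quat=quat.random_unit(rng, (T, 5)),
        gyro=rng.standard_normal((T, 5, 3)),
        acc=rng.standard_normal((T, 5, 3)),
    )


class TestSanitize:
    def test_clean_series_unchanged(self):
        s = make_stream(600)
        out = F.sanitize_stream(s)
        assert isinstance(out, F.SensorStream)
        np.testing.assert_array_equal(out.gyro, s.gyro)

    def test_inf_rejected_with_report(self):
        s = make_stream(100)
        s.acc[50, 2, 1] = np.inf
        out = F.sanitize_stream(s)
        assert isinstance(out, F.RejectionReport)
        assert "infinite" in out.reason

    def test_long_nan_gap_rejected(self):
        s = make_stream(100)
        s.gyro[40:44] = np.nan  # 4 >= max_gap=3
        out = F.sanitize_stream(s)
        assert isinstance(out, F.RejectionReport)
        assert out.longest_gap == 4

    def test_single_nan_interpolated_midpoint(self):
        s = make_stream(100)
        # smooth rotation: frames 49/51 at 10° and 20° about x per sensor
        s.quat[49] = quat.from_axis_angle([1, 0, 0], np.full(5, np.radians(10.0)))
        s.quat[51] = quat.from_axis_angle([1, 0, 0], np.full(5, np.radians(20.0)))
        s.gyro[50] = np.nan
        s.quat[50] = np.nan
        out = F.sanitize_stream(s)
        assert isinstance(out, F.SensorStream)
        np.testing.assert_allclose(out.gyro[50], (s.gyro[49] + s.gyro[51]) / 2)
        expected_q = quat.from_axis_angle([1, 0, 0], np.full(5, np.radians(15.0)))
        # nlerp of nearby frames lands within a small fraction of a degree of slerp
        assert quat.geodesic_error_deg(out.quat[50], expected_q).max() < 0.01

    def test_non_monotonic_time_raises(self):
        s = make_stream(10)
        s.time[5] = s.time[3]
        with pytest.raises(F.StreamFormatError):
            F.sanitize_stream(s)


class TestNormStats:
    def test_all_zero_omega_hits_sigma_floor(self):
        s = make_stream(50)
        s.gyro[:] = 0.0
        stats = F.compute_norm_stats([s])
        assert np.all(stats.mu[:, 0] == 0.0)
        assert np.all(stats.sigma[:, 0] == F.EPS)

    def test_pooled_mean_over_axes(self):
        s = make_stream(30)
        s.gyro[:] = np.array([1.0, 2.0, 3.0])  # same per axis on every sensor
        stats = F.compute_norm_stats([s])
        np.testing.assert_allclose(stats.mu[:, 0], 2.0)

    def test_axis_permutation_invariance(self):
        s = make_stream(40)
        s2 = s.copy()
        s2.gyro = s2.gyro[:, :, [2, 0, 1]]
        s2.acc = s2.acc[:, :, [1, 2, 0]]
        a, b = F.compute_norm_stats([s]), F.compute_norm_stats([s2])
        np.testing.assert_allclose(a.mu, b.mu)
        np.testing.assert_allclose(a.sigma, b.sigma)

    def test_empty_collection_raises(self):
        with pytest.raises(ValueError):
            F.compute_norm_stats([])


class TestZnormClamp:
    def test_at_mean(self):
        assert F.znorm_clamp(3.0, 3.0, 2.0) == 0.0

    def test_ten_sigma_clamped_to_five(self):
        assert F.znorm_clamp(10.0, 0.0, 1.0) == 5.0

    def test_minus_two_sigma(self):
        assert abs(F.znorm_clamp(-2.0, 0.0, 1.0) + 2.0) < 1e-6

    def test_gaussian_clamp_fraction_tiny(self):
        rng = np.random.default_rng(99)
        x = rng.standard_normal(1_000_000)
        frac = np.mean(np.abs(F.znorm_clamp(x, 0.0, 1.0)) == 5.0)
        # two-sided tail mass beyond 5σ is ≈5.7e-7
        assert frac <= 2e-6


class TestAssembleFeatures:
    def test_fifty_columns(self):
        s = make_stream(30)
        stats = F.compute_norm_stats([s])
        out = F.assemble_features(s, stats)
        assert out.shape == (30, 50)

    def test_static_identity_pose(self):
        s = make_stream(20)
        s.quat[:] = quat.IDENTITY
        s.gyro[:] = 0.0
        s.acc[:] = 0.0
        mu = np.full((5, 2), 0.5)
        sigma = np.ones((5, 2))
        out = F.assemble_features(s, F.NormStats(mu, sigma))
        for i in range(5):
            block = out[:, i * 10 : (i + 1) * 10]
            np.testing.assert_allclose(block[:, :4], np.tile([1.0, 0, 0, 0], (20, 1)))
            np.testing.assert_allclose(block[:, 4:], -0.5 / (1 + F.EPS))

    def test_quaternion_normalization_idempotent(self):
        s = make_stream(25)
        s.quat *= 3.0  # un-normalized input
        stats = F.compute_norm_stats([s])
        once = F.assemble_features(s, stats)
        s2 = s.copy()
        s2.quat = once[:, :50].reshape(25, 5, 10)[:, :, :4]
        twice = F.assemble_features(
            F.SensorStream(s.time, s2.quat, s.gyro, s.acc), stats
        )
        np.testing.assert_allclose(once[:, :4], twice[:, :4], atol=1e-12)

    def test_sensor_layout_audit(self):
        """Permuting the sensor axis without updating the layout moves the
        quaternion blocks — the fixed 10-column stride detects it."""
        s = make_stream(10)
        stats = F.compute_norm_stats([s])
        base = F.assemble_features(s, stats)
        s2 = s.copy()
        perm = [1, 0, 2, 3, 4]
        s2.quat, s2.gyro, s2.acc = s2.quat[:, perm], s2.gyro[:, perm], s2.acc[:, perm]
        swapped = F.assemble_features(s2, F.NormStats(stats.mu[perm], stats.sigma[perm]))
        assert not np.allclose(base, swapped)
        np.testing.assert_allclose(base[:, :10], swapped[:, 10:20])

    def test_wrong_sensor_count(self):
        s = make_stream(10)
        bad = F.SensorStream(s.time, s.quat[:, :4], s.gyro[:, :4], s.acc[:, :4])
        with pytest.raises(F.StreamFormatError):
            F.assemble_features(bad, F.compute_norm_stats([s]))


class TestTrainingTarget:
    def test_equal_orientations_give_identity_swing(self, rng):
        q = quat.random_unit(rng, (10, 4))
        tgt = F.make_training_target(q, q, np.zeros((10, 4, 3)), np.zeros((10, 4, 3)))
        err_rad = np.radians(quat.geodesic_error_deg(tgt[..., :4], np.broadcast_to(quat.IDENTITY, (10, 4, 4))))
        assert err_rad.max() < 1e-6

    def test_pure_limb_axis_rotation_is_all_twist(self, rng):
        qd = quat.random_unit(rng, 4)
        twist = quat.from_axis_angle([1, 0, 0], np.full(4, 0.7))
        qp = quat.hamilton_product(twist, qd)
        tgt = F.make_training_target(qp, qd, np.zeros((4, 3)), np.zeros((4, 3)))
        err_rad = np.radians(quat.geodesic_error_deg(tgt[..., :4], np.broadcast_to(quat.IDENTITY, (4, 4))))
        assert err_rad.max() < 1e-6

    def test_chain_recomposition(self, rng):
        qp = quat.random_unit(rng, (50, 4))
        qd = quat.random_unit(rng, (50, 4))
        q_rel = quat.relative_rotation(qp, qd)
        st = quat.swing_twist_decompose(q_rel)
        back = quat.hamilton_product(quat.hamilton_product(st.swing, st.twist), qd)
        assert quat.geodesic_error_deg(back, qp).max() < 1e-4

    def test_target_round_trip_on_stream(self, adl_session):
        gt = adl_session.gt
        tgt = F.make_training_target(gt.q_proximal, gt.q_distal, gt.omega, gt.acc)
        assert np.radians(quat.geodesic_error_deg(tgt[..., :4], gt.swing)).max() < 1e-6


class TestSlidingWindows:
    def test_exact_window_count(self):
        feats = np.zeros((120, 50))
        tgts = np.zeros((120, 4, 10))
        X, y = F.sliding_windows(feats, tgts, L=120, stride=30)
        assert X.shape == (1, 120, 50) and y.shape == (1, 4, 10)

    def test_count_formula(self):
        feats = np.zeros((240, 50))
        tgts = np.zeros((240, 4, 10))
        X, _ = F.sliding_windows(feats, tgts, L=120, stride=60)
        assert len(X) == 3

    def test_short_series_empty(self):
        X, y = F.sliding_windows(np.zeros((50, 50)), np.zeros((50, 4, 10)), L=120, stride=30)
        assert len(X) == 0 and len(y) == 0

    def test_causality_future_mutation_invisible(self):
        rng = np.random.default_rng(5)
        feats = rng.standard_normal((150, 50))
        tgts = rng.standard_normal((150, 4, 10))
        X1, y1 = F.sliding_windows(feats, tgts, L=120, stride=120)
        feats2, tgts2 = feats.copy(), tgts.copy()
        feats2[120:] = 999.0
        tgts2[120:] = 999.0
        X2, y2 = F.sliding_windows(feats2, tgts2, L=120, stride=120)
        np.testing.assert_array_equal(X1, X2)
        np.testing.assert_array_equal(y1, y2)


class TestHardNegativeValidity:
    def test_static_true(self):
        assert F.hard_negative_validity(np.zeros((100, 4, 3)))

    def test_single_fast_frame_false(self):
        w = np.zeros((100, 4, 3))
        w[50, 2] = [0.2, 0.0, 0.0]
        assert not F.hard_negative_validity(w)

    def test_boundary_strictly_excluded(self):
        w = np.zeros((10, 4, 3))
        w[0, 0] = [0.1, 0.0, 0.0]
        assert not F.hard_negative_validity(w)


class TestMixBatches:
    def test_ten_percent_of_64_is_six(self):
        assert F.hard_negatives_per_batch(64, 0.1) == 6

    def test_floor_of_one_when_positive(self):
        assert F.hard_negatives_per_batch(64, 0.001) == 1

    def test_r_zero_all_adl(self):
        batches = list(F.mix_batches(200, 50, batch_size=64, r=0.0, seed=0))
        assert all(len(h) == 0 and len(a) == 64 for a, h in batches)

    def test_composition_and_determinism(self):
        b1 = list(F.mix_batches(600, 100, batch_size=64, r=0.1, seed=42))
        b2 = list(F.mix_batches(600, 100, batch_size=64, r=0.1, seed=42))
        assert all(len(h) == 6 and len(a) == 58 for a, h in b1)
        for (a1, h1), (a2, h2) in zip(b1, b2):
            np.testing.assert_array_equal(a1, a2)
            np.testing.assert_array_equal(h1, h2)

    def test_adl_sampled_without_replacement(self):
        batches = list(F.mix_batches(580, 100, batch_size=64, r=0.1, seed=1))
        seen = np.concatenate([a for a, _ in batches])
        assert len(seen) == len(set(seen.tolist()))

    def test_bad_ratio_raises(self):
        with pytest.raises(ValueError):
            F.hard_negatives_per_batch(64, 1.5)


class TestStreamIO:
    def test_csv_round_trip(self, tmp_path):
        s = make_stream(40)
        s.quat = quat.normalize(s.quat)
        path = tmp_path / "stream.csv"
        s.to_csv(path)
        back = F.SensorStream.from_csv(path)
        np.testing.assert_allclose(back.quat, s.quat, atol=1e-12)
        np.testing.assert_allclose(back.gyro, s.gyro, atol=1e-12)
        np.testing.assert_allclose(back.time, s.time, atol=1e-12)

    def test_manifest_round_trip(self, tmp_path):
        m = F.Manifest()
        m.add("a.csv", "adl", "train")
        m.add("b.csv", "hard_negative:elbow_flexion", "test")
        p = tmp_path / "manifest.json"
        m.save(p)
        back = F.Manifest.load(p)
        assert back.entries == m.entries
        assert len(back.files(partition="test")) == 1
        assert len(back.files(label_prefix="hard_negative")) == 1

    def test_manifest_rejects_bad_partition(self):
        with pytest.raises(ValueError):
            F.Manifest().add("a.csv", "adl", "holdout")


# -- hypothesis property tests ------------------------------------------------

from hypothesis import given
from hypothesis import strategies as st


@given(
    st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
    st.floats(min_value=-10, max_value=10),
    st.floats(min_value=1e-6, max_value=100),
)
def test_znorm_clamp_always_bounded(x, mu, sigma):
    out = F.znorm_clamp(x, mu, sigma)
    assert -5.0 <= out <= 5.0


def test_npz_container_round_trip(tmp_path):
    s = make_stream(25)
    path = tmp_path / "stream.npz"
    s.to_npz(path)
    back = F.SensorStream.from_npz(path)
    np.testing.assert_array_equal(back.quat, s.quat)
    np.testing.assert_array_equal(back.time, s.time)
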
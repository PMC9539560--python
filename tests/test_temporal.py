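import numpy as np
import pytest

import rootqsm as rq
from rootqsm.geometry_io import PointCloud
from rootqsm.temporal import (
    RigidTransform,
    coarse_align,
    growth_spread,
    icp,
    transform_qsm,
)


def rot_z(deg):
    a = np.radians(deg)
    return np.array([[np.cos(a), -np.sin(a), 0],
                     [np.sin(a), np.cos(a), 0],
                     [0, 0, 1.0]])


class TestRigidTransform:
    def test_orthonormality_enforced(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2, np.zeros(3))

    def test_reflection_rejected(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            RigidTransform(R, np.zeros(3))

    def test_rotation_only_zero_translation(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3), np.ones(3), rotation_only=True)

    def test_json_roundtrip(self, tmp_path):
        tf = RigidTransform(rot_z(30), np.array([1.0, 2.0, 3.0]))
        tf.to_json(tmp_path / "t.json", rms=0.5)
        back = RigidTransform.from_json(tmp_path / "t.json")
        np.testing.assert_allclose(back.rotation, tf.rotation)
        np.testing.assert_allclose(back.translation, tf.translation)

    def test_composition(self):
        a = RigidTransform(rot_z(20), np.array([1.0, 0, 0]))
        b = RigidTransform(rot_z(15), np.array([0, 2.0, 0]))
        pts = np.random.default_rng(0).normal(size=(10, 3))
        np.testing.assert_allclose(a.compose(b).apply(pts),
                                   a.apply(b.apply(pts)), atol=1e-12)


class TestCoarseAlign:
    def test_recovers_90deg_z_rotation(self):
        src = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1.0], [1, 1, 0]])
        R = rot_z(90)
        pairs = list(zip(src, src @ R.T))
        tf = coarse_align(pairs)
        np.testing.assert_allclose(tf.rotation, R, atol=1e-9)
        np.testing.assert_allclose(tf.translation, 0, atol=1e-9)

    def test_identity_for_identical_pairs(self):
        src = np.array([[1, 0, 0], [0, 2, 0], [0, 0, 3.0]])
        tf = coarse_align(list(zip(src, src)))
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-9)

    def test_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            coarse_align([([0, 0, 0], [0, 0, 0]), ([1, 0, 0], [1, 0, 0])])

    def test_collinear_pairs_rejected(self):
        src = [[0, 0, 0], [1, 0, 0], [2, 0, 0]]
        with pytest.raises(ValueError, match="collinear"):
            coarse_align(list(zip(src, src)))


class TestICP:
    def test_perfect_overlap_recovers_rotation(self, root_mesh):
        mesh, _ = root_mesh
        cloud = PointCloud(mesh.vertices)
        c = cloud.points.mean(0)
        rotated = PointCloud((cloud.points - c) @ rot_z(5).T + c)
        tf, rms, conv = icp(rotated, cloud, overlap_fraction=1.0)
        assert conv
        assert abs(tf.angle_deg - 5.0) < 0.1
        assert rms < 1e-6

    def test_rms_monotone_and_rotation_only_centroid(self, root_mesh):
        mesh, _ = root_mesh
        cloud = PointCloud(mesh.vertices)
        c = cloud.points.mean(0)
        rotated = PointCloud((cloud.points - c) @ rot_z(4).T + c)
        tf, rms, conv = icp(rotated, cloud, overlap_fraction=0.8,
                            rotation_only=True)
        assert conv and abs(tf.angle_deg - 4.0) < 0.2
        np.testing.assert_allclose(tf.translation, 0.0)
        # rotation about the centroid leaves the centroid in place
        moved = tf.apply(rotated.points)
        np.testing.assert_allclose(moved.mean(0), rotated.points.mean(0),
                                   atol=0.3)

    def test_grown_superset_series(self, root_spec):
        """Week-1 vs grown week-2 with a 3 deg perturbation, overlap 0.4."""
        series = rq.generate_series(root_spec, weeks=2, perturb_deg=3.0)
        c1 = PointCloud(series[0]["mesh"].vertices)
        c2 = PointCloud(series[1]["mesh"].vertices)
        tf, rms, conv = icp(c1, c2, overlap_fraction=0.4, rotation_only=True)
        assert conv
        assert abs(tf.angle_deg - 3.0) < 0.5

    def test_disjoint_clouds_flagged(self):
        """Non-overlapping scans cannot be registered by rotation alone:
        the result carries a failure flag and a large residual."""
        rng = np.random.default_rng(0)
        a = PointCloud(rng.normal(size=(300, 3)))
        b = PointCloud(rng.normal(size=(300, 3)) + [200.0, 0, 0])
        with pytest.warns(UserWarning):
            tf, rms, conv = icp(a, b, overlap_fraction=0.5,
                                rotation_only=True)
        assert not conv
        assert rms > 10

    def test_tiny_cloud_rejected(self):
        a = PointCloud(np.random.default_rng(0).normal(size=(20, 3)))
        with pytest.raises(ValueError, match="100"):
            icp(a, a, overlap_fraction=0.5)


class TestGrowthSpread:
    def test_identity_zero_delta(self, root_qsm):
        delta = growth_spread(root_qsm, root_qsm)
        np.testing.assert_allclose(delta.values, 0.0, atol=1e-9)

    def test_new_lateral_shows_in_one_sector(self, root_qsm):
        from rootqsm.cylinder_model import Cylinder, QSM

        extra = Cylinder(start=root_qsm.base_point + [0, 0, -5.0],
                         axis=[1.0, 0, 0], length=8.0, radius=0.1,
                         parent=0, segment_id=99, order=1)
        grown = QSM(list(root_qsm.cylinders) + [extra], sf=root_qsm.sf,
                    seed=0, base_point=root_qsm.base_point)
        delta = growth_spread(root_qsm, grown)
        assert delta.values.max() > 1.0
        # growth concentrated near the +x sector at that depth
        row, col = np.unravel_index(np.argmax(delta.values),
                                    delta.values.shape)
        assert col in (0, 17)

    def test_series_deltas_bounded_growth(self, root_spec):
        """Elongation-only growth: spread deltas are positive on average
        and any negative cell stays within the fitting-jitter floor."""
        series = rq.generate_series(root_spec, weeks=2,
                                    new_laterals_per_week=0)
        qsms = []
        for wk in series:
            cloud = rq.mesh_to_pointcloud(wk["mesh"], 0.8)
            qsms.append(rq.reconstruct(cloud, seed=4))
        delta = growth_spread(qsms[0], qsms[1]).values
        occupied = delta != 0
        assert delta[occupied].mean() > 0
        assert delta.min() > -0.6  # about two patch diameters, physical cm

    def test_transformed_qsm_traits_invariant(self, root_qsm):
        tf = RigidTransform(rot_z(30), np.array([1.0, -2.0, 0.5]))
        moved = transform_qsm(root_qsm, tf)
        t0 = rq.total_traits(root_qsm)
        t1 = rq.total_traits(moved)
        assert t1.volume == pytest.approx(t0.volume, rel=1e-9)
        assert t1.length == pytest.approx(t0.length, rel=1e-9)
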
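import numpy as np
import pytest

import rootqsm as rq
from rootqsm.cylinder_model import (
    Cylinder,
    CylinderFitError,
    EmptyModelError,
    QSM,
    fill_gaps,
    fit_cylinder,
)

from conftest import cylinder_surface_points


class TestFitCylinder:
    def test_noiseless_exact_recovery(self):
        pts = cylinder_surface_points(radius=1.0, length=5.0)
        start, axis, length, radius, rms = fit_cylinder(pts, [0, 0, 1])
        assert abs(radius - 1.0) < 1e-6
        assert abs(length - 5.0) < 1e-6
        assert np.arccos(min(abs(axis @ [0, 0, 1]), 1.0)) < 1e-6
        assert rms < 1e-6

    def test_tilted_axis_recovery(self):
        pts = cylinder_surface_points(radius=0.5, length=4.0)
        axis_true = np.array([1.0, 1.0, 2.0]) / np.sqrt(6.0)
        helper = np.array([0.0, 0.0, 1.0])
        u = np.cross(axis_true, helper)
        u /= np.linalg.norm(u)
        v = np.cross(axis_true, u)
        rot = np.c_[u, v, axis_true]
        tilted = pts @ rot.T
        _, axis, length, radius, _ = fit_cylinder(tilted, axis_true + 0.05)
        assert abs(radius - 0.5) < 1e-6
        assert abs(abs(axis @ axis_true) - 1.0) < 1e-9

    def test_noise_bias_small_over_seeds(self):
        """Radius estimator bias under sigma=0.01 surface noise < 0.005."""
        errs = []
        for seed in range(100):
            pts = cylinder_surface_points(radius=1.0, length=5.0,
                                          noise=0.01, seed=seed)
            *_, radius, rms = fit_cylinder(pts, [0, 0, 1])
            errs.append(radius - 1.0)
        assert abs(np.mean(errs)) < 0.005
        assert 0.005 < rms < 0.02  # rms tracks the noise level

    def test_collinear_points_rejected(self):
        pts = np.c_[np.zeros(10), np.zeros(10), np.linspace(0, 1, 10)]
        with pytest.raises(CylinderFitError):
            fit_cylinder(pts, [0, 0, 1])

    def test_too_few_points_rejected(self):
        with pytest.raises(CylinderFitError):
            fit_cylinder(np.eye(3), [0, 0, 1])


def _chain_qsm(gap=0.0, r1=1.0, r2=1.0):
    c1 = Cylinder(start=[0, 0, 0], axis=[0, 0, -1], length=5.0, radius=r1,
                  segment_id=0)
    c2 = Cylinder(start=[0, 0, -5.0 - gap], axis=[0, 0, -1], length=5.0,
                  radius=r2, parent=0, segment_id=0)
    return QSM([c1, c2], sf=1.0, seed=0, base_point=np.zeros(3))


class TestFillGaps:
    def test_collinear_gap_filled(self):
        out = fill_gaps(_chain_qsm(gap=2.0), tolerance=0.5)
        gaps = [c for c in out.cylinders if c.gap_fill]
        assert len(gaps) == 1
        assert gaps[0].length == pytest.approx(2.0)
        # re-parented through the inserted cylinder
        assert out.cylinders[1].parent == 2
        assert gaps[0].parent == 0

    def test_contiguous_chain_untouched(self):
        out = fill_gaps(_chain_qsm(gap=0.0), tolerance=0.5)
        assert len(out.cylinders) == 2

    def test_radius_interpolation(self):
        out = fill_gaps(_chain_qsm(gap=3.0, r1=2.0, r2=1.0), tolerance=0.5)
        gap = next(c for c in out.cylinders if c.gap_fill)
        assert gap.radius == pytest.approx(1.5)


class TestModelSegmentViaPipeline:
    def test_straight_tube_length_recovered(self):
        """Cylinder chain over a plain tube sums to the tube length."""
        theta = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        z = np.linspace(0, -10, 120)
        T, Z = np.meshgrid(theta, z)
        pts = np.c_[0.4 * np.cos(T).ravel(), 0.4 * np.sin(T).ravel(), Z.ravel()]
        qsm = rq.reconstruct(rq.PointCloud(pts), seed=0)
        total = sum(c.length for c in qsm.cylinders)
        assert total == pytest.approx(10.0, rel=0.05)
        assert 1 <= len(qsm.cylinders) <= 16

    def test_quarter_torus_follows_curvature(self):
        """Curved tube: smooth chain, summed length near the arc length."""
        R, r = 8.0, 0.4
        phi = np.linspace(0, np.pi / 2, 160)
        theta = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        P, T = np.meshgrid(phi, theta)
        x = (R + r * np.cos(T)) * np.cos(P)
        z = -(R + r * np.cos(T)) * np.sin(P)
        y = r * np.sin(T)
        cloud = rq.PointCloud(np.c_[x.ravel() - R, y.ravel(), z.ravel()])
        qsm = rq.reconstruct(cloud, seed=0)
        arc = np.pi / 2 * R
        total = sum(c.length for c in qsm.cylinders)
        assert total == pytest.approx(arc, rel=0.08)
        chain = [c for c in qsm.cylinders if not c.gap_fill]
        for a, b in zip(chain, chain[1:]):
            angle = np.degrees(np.arccos(np.clip(a.axis @ b.axis, -1, 1)))
            assert angle < 30.0


class TestReconstruct:
    def test_tree_topology_single_root(self, root_qsm):
        roots = [c for c in root_qsm.cylinders if c.parent is None]
        assert len(roots) == 1
        for i, c in enumerate(root_qsm.cylinders):
            if c.parent is not None:
                assert 0 <= c.parent < len(root_qsm.cylinders)
                assert c.parent != i

    def test_branch_count_matches_generator(self, root_qsm, root_mesh):
        _, truth = root_mesh
        order1_segments = {c.segment_id for c in root_qsm.cylinders
                           if c.order == 1}
        assert len(order1_segments) == truth["n_ramifications"]

    def test_determinism_same_seed(self, root_cloud, root_qsm):
        again = rq.reconstruct(root_cloud, seed=10)
        assert len(again.cylinders) == len(root_qsm.cylinders)
        for a, b in zip(again.cylinders, root_qsm.cylinders):
            np.testing.assert_array_equal(a.start, b.start)
            assert a.radius == b.radius and a.length == b.length

    def test_pure_noise_rejected(self):
        rng = np.random.default_rng(0)
        cloud = rq.PointCloud(rng.uniform(-10, 10, size=(300, 3)))
        with pytest.raises((EmptyModelError, ValueError)):
            rq.reconstruct(cloud, seed=0, patch_diameter=0.05)

    def test_axes_unit_norm(self, root_qsm):
        for c in root_qsm.cylinders:
            assert np.linalg.norm(c.axis) == pytest.approx(1.0, abs=1e-9)

    def test_csv_roundtrip(self, root_qsm, tmp_path):
        path = tmp_path / "qsm.csv"
        root_qsm.to_csv(path)
        back = QSM.from_csv(path, sf=root_qsm.sf)
        assert len(back.cylinders) == len(root_qsm.cylinders)
        np.testing.assert_allclose(
            [c.radius for c in back.cylinders],
            [c.radius for c in root_qsm.cylinders])
        assert [c.parent for c in back.cylinders] == \
            [c.parent for c in root_qsm.cylinders]
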
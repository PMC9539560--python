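import numpy as np
import pytest

import rootqsm as rq
from rootqsm.cylinder_model import Cylinder, QSM
from rootqsm.traits import (
    cylinder_distributions,
    order_traits,
    percent_ratios,
    root_ball,
    spread,
    taproot_taper,
    total_traits,
)


def single_cylinder_qsm(r=0.5, l=10.0, sf=1.0):
    c = Cylinder(start=[0, 0, 0], axis=[0, 0, -1], length=l * sf, radius=r * sf,
                 segment_id=0)
    return QSM([c], sf=sf, seed=0, base_point=np.zeros(3))


class TestTotalTraits:
    def test_single_cylinder_closed_form(self):
        tt = total_traits(single_cylinder_qsm())
        assert tt.volume == pytest.approx(np.pi * 0.25 * 10, rel=1e-9)
        assert tt.area == pytest.approx(2 * np.pi * 0.5 * 10, rel=1e-9)
        assert tt.length == pytest.approx(10.0)
        assert tt.rooting_depth == pytest.approx(10.0)
        assert tt.n_ramifications == 0

    def test_ratio_identity(self, root_qsm):
        """%V/A x %A/L / 100 == %V/L exactly on unrounded totals."""
        tt = total_traits(root_qsm)
        assert tt.pct_volume_area * tt.pct_area_length / 100.0 == \
            pytest.approx(tt.pct_volume_length, rel=1e-12)

    def test_printed_ratio_examples(self):
        r = percent_ratios(48.34, 173.5, 138.6)
        assert r["pct_volume_area"] == pytest.approx(27.86, abs=0.02)
        r2 = percent_ratios(4.60, 92.71, 247.8)
        assert r2["pct_volume_length"] == pytest.approx(1.86, abs=0.02)

    def test_unit_scaling_rules(self, root_mesh):
        """A mesh in halved units (coordinates x2) with SF halved yields the
        same scaled cloud, so traits follow the exact unit rules: lengths
        x2, areas x4, volumes x8 in the new unit."""
        mesh, _ = root_mesh
        c1 = rq.mesh_to_pointcloud(mesh, 0.5)
        mesh2 = rq.TriMesh(mesh.vertices * 2.0, mesh.faces)
        c2 = rq.mesh_to_pointcloud(mesh2, 0.25)
        np.testing.assert_allclose(c1.points, c2.points, atol=1e-12)
        t1 = total_traits(rq.reconstruct(c1, seed=3))
        t2 = total_traits(rq.reconstruct(c2, seed=3))
        assert t2.length == pytest.approx(2.0 * t1.length, rel=1e-9)
        assert t2.area == pytest.approx(4.0 * t1.area, rel=1e-9)
        assert t2.volume == pytest.approx(8.0 * t1.volume, rel=1e-9)
        assert t2.n_ramifications == t1.n_ramifications


class TestRootBall:
    def test_square_projected_area(self):
        pts = np.array([[0, 0, -1], [1, 0, -1], [1, 1, -1], [0, 1, -1.0]])
        ball = root_ball(pts)
        assert ball["ball_area_convexhull"] == pytest.approx(1.0)
        assert ball["ball_volume_convexhull"] == 0.0  # coplanar -> warned 0

    def test_unit_tetrahedron_volume(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        ball = root_ball(pts)
        assert ball["ball_volume_convexhull"] == pytest.approx(1 / 6)

    def test_disc_hull_area_converges(self):
        rng = np.random.default_rng(0)
        n = 4000
        r = 5 * np.sqrt(rng.uniform(size=n))
        th = rng.uniform(0, 2 * np.pi, n)
        pts = np.c_[r * np.cos(th), r * np.sin(th), rng.normal(0, 0.1, n)]
        ball = root_ball(pts)
        assert ball["ball_area_convexhull"] <= 25 * np.pi
        assert ball["ball_area_convexhull"] > 0.95 * 25 * np.pi

    def test_alpha_shape_below_hull(self, root_qsm):
        tt = total_traits(root_qsm)
        assert tt.ball_area_alphashape <= tt.ball_area_convexhull + 1e-9
        assert tt.ball_volume_alphashape <= tt.ball_volume_convexhull + 1e-9
        assert tt.ball_diam_max >= tt.ball_diam_avg


class TestTaper:
    def test_two_cylinder_taper(self):
        c1 = Cylinder(start=[0, 0, 0], axis=[0, 0, -1], length=5, radius=1,
                      segment_id=0)
        c2 = Cylinder(start=[0, 0, -5], axis=[0, 0, -1], length=5, radius=0.5,
                      parent=0, segment_id=0)
        qsm = QSM([c1, c2], sf=1.0, seed=0, base_point=np.zeros(3))
        tp = taproot_taper(qsm)
        np.testing.assert_allclose(tp.distance_along_taproot, [2.5, 7.5])
        np.testing.assert_allclose(tp.diameter, [2.0, 1.0])

    def test_tapering_root_monotone(self, root_qsm):
        tp = taproot_taper(root_qsm)
        assert np.all(np.diff(tp.distance_along_taproot) > 0)
        # generator tapers 0.8 -> 0.3 cm; fitted diameters follow the trend
        slope = np.polyfit(tp.distance_along_taproot, tp.diameter, 1)[0]
        assert slope < 0


class TestSpread:
    def test_shape_and_vertical_taproot_zero(self):
        qsm = single_cylinder_qsm()
        sp = spread(qsm)
        assert sp.values.shape == (10, 18)
        np.testing.assert_allclose(sp.values, 0.0, atol=1e-9)

    def test_single_lateral_single_cell(self):
        tap = Cylinder(start=[0, 0, 0], axis=[0, 0, -1], length=10, radius=0.3,
                       segment_id=0)
        # lateral at 45 deg azimuth reaching 4 cm, depth about 3 cm
        lat = Cylinder(start=[0, 0, -3], axis=[np.sqrt(0.5), np.sqrt(0.5), 0],
                       length=4.0, radius=0.1, parent=0, segment_id=1, order=1)
        qsm = QSM([tap, lat], sf=1.0, seed=0, base_point=np.zeros(3))
        sp = spread(qsm)
        nz = np.argwhere(sp.values > 0)
        assert (nz[:, 1] == 2).all()  # 45 deg is in the [40, 60) sector
        assert sp.values.max() == pytest.approx(4.0, rel=1e-6)

    def test_radial_laterals_fill_sectors(self, root_qsm):
        sp = spread(root_qsm)
        assert (sp.values >= 0).all()
        assert sp.values.max() > 1.0


class TestDistributions:
    def test_half_open_boundary_rule(self):
        # diameters 0.05 mm and 0.10 mm (cm/1000 scale): classes 0 and 1
        c1 = Cylinder(start=[0, 0, 0], axis=[0, 0, -1], length=1,
                      radius=0.0025, segment_id=0)
        c2 = Cylinder(start=[0, 0, -1], axis=[0, 0, -1], length=1,
                      radius=0.005, parent=0, segment_id=0)
        qsm = QSM([c1, c2], sf=1.0, seed=0, base_point=np.zeros(3))
        d = cylinder_distributions(qsm, "main")["diameter"]
        assert d.count[0] == 1 and d.count[1] == 1

    def test_conservation_all_classifiers(self, root_qsm):
        tt = total_traits(root_qsm)
        for which, orders in (("main", 0), ("lateral", 1)):
            dists = cylinder_distributions(qsm=root_qsm, which=which)
            sel = [c for c in root_qsm.cylinders
                   if (c.order == 0) == (which == "main")]
            vol = sum(c.volume for c in sel) / root_qsm.sf**3
            for tab in dists.values():
                assert tab.volume.sum() == pytest.approx(vol, rel=1e-9)
                assert np.all(np.diff(tab.class_edges) > 0)
        main_v = cylinder_distributions(root_qsm, "main")["depth"].volume.sum()
        lat_v = cylinder_distributions(root_qsm, "lateral")["depth"].volume.sum()
        assert main_v + lat_v == pytest.approx(tt.volume, rel=1e-9)

    def test_unknown_classifier_rejected(self, root_qsm):
        with pytest.raises(ValueError, match="main.*lateral"):
            cylinder_distributions(root_qsm, "stems")


class TestOrderTraits:
    def test_y_root_rows(self, root_qsm):
        table = order_traits(root_qsm)
        assert list(table["order"]) == [0, 1]
        assert table.loc[1, "count"] == 6

    def test_sums_to_totals(self, root_qsm):
        tt = total_traits(root_qsm)
        table = order_traits(root_qsm)
        assert table["volume"].sum() == pytest.approx(tt.volume, rel=1e-9)
        assert table["length"].sum() == pytest.approx(tt.length, rel=1e-9)
        assert table["area"].sum() == pytest.approx(tt.area, rel=1e-9)
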
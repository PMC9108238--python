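"""Centerline extraction and morphometric operations against closed forms."""

import numpy as np
import pytest
import trimesh

from aortamorph.centerline_morph import (Centerline, MeshIntegrityError,
                                         curvature_profile, extract_centerline,
                                         lumen_volume, morphometry_table,
                                         oversizing, section_metrics,
                                         slice_sections, tortuosity)
from aortamorph.mesh_io import SurfaceMesh
from aortamorph.registration import RigidTransform, apply_transform


def polygon_section(points2d, s=0.0):
    """CrossSection-like fixture from a planar polygon in the z=s plane."""
    from aortamorph.centerline_morph import CrossSection
    pts3 = np.column_stack([points2d, np.full(len(points2d), s)])
    return CrossSection(s_mm=s, origin=np.array([0.0, 0.0, s]),
                        normal=np.array([0.0, 0.0, 1.0]),
                        contours=[(pts3, "primary")])


class TestTortuosity:
    def test_straight_is_zero(self):
        pts = np.column_stack([np.zeros(20), np.zeros(20), np.linspace(0, 50, 20)])
        assert tortuosity(Centerline(pts)) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("arc_deg,expected", [
        (180.0, 1.0 - 2.0 / np.pi),                                # semicircle
        (90.0, 1.0 - np.sqrt(2.0) / (np.pi / 2.0)),                # quarter
    ])
    def test_circular_arcs_closed_form(self, arc_deg, expected):
        theta = np.linspace(0.0, np.deg2rad(arc_deg), 2000)
        R = 50.0
        pts = np.column_stack([R * np.cos(theta), R * np.sin(theta),
                               np.zeros_like(theta)])
        assert tortuosity(Centerline(pts)) == pytest.approx(expected, abs=1e-4)

    def test_invariant_under_rigid_motion_and_scaling(self, rng):
        theta = np.linspace(0, 2.0, 300)
        pts = np.column_stack([np.cos(theta), np.sin(theta), theta])
        base = tortuosity(Centerline(pts))
        t = RigidTransform.from_axis_angle(rng.normal(size=3), 0.7, [3, -1, 9])
        assert tortuosity(Centerline(t.apply(pts))) == pytest.approx(base, rel=1e-12)
        assert tortuosity(Centerline(7.3 * pts)) == pytest.approx(base, rel=1e-12)

    def test_bounds(self):
        theta = np.linspace(0, 4 * np.pi, 500)
        coil = np.column_stack([np.cos(theta), np.sin(theta), 0.01 * theta])
        v = tortuosity(Centerline(coil))
        assert 0.0 <= v < 1.0


class TestCurvature:
    def test_straight_line_zero(self):
        pts = np.column_stack([np.linspace(0, 80, 100), np.zeros(100), np.zeros(100)])
        assert np.allclose(curvature_profile(Centerline(pts)), 0.0)

    def test_helix_closed_form(self):
        a, b = 20.0, 5.0
        t = np.linspace(0, 6 * np.pi, 400)
        pts = np.column_stack([a * np.cos(t), a * np.sin(t), b * t])
        kappa = curvature_profile(Centerline(pts))
        assert kappa == pytest.approx(a / (a * a + b * b), rel=0.02)


class TestSliceSections:
    def test_cylinder_station_count_and_area(self, cylinder):
        _, mesh, cl = cylinder
        secs = slice_sections(mesh, cl, interval_mm=2.0)
        assert len(secs) == 51  # endpoints inclusive
        for cs in secs[::10]:
            m = section_metrics(cs).metrics
            assert m["area_mm2"] == pytest.approx(np.pi * 100.0, rel=0.01)
            assert len(cs.contours) == 1

    def test_dissected_combined_mesh_two_contours(self, dissected):
        _, tl, fl, cl, _ = dissected
        combined = SurfaceMesh(
            np.vstack([tl.vertices, fl.vertices]),
            np.vstack([tl.faces, fl.faces + tl.n_vertices]))
        secs = slice_sections(combined, cl, interval_mm=25.0)
        mid = [s for s in secs if 10 < s.s_mm < 90]
        for cs in mid:
            assert len(cs.contours) == 2
            labels = sorted(label for _, label in cs.contours)
            assert labels == ["primary", "secondary"]


class TestSectionMetrics:
    def test_circle_64gon(self):
        phi = 2 * np.pi * np.arange(64) / 64
        m = section_metrics(polygon_section(
            10.0 * np.column_stack([np.cos(phi), np.sin(phi)]))).metrics
        assert m["area_mm2"] == pytest.approx(np.pi * 100.0, rel=0.01)
        assert m["circumference_mm"] == pytest.approx(2 * np.pi * 10.0, rel=0.01)
        assert m["equivalent_diameter_mm"] == pytest.approx(20.0, rel=0.01)
        assert m["aspect_ratio"] == pytest.approx(1.0, rel=0.01)

    def test_ellipse_axes(self):
        phi = 2 * np.pi * np.arange(256) / 256
        m = section_metrics(polygon_section(
            np.column_stack([20.0 * np.cos(phi), 10.0 * np.sin(phi)]))).metrics
        assert m["transverse_diameter_mm"] == pytest.approx(40.0, rel=0.02)
        assert m["longitudinal_diameter_mm"] == pytest.approx(20.0, rel=0.02)
        assert m["aspect_ratio"] == pytest.approx(2.0, rel=0.02)

    def test_square_closed_form(self):
        sq = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]])
        m = section_metrics(polygon_section(sq)).metrics
        assert m["transverse_diameter_mm"] == pytest.approx(np.sqrt(200.0), rel=1e-6)
        assert m["equivalent_diameter_mm"] == pytest.approx(
            2.0 * np.sqrt(100.0 / np.pi), rel=1e-6)

    def test_equivalent_le_transverse_on_phantom_slices(self, cylinder):
        _, mesh, cl = cylinder
        for cs in slice_sections(mesh, cl, interval_mm=10.0):
            m = section_metrics(cs).metrics
            assert m["equivalent_diameter_mm"] <= m["transverse_diameter_mm"] + 1e-9


class TestLumenVolume:
    def test_icosphere_volume(self):
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        mesh = SurfaceMesh(sphere.vertices, sphere.faces)
        assert lumen_volume(mesh) == pytest.approx(4.0 / 3.0 * np.pi, rel=0.005)

    def test_rigid_invariance(self, small_cylinder, rng):
        _, mesh, _ = small_cylinder
        t = RigidTransform.from_axis_angle(rng.normal(size=3), 0.5, [10, 0, -4])
        assert lumen_volume(apply_transform(mesh, t)) == pytest.approx(
            lumen_volume(mesh), rel=1e-9)

    def test_open_mesh_rejected(self, small_cylinder):
        _, mesh, _ = small_cylinder
        open_mesh = SurfaceMesh(mesh.vertices, mesh.faces[:-10])
        with pytest.raises(MeshIntegrityError):
            lumen_volume(open_mesh)


class TestExtractCenterline:
    def test_straight_cylinder_axis_recovered(self, cylinder):
        _, mesh, _ = cylinder
        cl = extract_centerline(mesh, [0.3, -0.4, 2.0], [0.1, 0.2, 98.0])
        assert np.max(np.linalg.norm(cl.points[:, :2], axis=1)) < 0.2

    def test_torus_tortuosity_recovered(self, semicircle_torus):
        _, mesh, _ = semicircle_torus
        p0 = np.array([50.0, 0.5, 0.0])
        p1 = np.array([-50.0, 0.5, 0.0])
        cl = extract_centerline(mesh, p0, p1)
        assert tortuosity(cl) == pytest.approx(1.0 - 2.0 / np.pi, abs=0.005)

    def test_equivariance_under_rigid_motion(self, cylinder):
        _, mesh, _ = cylinder
        t = RigidTransform.from_axis_angle([0.2, 1.0, 0.1], 0.4, [8.0, -2.0, 3.0])
        moved = apply_transform(mesh, t)
        cl = extract_centerline(moved,
                                t.apply(np.array([[0.0, 0.0, 2.0]]))[0],
                                t.apply(np.array([[0.0, 0.0, 98.0]]))[0])
        # distance of every extracted point to the transformed analytic axis line
        origin = t.apply(np.zeros((1, 3)))[0]
        direction = t.rotation @ np.array([0.0, 0.0, 1.0])
        rel = cl.points - origin
        d = np.linalg.norm(rel - np.outer(rel @ direction, direction), axis=1)
        assert np.max(d) < 0.2

    def test_outside_seed_rejected(self, cylinder):
        _, mesh, _ = cylinder
        with pytest.raises(ValueError, match="outside"):
            extract_centerline(mesh, [30.0, 0.0, 50.0], [0.0, 0.0, 98.0])


class TestOversizing:
    def test_basic_arithmetic(self):
        assert oversizing(30, 30, 30, 30) == (0.0, 0.0)
        prox, dist = oversizing(33.0, 30.0, 30.0, 30.0)
        assert prox == pytest.approx(10.0)
        assert dist == pytest.approx(0.0)

    def test_inversion_reproduces_reported_percentages(self):
        # 34-26 mm tapered stent; vessel diameters back-solved from the ratios
        prox, dist = oversizing(34.0, 26.0, 34.0 / 1.058, 26.0 / 1.153)
        assert prox == pytest.approx(5.8, abs=0.01)
        assert dist == pytest.approx(15.3, abs=0.01)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            oversizing(30.0, 30.0, 0.0, 30.0)


class TestMorphometryTable:
    def test_cylinder_summary(self, cylinder, tmp_path):
        _, mesh, cl = cylinder
        table = morphometry_table(mesh, cl, interval_mm=5.0, region="MAGR")
        assert table.scalars["tortuosity"] == pytest.approx(0.0, abs=1e-9)
        assert table.scalars["volume_mm3"] == pytest.approx(np.pi * 1e4, rel=0.01)
        assert len(table.stations) == 21
        table.to_csv(tmp_path / "t.csv")
        table.to_json(tmp_path / "t.json")
        assert (tmp_path / "t.csv").exists() and (tmp_path / "t.json").exists()

    def test_slice_metrics_rigid_invariant(self, small_cylinder, rng):
        _, mesh, cl = small_cylinder
        t = RigidTransform.from_axis_angle(rng.normal(size=3), 0.6, [4, 4, -7])
        a = morphometry_table(mesh, cl, interval_mm=10.0).stations
        b = morphometry_table(apply_transform(mesh, t),
                              Centerline(t.apply(cl.points)),
                              interval_mm=10.0).stations
        for col in ("area_mm2", "circumference_mm", "equivalent_diameter_mm"):
            np.testing.assert_allclose(a[col], b[col], rtol=1e-6)
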
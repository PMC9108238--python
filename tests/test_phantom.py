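"""Phantom generators against their analytic ground truth."""

import numpy as np
import pytest

from aortamorph.centerline_morph import (curvature_profile, lumen_volume,
                                         slice_sections, section_metrics,
                                         tortuosity)
from aortamorph.mesh_io import FieldTimeSeries
from aortamorph.phantom import (FieldSpec, PhantomSpec, deform_phantom,
                                make_dissected_phantom, make_field_series,
                                make_tube)
from aortamorph.registration import RigidTransform


class TestMakeTube:
    def test_straight_tube_is_watertight_with_analytic_volume(self, cylinder):
        spec, mesh, cl = cylinder
        assert mesh.is_watertight
        vol = lumen_volume(mesh)
        assert vol == pytest.approx(np.pi * 100.0 * 100.0, rel=0.01)

    def test_straight_tube_centerline_is_straight(self, cylinder):
        _, _, cl = cylinder
        assert tortuosity(cl) == pytest.approx(0.0, abs=1e-12)
        assert cl.length_mm == pytest.approx(100.0, rel=1e-3)

    def test_torus_curvature_is_inverse_bend_radius(self, semicircle_torus):
        _, _, cl = semicircle_torus
        kappa = curvature_profile(cl)
        assert kappa == pytest.approx(1.0 / 50.0, rel=0.01)

    def test_torus_arclength_matches_analytic(self, semicircle_torus):
        _, _, cl = semicircle_torus
        assert cl.length_mm == pytest.approx(np.pi * 50.0, rel=1e-3)

    def test_centerline_sampling_spacing(self, arch):
        _, _, cl = arch
        assert np.max(np.diff(cl.arclength_mm)) <= 0.5 + 1e-9

    def test_outward_orientation(self, cylinder, semicircle_torus, arch):
        for _, mesh, _ in (cylinder, semicircle_torus, arch):
            assert mesh.as_trimesh().volume > 0

    @pytest.mark.parametrize("bad", [
        dict(kind="straight_tube", radius_mm=-1.0),
        dict(kind="torus_segment", radius_mm=60.0, bend_radius_mm=50.0),
        dict(kind="straight_tube", radius_mm=5.0, length_mm=-2.0),
    ])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            PhantomSpec(**bad)

    def test_make_tube_rejects_dissected_kind(self):
        spec = PhantomSpec("dissected_segment", radius_mm=10.0)
        with pytest.raises(ValueError):
            make_tube(spec)


class TestDissectedPhantom:
    def test_lumens_watertight_sharing_septum(self, dissected):
        _, tl, fl, _, _ = dissected
        assert tl.is_watertight and fl.is_watertight

    def test_area_fractions_match_septum_fraction(self, dissected):
        spec, tl, fl, cl, _ = dissected
        total = np.pi * spec.radius_mm ** 2
        secs = [section_metrics(s) for s in slice_sections(tl, cl, interval_mm=25.0)]
        for s in secs:
            assert s.metrics["area_mm2"] == pytest.approx(0.3 * total, rel=0.02)

    def test_symmetric_septum_halves_areas(self):
        spec = PhantomSpec("dissected_segment", radius_mm=10.0, length_mm=40.0,
                           septum_fraction=0.5)
        tl, fl, cl, _ = make_dissected_phantom(spec)
        half = 0.5 * np.pi * 100.0
        for mesh in (tl, fl):
            s = section_metrics(slice_sections(mesh, cl, interval_mm=20.0)[1])
            assert s.metrics["area_mm2"] == pytest.approx(half, rel=0.02)

    def test_volume_additivity(self, dissected):
        spec, tl, fl, _, _ = dissected
        total = np.pi * spec.radius_mm ** 2 * spec.length_mm
        assert lumen_volume(tl) + lumen_volume(fl) == pytest.approx(total, rel=0.01)

    def test_tears_sorted_ascending(self, dissected):
        _, _, _, _, tears = dissected
        s = [t["s_mm"] for t in tears]
        assert s == sorted(s) == [20.0, 80.0]

    def test_tear_outside_segment_rejected(self):
        spec = PhantomSpec("dissected_segment", radius_mm=10.0, length_mm=50.0,
                           tear_arclengths_mm=[60.0])
        with pytest.raises(ValueError, match="tear"):
            make_dissected_phantom(spec)


class TestFieldSeries:
    def test_uniform_steady_field(self, small_cylinder):
        _, mesh, _ = small_cylinder
        s = make_field_series(mesh, FieldSpec("uniform", base_value=2.0),
                              kind="vector3")
        assert s.values.shape == (50, mesh.n_vertices, 3)
        assert np.allclose(np.linalg.norm(s.values, axis=2), 2.0)

    def test_axial_linear_profile(self, small_cylinder):
        _, mesh, _ = small_cylinder
        s = make_field_series(
            mesh, FieldSpec("axial_linear", base_value=100.0, axial_slope=-10.0))
        expected = 100.0 - 10.0 * mesh.vertices[:, 2]
        assert np.allclose(s.values[0], expected)
        assert np.allclose(s.values[-1], expected)  # steady

    def test_pulsatile_cosine_closed_form(self, small_cylinder):
        _, mesh, _ = small_cylinder
        spec = FieldSpec("pulsatile_cosine", base_value=3.0, amplitude=1.5,
                         period_s=0.8, phase_rad=0.3, n_timesteps=50)
        s = make_field_series(mesh, spec)
        t = s.times_s
        expected = 3.0 + 1.5 * np.cos(2 * np.pi * t / 0.8 + 0.3)
        assert np.allclose(s.values[:, 0], expected)
        assert len(t) == 50 and t[0] == 0.0 and t[-1] < 0.8

    def test_determinism(self, small_cylinder):
        _, mesh, _ = small_cylinder
        spec = FieldSpec("pulsatile_cosine", base_value=1.0, amplitude=0.5)
        a = make_field_series(mesh, spec, kind="vector3")
        b = make_field_series(mesh, spec, kind="vector3")
        assert np.array_equal(a.values, b.values)


class TestDeformPhantom:
    def test_identity_no_growth_is_noop(self, small_cylinder):
        _, mesh, _ = small_cylinder
        out = deform_phantom(mesh, RigidTransform.identity(), 0.0)
        assert np.allclose(out.vertices, mesh.vertices)

    def test_growth_increases_slice_diameter(self, small_cylinder):
        _, mesh, cl = small_cylinder
        grown = deform_phantom(mesh, RigidTransform.identity(), 0.5)
        secs = [section_metrics(s) for s in slice_sections(grown, cl, interval_mm=10.0)]
        interior = [s for s in secs if 5.0 < s.s_mm < 55.0]
        for s in interior:
            assert s.metrics["equivalent_diameter_mm"] == pytest.approx(21.0, rel=0.01)

    def test_collapse_rejected(self, small_cylinder):
        _, mesh, _ = small_cylinder
        with pytest.raises(ValueError, match="collapse"):
            deform_phantom(mesh, RigidTransform.identity(), -10.0)

    def test_rigid_part_preserves_volume(self, small_cylinder):
        _, mesh, _ = small_cylinder
        t = RigidTransform.from_axis_angle([0, 1, 0], 0.3, [5.0, -3.0, 2.0])
        out = deform_phantom(mesh, t, 0.0)
        assert lumen_volume(out) == pytest.approx(lumen_volume(mesh), rel=1e-9)
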
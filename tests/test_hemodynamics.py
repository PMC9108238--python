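"""Wall-shear indicators, LPD/FBP, energy loss, flow distribution."""

import numpy as np
import pytest

from aortamorph.hemodynamics import (FlowBoundary, IndicatorMaps, LPDProfile,
                                     circumferential_average, energy_loss,
                                     first_balance_position, flow_distribution,
                                     lpd_profile, osi, rrt,
                                     slice_average_pressure, tawss)
from aortamorph.centerline_morph import slice_sections
from aortamorph.mesh_io import FieldTimeSeries, Waveform
from aortamorph.phantom import FieldSpec, make_field_series


def vector_series(values_t, n_vertices=5, period=1.0, direction=(1.0, 0.0, 0.0)):
    """WSS series with the same scalar trace at every vertex along a fixed axis."""
    values_t = np.asarray(values_t, dtype=float)
    nt = len(values_t)
    t = np.arange(nt) * period / nt
    v = values_t[:, None, None] * np.asarray(direction)[None, None, :]
    v = np.repeat(v, n_vertices, axis=1)
    return FieldTimeSeries("wss", "vector3", v, t, period, "Pa")


class TestIndicators:
    def test_steady_limits(self):
        s = vector_series(np.full(50, 2.0))
        assert np.allclose(tawss(s), 2.0)
        assert np.allclose(osi(s), 0.0)
        maps = IndicatorMaps.from_wss(s)
        assert np.allclose(maps.rrt_pa_inv, 0.5)

    def test_rectified_cosine_tawss(self):
        t = np.arange(200) / 200
        s = vector_series(np.cos(2 * np.pi * t))
        assert np.allclose(tawss(s), 2.0 / np.pi, rtol=1e-3)

    def test_zero_mean_reversal_gives_half(self):
        t = np.arange(50) / 50
        s = vector_series(np.cos(2 * np.pi * t))
        assert np.allclose(osi(s), 0.5, atol=1e-12)
        maps = IndicatorMaps.from_wss(s)
        assert np.all(np.isinf(maps.rrt_pa_inv))

    def test_offset_cosine_against_quadrature(self):
        t_dense = np.linspace(0, 1, 200001)
        trace = 1.0 + np.cos(2 * np.pi * t_dense)
        expected_osi = 0.5 * (1.0 - 1.0 / np.trapezoid(np.abs(trace), t_dense))
        t = np.arange(500) / 500
        s = vector_series(1.0 + np.cos(2 * np.pi * t))
        assert np.allclose(osi(s), expected_osi, atol=1e-4)

    def test_tawss_homogeneity(self, rng):
        s = vector_series(rng.normal(size=64))
        assert np.allclose(tawss(s.scaled(2.0)), 2.0 * tawss(s), rtol=1e-12)

    def test_osi_bounds_random_series(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            nt, nv = 20, 4
            t = np.arange(nt) / nt
            v = rng.normal(size=(nt, nv, 3))
            s = FieldTimeSeries("wss", "vector3", v, t, 1.0)
            o = osi(s)
            assert np.all(o >= 0.0) and np.all(o <= 0.5)

    def test_rrt_identity(self, rng):
        v = rng.normal(size=(30, 8, 3)) + 1.0
        s = FieldTimeSeries("wss", "vector3", v, np.arange(30) / 30, 1.0)
        maps = IndicatorMaps.from_wss(s)
        finite = np.isfinite(maps.rrt_pa_inv)
        ident = maps.rrt_pa_inv[finite] * (1 - 2 * maps.osi[finite]) * maps.tawss_pa[finite]
        assert np.allclose(ident, 1.0, atol=1e-9)

    def test_rrt_equals_inverse_mean_vector(self, rng):
        v = rng.normal(size=(25, 6, 3)) + 0.5
        t = np.arange(25) / 25
        s = FieldTimeSeries("wss", "vector3", v, t, 1.0)
        t_ext = np.concatenate([t, [1.0]])
        v_ext = np.concatenate([v, v[:1]], axis=0)
        mean_vec = np.trapezoid(v_ext, t_ext, axis=0)
        maps = IndicatorMaps.from_wss(s)
        assert np.allclose(maps.rrt_pa_inv, 1.0 / np.linalg.norm(mean_vec, axis=1),
                           rtol=1e-9)

    def test_scalar_series_rejected(self):
        s = FieldTimeSeries("p", "scalar", np.ones((5, 3)), np.arange(5) / 5, 1.0)
        with pytest.raises(TypeError):
            tawss(s)


class TestSliceAveragePressure:
    def test_uniform_steady(self, small_cylinder):
        _, mesh, cl = small_cylinder
        p = make_field_series(mesh, FieldSpec("uniform", base_value=100.0))
        secs = slice_sections(mesh, cl, interval_mm=10.0)
        s, pav = slice_average_pressure(mesh, p, secs)
        assert np.allclose(pav, 100.0)

    def test_axial_linear_profile(self, small_cylinder):
        _, mesh, cl = small_cylinder
        p = make_field_series(
            mesh, FieldSpec("axial_linear", base_value=100.0, axial_slope=-10.0))
        secs = slice_sections(mesh, cl, interval_mm=4.0)
        s, pav = slice_average_pressure(mesh, p, secs)
        expected = 100.0 - 10.0 * s
        interior = (s > 0) & (s < 60)
        assert np.allclose(pav[interior], expected[interior], rtol=0.01, atol=0.5)

    def test_pulsatile_time_average(self, small_cylinder):
        _, mesh, cl = small_cylinder
        p = make_field_series(
            mesh, FieldSpec("pulsatile_cosine", base_value=100.0, amplitude=20.0))
        secs = slice_sections(mesh, cl, interval_mm=20.0)
        _, pav = slice_average_pressure(mesh, p, secs)
        assert np.allclose(pav, 100.0, atol=1e-9)


class TestLPDAndFBP:
    def test_identical_lumen_pressures_zero(self):
        s = np.arange(10.0)
        prof = lpd_profile(np.full(10, 50.0), np.full(10, 50.0), s)
        assert np.allclose(prof.lpd_pa, 0.0)

    def test_linear_profiles(self):
        s = np.arange(10.0)
        prof = lpd_profile(100.0 - 10.0 * s, 80.0 - 5.0 * s, s)
        assert np.allclose(prof.lpd_pa, 20.0 - 5.0 * s)
        assert first_balance_position(prof) == pytest.approx(4.0)

    def test_antisymmetry(self):
        s = np.arange(8.0)
        a = lpd_profile(100.0 - 3.0 * s, np.full(8, 90.0), s)
        b = lpd_profile(np.full(8, 90.0), 100.0 - 3.0 * s, s)
        assert np.allclose(a.lpd_pa, -b.lpd_pa)

    def test_interpolated_crossing(self):
        s = np.array([10.0, 11.0, 12.0, 13.0, 14.0])
        lpd = np.array([4.0, 3.0, 2.0, -3.0, -4.0])
        prof = LPDProfile(s, lpd, np.zeros(5))
        assert first_balance_position(prof) == pytest.approx(12.4)

    def test_no_crossing_returns_sentinel(self):
        s = np.arange(5.0)
        prof = lpd_profile(np.full(5, 120.0), np.full(5, 100.0), s)
        assert first_balance_position(prof) is None

    def test_exact_zero_station_is_fbp(self):
        s = np.arange(5.0)
        prof = LPDProfile(s, np.array([5.0, 2.0, 0.0, 2.0, 5.0]), np.zeros(5))
        assert first_balance_position(prof) == pytest.approx(2.0)

    def test_station_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lpd_profile(np.ones(4), np.ones(5), np.arange(5.0))


class TestEnergyLoss:
    @staticmethod
    def steady(label, kind, u, p, area, nt=50):
        t = np.arange(nt) / nt
        return FlowBoundary(label, kind, t, np.full(nt, u), np.full(nt, p), area)

    def test_steady_pressure_drop_closed_form(self):
        # equal areas and velocities: kinetic fluxes cancel, EL = dP * Q
        b_in = self.steady("in", "inlet", 1.0, 200.0, 1e-4)
        b_out = self.steady("out", "outlet", 1.0, 100.0, 1e-4)
        res = energy_loss([b_in, b_out], period_s=1.0)
        assert res.el_w == pytest.approx(0.01, rel=1e-12)

    def test_identical_states_zero(self):
        b_in = self.steady("in", "inlet", 0.7, 150.0, 2e-4)
        b_out = self.steady("out", "outlet", 0.7, 150.0, 2e-4)
        assert energy_loss([b_in, b_out], period_s=1.0).el_w == pytest.approx(0.0)

    def test_pulsatile_matches_quadrature(self):
        nt = 50
        t = np.arange(nt) / nt
        q0, dp, area = 1e-4, 100.0, 1e-4
        u = q0 * (1.0 + np.cos(2 * np.pi * t)) / area
        b_in = FlowBoundary("in", "inlet", t, u, np.full(nt, 100.0 + dp), area)
        b_out = FlowBoundary("out", "outlet", t, u, np.full(nt, 100.0), area)
        res = energy_loss([b_in, b_out], period_s=1.0)
        # kinetic terms cancel; <Q> = q0, so EL = dP * q0
        assert res.el_w == pytest.approx(dp * q0, rel=1e-3)
        # independent high-resolution quadrature of the same integrand
        td = np.linspace(0, 1, 200001)
        ud = q0 * (1 + np.cos(2 * np.pi * td)) / area
        el_dense = np.trapezoid((100.0 + dp - 100.0) * ud * area, td)
        assert res.el_w == pytest.approx(el_dense, rel=1e-3)

    def test_pressure_offset_invariance_with_mass_conservation(self):
        b_in = self.steady("in", "inlet", 1.0, 500.0, 1e-4)
        o1 = self.steady("o1", "outlet", 0.5, 300.0, 1e-4)
        o2 = self.steady("o2", "outlet", 0.5, 100.0, 1e-4)
        base = energy_loss([b_in, o1, o2], period_s=1.0).el_w
        shift = [self.steady(b.label, b.kind, b.velocity_m_s[0],
                             b.pressure_pa[0] + 1e4, b.area_m2)
                 for b in (b_in, o1, o2)]
        assert energy_loss(shift, period_s=1.0).el_w == pytest.approx(base, rel=1e-9)

    def test_missing_inlet_rejected(self):
        with pytest.raises(ValueError, match="inlet"):
            energy_loss([self.steady("o", "outlet", 1.0, 0.0, 1e-4)], period_s=1.0)

    def test_negative_loss_flagged(self):
        b_in = self.steady("in", "inlet", 1.0, 100.0, 1e-4)
        b_out = self.steady("out", "outlet", 1.0, 200.0, 1e-4)
        res = energy_loss([b_in, b_out], period_s=1.0)
        assert res.el_w < 0 and res.negative_warning


class TestFlowDistribution:
    @staticmethod
    def const_wave(u, site=""):
        t = np.arange(20) / 20
        return Waveform(t, np.full(20, u), 1.0, site)

    def test_fraction_of_inflow(self):
        fd = flow_distribution((self.const_wave(1.0), 5e-4),
                               [("LSA", self.const_wave(1.0), 1e-4)])
        assert fd.ratios["LSA"] == pytest.approx(0.2)

    def test_identical_branch_is_unity(self):
        fd = flow_distribution((self.const_wave(0.8), 3e-4),
                               [("b", self.const_wave(0.8), 3e-4)])
        assert fd.ratios["b"] == pytest.approx(1.0)

    def test_four_branch_bookkeeping(self):
        branches = [(f"b{i}", self.const_wave(1.0), 1e-5) for i in range(4)]
        fd = flow_distribution((self.const_wave(1.0), 1e-4), branches)
        assert all(r == pytest.approx(0.1) for r in fd.ratios.values())
        assert sum(fd.ratios.values()) == pytest.approx(0.4)

    def test_zero_inflow_rejected(self):
        with pytest.raises(ZeroDivisionError):
            flow_distribution((self.const_wave(0.0), 1e-4),
                              [("b", self.const_wave(1.0), 1e-5)])


class TestCircumferentialAverage:
    def test_uniform_field(self, small_cylinder):
        _, mesh, cl = small_cylinder
        s, prof = circumferential_average(np.full(mesh.n_vertices, 3.3), mesh, cl)
        assert np.allclose(prof[np.isfinite(prof)], 3.3)

    def test_axial_coordinate_field(self, small_cylinder):
        _, mesh, cl = small_cylinder
        s, prof = circumferential_average(mesh.vertices[:, 2], mesh, cl,
                                          interval_mm=2.0)
        ok = np.isfinite(prof)
        assert np.max(np.abs(prof[ok] - s[ok])) <= 1.0 + 1e-9

    def test_vertex_permutation_invariance(self, small_cylinder, rng):
        _, mesh, cl = small_cylinder
        field = rng.normal(size=mesh.n_vertices)
        _, a = circumferential_average(field, mesh, cl)
        perm = rng.permutation(mesh.n_vertices)
        mesh_p = mesh.copy(vertices=mesh.vertices[perm])
        _, b = circumferential_average(field[perm], mesh_p, cl)
        np.testing.assert_allclose(a, b, rtol=1e-12)
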